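"""Decile-based exposure disparity statistics.

Tracts are partitioned by extreme values of a demographic variable (first
and tenth deciles by default). The disparity ratio is the mean exposure of
the marginalized subgroup divided by the mean exposure of the
nonmarginalized subgroup, on the raw concentration scale. Two significance
procedures accompany it: a two-sample Kolmogorov-Smirnov test comparing the
subgroup exposure distributions within a period, and a two-sample z test on
log-transformed exposures for whether the disparity changed between the
baseline and lockdown periods (|z| > 1.96 at the 95% level).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SubgroupPartition",
    "DisparityResult",
    "MARGINALIZED_SIDE",
    "partition_deciles",
    "disparity_ratio",
    "ks_subgroup_test",
    "disparity_change_test",
    "profile_drop_deciles",
    "compute_disparities",
]

Z_CRITICAL = 1.96
KS_ALPHA = 0.05

#: which decile of each demographic variable is the marginalized subgroup
MARGINALIZED_SIDE = {
    "frac_white": "low",       # least White
    "frac_black": "high",
    "frac_hispanic": "high",   # most Hispanic
    "median_income": "low",    # lowest income
    "frac_no_vehicle": "high",  # lowest vehicle ownership
    "frac_college": "low",     # lowest educational attainment
    "frac_graduate": "low",
}


class DegeneratePartitionError(ValueError):
    """All values identical; decile subgroups are undefined."""


@dataclass
class SubgroupPartition:
    """Tracts in the extreme deciles of one demographic variable."""

    variable: str
    conglomeration: str
    lower_pct: float
    upper_pct: float
    low_ids: pd.Index
    high_ids: pd.Index
    marginalized: str = "low"  # which side is the marginalized subgroup
    thresholds: tuple = (math.nan, math.nan)

    @property
    def marginalized_ids(self) -> pd.Index:
        return self.low_ids if self.marginalized == "low" else self.high_ids

    @property
    def nonmarginalized_ids(self) -> pd.Index:
        return self.high_ids if self.marginalized == "low" else self.low_ids


@dataclass
class DisparityResult:
    variable: str
    conglomeration: str
    mean_marg_baseline: float
    mean_nonmarg_baseline: float
    ratio_baseline: float
    ks_p_baseline: float
    significant_baseline: bool
    mean_marg_lockdown: float
    mean_nonmarg_lockdown: float
    ratio_lockdown: float
    ks_p_lockdown: float
    significant_lockdown: bool
    z_change: float
    change_significant: bool
    n_marg: int
    n_nonmarg: int


def partition_deciles(
    values: pd.Series,
    lower_pct: float = 10.0,
    upper_pct: float = 90.0,
    variable: str = "",
    conglomeration: str = "all",
    marginalized: str | None = None,
) -> SubgroupPartition:
    """Split tracts at the ``lower_pct`` / ``upper_pct`` percentiles.

    Low subgroup: value <= P_lower; high subgroup: value >= P_upper,
    percentiles by linear interpolation. Under heavy ties the subgroups are
    capped at ceil(n * tail_fraction), keeping the smallest (resp. largest)
    values with ties broken by tract-id order so membership is reproducible.
    """
    v = values.dropna()
    n = len(v)
    if n < 20:
        raise ValueError(f"need >= 20 tracts with values, got {n}")
    arr = v.to_numpy(dtype=float)
    if np.ptp(arr) == 0:
        raise DegeneratePartitionError(f"all values of {variable or 'variable'} identical")
    p_lo, p_hi = np.percentile(arr, [lower_pct, upper_pct])

    cap_lo = math.ceil(n * lower_pct / 100.0)
    cap_hi = math.ceil(n * (100.0 - upper_pct) / 100.0)
    order = np.lexsort((v.index.to_numpy(), arr))
    low_sorted = order[arr[order] <= p_lo][:cap_lo]
    order_hi = np.lexsort((v.index.to_numpy(), -arr))
    high_sorted = order_hi[arr[order_hi] >= p_hi][:cap_hi]

    low_ids = v.index[np.sort(low_sorted)]
    high_ids = v.index[np.sort(high_sorted)]
    if marginalized is None:
        marginalized = MARGINALIZED_SIDE.get(variable, "low")
    return SubgroupPartition(
        variable=variable,
        conglomeration=conglomeration,
        lower_pct=lower_pct,
        upper_pct=upper_pct,
        low_ids=low_ids,
        high_ids=high_ids,
        marginalized=marginalized,
        thresholds=(float(p_lo), float(p_hi)),
    )


def _subgroup_values(exposures: pd.Series, ids: pd.Index) -> np.ndarray:
    vals = exposures.reindex(ids).dropna().to_numpy(dtype=float)
    return vals


def disparity_ratio(exposures: pd.Series, partition: SubgroupPartition):
    """Subgroup mean exposures and their ratio (marginalized / nonmarginalized).

    Means are arithmetic means on the raw scale.
    Returns (ratio, mean_marginalized, mean_nonmarginalized).
    """
    m = _subgroup_values(exposures, partition.marginalized_ids)
    nm = _subgroup_values(exposures, partition.nonmarginalized_ids)
    if m.size == 0 or nm.size == 0:
        raise ValueError("empty subgroup")
    mean_m = float(m.mean())
    mean_nm = float(nm.mean())
    if mean_nm <= 0:
        raise ValueError("nonmarginalized subgroup mean is not positive")
    return mean_m / mean_nm, mean_m, mean_nm


def ks_subgroup_test(exposures: pd.Series, partition: SubgroupPartition, alpha: float = KS_ALPHA):
    """Two-sided two-sample KS test between the subgroup exposure distributions.

    Returns (D, p, significant at alpha).
    """
    a = _subgroup_values(exposures, partition.marginalized_ids)
    b = _subgroup_values(exposures, partition.nonmarginalized_ids)
    if a.size < 1 or b.size < 1:
        raise ValueError("empty subgroup")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


def disparity_change_test(
    exposures_baseline: pd.Series,
    exposures_lockdown: pd.Series,
    partition: SubgroupPartition,
):
    """z test for a change in the log-scale disparity between the two periods.

    The statistic is the difference-in-differences of mean log exposures,

        z = [(m_L - nm_L) - (m_B - nm_B)] / SE,

    where m/nm are subgroup means of log NO2 per period and SE pools the four
    independent group variances (Welch-style, s^2/n summed). Nonpositive
    exposures cannot be log-transformed and are dropped (count returned).
    Returns (z, significant at |z| > 1.96, n_dropped).
    """
    groups = []
    n_dropped = 0
    for expo in (exposures_baseline, exposures_lockdown):
        for ids in (partition.marginalized_ids, partition.nonmarginalized_ids):
            vals = _subgroup_values(expo, ids)
            pos = vals[vals > 0]
            n_dropped += vals.size - pos.size
            if pos.size < 2:
                raise ValueError("a subgroup has fewer than 2 positive exposures")
            groups.append(np.log(pos))
    mb, nmb, ml, nml = groups
    delta_b = mb.mean() - nmb.mean()
    delta_l = ml.mean() - nml.mean()
    se = math.sqrt(sum(g.var(ddof=1) / g.size for g in groups))
    z = (delta_l - delta_b) / se
    return float(z), bool(abs(z) > Z_CRITICAL), int(n_dropped)


def profile_drop_deciles(
    delta: pd.Series,
    tracts: pd.DataFrame,
    variables: list[str] | None = None,
    lower_pct: float = 10.0,
    upper_pct: float = 90.0,
) -> pd.DataFrame:
    """Demographic profiles of the extreme deciles of the NO2 change.

    For urban tracts partitioned by delta-NO2 (first decile = largest drops,
    tenth decile = smallest drops), returns mean demographics over the
    largest-drop decile, all tracts considered, and the smallest-drop decile,
    plus a KS p-value comparing each variable's distribution between the two
    extreme deciles.
    """
    if variables is None:
        variables = [
            "frac_white",
            "frac_black",
            "frac_other",
            "frac_hispanic",
            "median_income",
            "frac_highschool",
            "frac_college",
            "frac_graduate",
            "frac_no_vehicle",
        ]
        variables = [v for v in variables if v in tracts.columns]
    part = partition_deciles(
        delta.dropna(), lower_pct, upper_pct, variable="delta_no2", marginalized="low"
    )
    demo = tracts.set_index("tract_id") if "tract_id" in tracts.columns else tracts
    rows = []
    for var in variables:
        largest = demo.loc[demo.index.intersection(part.low_ids), var].dropna()
        smallest = demo.loc[demo.index.intersection(part.high_ids), var].dropna()
        everyone = demo.loc[demo.index.intersection(delta.dropna().index), var].dropna()
        if len(largest) and len(smallest):
            ks = stats.ks_2samp(largest, smallest, method="asymp")
            p = float(ks.pvalue)
        else:
            p = math.nan
        rows.append(
            {
                "variable": var,
                "mean_largest_drops": float(largest.mean()),
                "mean_all": float(everyone.mean()),
                "mean_smallest_drops": float(smallest.mean()),
                "ks_p": p,
                "significant": bool(p < KS_ALPHA) if not math.isnan(p) else False,
            }
        )
    return pd.DataFrame(rows)


def _conglomeration_mask(tracts: pd.DataFrame, key: str) -> pd.Series:
    if key == "all":
        return pd.Series(True, index=tracts.index)
    if key == "urban":
        return tracts["urban"].astype(bool)
    if key == "rural":
        return ~tracts["urban"].astype(bool)
    if key.startswith("msa:"):
        return tracts["msa_key"] == key[4:]
    raise ValueError(f"unknown conglomeration {key!r}")


def compute_disparities(
    exposures: pd.DataFrame,
    tracts: pd.DataFrame,
    variables: list[str] | None = None,
    conglomerations: list[str] | None = None,
    lower_pct: float = 10.0,
    upper_pct: float = 90.0,
) -> pd.DataFrame:
    """Disparity table: one row per variable x conglomeration.

    ``exposures`` must carry tract_id, no2_baseline, no2_lockdown. Decile
    thresholds are recomputed within each conglomeration. Tracts missing the
    demographic variable are excluded from that variable's partition only.
    """
    if variables is None:
        variables = ["frac_white", "frac_hispanic", "median_income",
                     "frac_no_vehicle", "frac_college"]
    if conglomerations is None:
        conglomerations = ["all", "urban", "rural"]
    tr = tracts.set_index("tract_id") if "tract_id" in tracts.columns else tracts
    ex = exposures.set_index("tract_id") if "tract_id" in exposures.columns else exposures
    rows = []
    for cong in conglomerations:
        mask = _conglomeration_mask(tr, cong)
        sub = tr.loc[mask]
        for var in variables:
            values = sub[var].dropna()
            values = values.loc[values.index.intersection(ex.index)]
            try:
                part = partition_deciles(values, lower_pct, upper_pct, variable=var,
                                         conglomeration=cong)
            except (ValueError, DegeneratePartitionError):
                continue
            eb = ex["no2_baseline"]
            el = ex["no2_lockdown"]
            rb, mb, nmb = disparity_ratio(eb, part)
            rl, ml, nml = disparity_ratio(el, part)
            _, pb, sb = ks_subgroup_test(eb, part)
            _, pl, sl = ks_subgroup_test(el, part)
            z, zsig, _ = disparity_change_test(eb, el, part)
            rows.append(
                DisparityResult(
                    variable=var,
                    conglomeration=cong,
                    mean_marg_baseline=mb,
                    mean_nonmarg_baseline=nmb,
                    ratio_baseline=rb,
                    ks_p_baseline=pb,
                    significant_baseline=sb,
                    mean_marg_lockdown=ml,
                    mean_nonmarg_lockdown=nml,
                    ratio_lockdown=rl,
                    ks_p_lockdown=pl,
                    significant_lockdown=sl,
                    z_change=z,
                    change_significant=zsig,
                    n_marg=len(part.marginalized_ids),
                    n_nonmarg=len(part.nonmarginalized_ids),
                ).__dict__
            )
    return pd.DataFrame(rows)
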