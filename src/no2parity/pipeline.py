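"""End-to-end orchestration: scenario -> regrid -> harmonize -> statistics.

A single RunConfig drives either a fully synthetic run (scenario generated
in memory) or a real-format run (pixel CSVs, tract GeoJSON, road GeoJSON
read from disk). Every stage's exclusion counts land in a reproducibility
manifest together with a hash of the configuration and the seed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .disparity import compute_disparities, disparity_ratio, partition_deciles, profile_drop_deciles
from .harmonize import build_exposure_table
from .regrid import GridSpec, difference, filter_pixels, oversample
from .roads import density_by_decile, segment_counts
from .synthetic import ScenarioConfig, Scenario, generate_scenario

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "sensitivity_sweep"]


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    mode: str = "synthetic"
    baseline_start: dt.date = dt.date(2019, 3, 13)
    baseline_end: dt.date = dt.date(2019, 6, 13)
    lockdown_start: dt.date = dt.date(2020, 3, 13)
    lockdown_end: dt.date = dt.date(2020, 6, 13)
    qa_threshold: float = 0.75
    grid_resolution: float = 0.01
    lower_pct: float = 10.0
    upper_pct: float = 90.0
    conglomerations: tuple = ("all", "urban", "rural")
    variables: tuple = ("frac_white", "frac_hispanic", "median_income",
                        "frac_no_vehicle", "frac_college")
    road_radius_km: float = 1.0
    seed: int = 0
    outdir: str | None = None
    scenario: ScenarioConfig | None = None
    # real mode inputs
    pixels_baseline_path: str | None = None
    pixels_lockdown_path: str | None = None
    tracts_path: str | None = None
    roads_path: str | None = None
    grid_bbox: tuple | None = None

    def __post_init__(self):
        if self.mode not in ("synthetic", "real"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if not (self.baseline_start < self.baseline_end
                and self.lockdown_start < self.lockdown_end):
            raise ValidationError("period start must precede end")
        if (self.baseline_end - self.baseline_start) != (
            self.lockdown_end - self.lockdown_start
        ):
            raise ValidationError("baseline and lockdown windows must have equal length")
        if self.mode == "real":
            for p in (self.pixels_baseline_path, self.pixels_lockdown_path,
                      self.tracts_path, self.roads_path):
                if p is None:
                    raise ValidationError("real mode requires all input paths")
                if not Path(p).exists():
                    raise ValidationError(f"input path does not exist: {p}")
        if self.mode == "synthetic" and self.scenario is None:
            object.__setattr__(self, "scenario",
                               ScenarioConfig(rng_seed=self.seed))

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), default=str, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    exposures: pd.DataFrame
    disparities: pd.DataFrame
    drop_profile: pd.DataFrame
    road_counts: pd.DataFrame
    road_profiles: pd.DataFrame
    manifest: dict
    grids: dict = dc_field(default_factory=dict)
    scenario: Scenario | None = None


def _expand_conglomerations(keys, tracts) -> list[str]:
    out = []
    for k in keys:
        if k == "msa:*":
            msas = sorted({m for m in tracts["msa_key"].dropna().unique()})
            out.extend(f"msa:{m}" for m in msas)
        else:
            out.append(k)
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages and return tables plus a reproducibility manifest."""
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "mode": config.mode,
    }

    scenario = None
    if config.mode == "synthetic":
        scen_cfg = config.scenario
        scenario = generate_scenario(scen_cfg)
        tracts = scenario.tracts
        roads = scenario.roads
        pixels = scenario.pixels
        spec = GridSpec.from_bbox(scen_cfg.domain_bbox, config.grid_resolution)
        manifest["excess_scale"] = scenario.field.excess_scale
    else:
        tracts = nio.read_tracts_geojson(config.tracts_path)
        roads = nio.read_roads_geojson(config.roads_path)
        pixels = {
            "baseline": nio.read_pixels_csv(config.pixels_baseline_path),
            "lockdown": nio.read_pixels_csv(config.pixels_lockdown_path),
        }
        windows = {
            "baseline": (config.baseline_start, config.baseline_end),
            "lockdown": (config.lockdown_start, config.lockdown_end),
        }
        for period, df in pixels.items():
            d = pd.to_datetime(df["date"]).dt.date
            lo, hi = windows[period]
            pixels[period] = df.loc[(d >= lo) & (d <= hi)]
        if config.grid_bbox is not None:
            bbox = config.grid_bbox
        else:
            lons = pd.concat([p["center_lon"] for p in pixels.values()])
            lats = pd.concat([p["center_lat"] for p in pixels.values()])
            bbox = (lons.min(), lats.min(), lons.max() + 1e-9, lats.max() + 1e-9)
        spec = GridSpec.from_bbox(bbox, config.grid_resolution)

    grids = {}
    for period in ("baseline", "lockdown"):
        raw = pixels[period]
        kept = filter_pixels(raw, config.qa_threshold)
        manifest[f"n_pixels_raw_{period}"] = int(len(raw))
        manifest[f"n_pixels_kept_{period}"] = int(len(kept))
        grids[period] = oversample(kept, spec, period=period)
    grids["delta"] = difference(grids["lockdown"], grids["baseline"])

    exposures, exclusions = build_exposure_table(grids["baseline"], grids["lockdown"], tracts)
    manifest["n_tracts"] = int(len(tracts))
    manifest["n_tracts_excluded"] = len(exclusions["no_exposure"])
    manifest["excluded_tract_ids"] = exclusions["no_exposure"]
    manifest["interpolated_fraction"] = (
        float(exposures["interpolated"].mean()) if len(exposures) else float("nan")
    )
    demo_missing = tracts[list(config.variables)].isna().any(axis=1)
    manifest["n_tracts_missing_demographics"] = int(demo_missing.sum())

    congs = _expand_conglomerations(config.conglomerations, tracts)
    disparities = compute_disparities(
        exposures, tracts, list(config.variables), congs,
        config.lower_pct, config.upper_pct,
    )

    urban_ids = tracts.loc[tracts["urban"].astype(bool), "tract_id"]
    delta = exposures.set_index("tract_id")["delta_no2"]
    delta_urban = delta.loc[delta.index.intersection(urban_ids)]
    drop_profile = profile_drop_deciles(delta_urban, tracts,
                                        lower_pct=config.lower_pct,
                                        upper_pct=config.upper_pct)

    counts = segment_counts(
        tracts["centroid_lon"].to_numpy(), tracts["centroid_lat"].to_numpy(),
        roads, radius_km=config.road_radius_km,
    )
    road_counts = pd.DataFrame({"tract_id": tracts["tract_id"], "segment_count": counts})
    rc = road_counts.set_index("tract_id")["segment_count"]
    urban_idx = rc.index.intersection(urban_ids)
    tr_idx = tracts.set_index("tract_id")
    rng = np.random.default_rng([config.seed, 99])
    profile_rows = []
    for var in list(config.variables) + ["delta_no2"]:
        vals = (delta_urban if var == "delta_no2"
                else tr_idx.loc[urban_idx, var])
        try:
            prof = density_by_decile(rc.loc[urban_idx], vals, ci=(var == "delta_no2"),
                                     rng=rng)
        except ValueError:
            continue
        prof.insert(0, "variable", var)
        profile_rows.append(prof)
    road_profiles = (
        pd.concat(profile_rows, ignore_index=True) if profile_rows else pd.DataFrame()
    )

    result = PipelineResult(
        exposures=exposures,
        disparities=disparities,
        drop_profile=drop_profile,
        road_counts=road_counts,
        road_profiles=road_profiles,
        manifest=manifest,
        grids=grids,
        scenario=scenario,
    )
    if config.outdir:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: RunConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.exposures.to_csv(out / "exposures.csv", index=False)
    result.disparities.to_csv(out / "disparities.csv", index=False)
    result.drop_profile.to_csv(out / "drop_profile.csv", index=False)
    result.road_counts.to_csv(out / "road_counts.csv", index=False)
    result.road_profiles.to_csv(out / "road_profiles.csv", index=False)
    for period, grid in result.grids.items():
        nio.write_grid_csv(grid, out / f"grid_{period}.csv")
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, default=str))


def sensitivity_sweep(config: RunConfig, settings: list[dict]) -> pd.DataFrame:
    """Disparity ratios under alternative percentile thresholds / period shifts.

    Each setting dict may override ``lower_pct``/``upper_pct`` and (for
    synthetic runs) shift the period start by ``start_shift_days``. Returns
    one row per setting x variable with baseline and lockdown ratios.
    """
    if len(settings) < 1:
        raise ValidationError("need at least one setting")
    rows = []
    for i, setting in enumerate(settings):
        overrides = {k: v for k, v in setting.items() if k in ("lower_pct", "upper_pct")}
        cfg = dataclasses.replace(config, **overrides, outdir=None)
        if "start_shift_days" in setting and cfg.mode == "synthetic":
            shift = dt.timedelta(days=setting["start_shift_days"])
            cfg = dataclasses.replace(
                cfg,
                baseline_start=cfg.baseline_start + shift,
                baseline_end=cfg.baseline_end + shift,
                lockdown_start=cfg.lockdown_start + shift,
                lockdown_end=cfg.lockdown_end + shift,
            )
        res = run_pipeline(cfg)
        sub = res.disparities[res.disparities["conglomeration"] == "all"]
        for rec in sub.itertuples(index=False):
            rows.append(
                {
                    "setting": setting.get("name", f"s{i}"),
                    "lower_pct": cfg.lower_pct,
                    "upper_pct": cfg.upper_pct,
                    "variable": rec.variable,
                    "ratio_baseline": rec.ratio_baseline,
                    "ratio_lockdown": rec.ratio_lockdown,
                }
            )
    return pd.DataFrame(rows)
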