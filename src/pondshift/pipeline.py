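"""Orchestration: run the full analysis on survey tables or synthetic data.

The pipeline wires the stages together: pond condition and availability ->
species-year summaries -> interspecific and intraspecific d-a model suites
-> regime-shift scans -> connectivity comparisons -> cross-correlation
diagnostics, and emits a machine-readable report.  Summaries follow the
mean-of-yearly-means convention throughout (a species' abundance is the
mean across years of its yearly mean density in occupied ponds, not the
pooled mean).  All p-values are reported raw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import availability as avail_mod
from . import connectivity as conn_mod
from . import core_io, da_models, timeseries_stats
from .regime_shift import StarsParams, stars

__all__ = ["AnalysisConfig", "interspecific_points", "run_all", "load_config"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class AnalysisConfig:
    survey: str | None = None
    ponds: str | None = None
    hydro: str | None = None
    tree: str | None = None
    synthetic_seed: int | None = None     # generate the canned scenario instead
    condition_threshold: float = avail_mod.CONDITION_THRESHOLD
    stars_cutoff: int = 4
    stars_alpha: float = 0.05
    exclude_species: tuple = ()
    alpha_dispersal: float = conn_mod.DEFAULT_ALPHA
    pic: bool = False
    seed: int = 0
    out: str = "results"

    def validate(self) -> None:
        if self.synthetic_seed is None:
            for name in ("survey", "ponds", "hydro"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"config is missing a {name} path and "
                                     f"no synthetic_seed is set")
                if not Path(path).exists():
                    raise ValueError(f"{name} file not found: {path}")


def load_config(path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = AnalysisConfig(**raw)
    cfg.validate()
    return cfg


def interspecific_points(survey: pd.DataFrame,
                         availability: dict[str, pd.DataFrame] | None = None
                         ) -> pd.DataFrame:
    """Per-species coordinates of the distribution-abundance scatter.

    Returns mean density in occupied ponds (mean of yearly means), mean
    number of ponds occupied, and, when availability series are supplied,
    mean constrained occupancy.
    """
    summ = core_io.species_year_summary(survey)
    rows = []
    for sp, sub in summ.groupby("species_id"):
        occupied_years = sub.dropna(subset=["mean_density_occupied"])
        if occupied_years.empty:
            continue
        row = {
            "species_id": sp,
            "mean_density": float(occupied_years["mean_density_occupied"].mean()),
            "mean_occupancy": float(sub["n_occupied"].mean()),
        }
        if availability and sp in availability:
            av = availability[sp]
            row["mean_constrained_occupancy"] = float(
                av["constrained_occupancy"].mean(skipna=True))
        rows.append(row)
    return pd.DataFrame(rows)


def _round_floats(obj, ndigits=6):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else round(v, ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_all(config: AnalysisConfig) -> dict:
    """Run the full pipeline; returns the report dict and writes the bundle."""
    config.validate()
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthetic_seed is not None:
        from .synthetic_data import scenario_chorus_frog
        bundle = scenario_chorus_frog(config.synthetic_seed)
        survey = bundle["survey"]
        ponds = bundle["landscape"]
        hydro = bundle["hydro"]
        focal = bundle["focal"]
    else:
        survey = core_io.read_survey(config.survey)
        ponds = core_io.read_ponds(config.ponds)
        hydro = core_io.read_hydro(config.hydro)
        focal = None

    survey = survey[~survey["species_id"].isin(config.exclude_species)]
    collapsed = core_io.season_collapse(survey)
    conditions = avail_mod.pond_condition(hydro, ponds)
    species = sorted(collapsed["species_id"].unique())

    availability = {}
    for sp in species:
        availability[sp] = avail_mod.availability_series(
            collapsed, conditions, sp, threshold=config.condition_threshold)

    points = interspecific_points(survey, availability)
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "seed": config.seed, "species": species,
                    "interspecific": {"points": points.to_dict("records")}}

    # interspecific d-a fits (raw and constrained occupancy axes)
    if len(points) >= 4:
        x = points["mean_density"].to_numpy()
        for axis, col in (("raw", "mean_occupancy"),
                          ("constrained", "mean_constrained_occupancy")):
        # the constrained axis only exists when availability could be built
            if col not in points or points[col].isna().all():
                continue
            y = points[col].to_numpy(dtype=float)
            models = da_models.fit_all(x, y, n_boot=0)
            tab = da_models.aicc_rank(models)
            report["interspecific"][f"fit_{axis}"] = tab[
                ["family", "K", "rss", "aicc", "delta", "weight",
                 "evidence_ratio"]].to_dict("records")

    # per-species regime shifts and tracking
    per_species = {}
    params = StarsParams(cutoff=config.stars_cutoff, alpha=config.stars_alpha)
    years = sorted(collapsed["year"].unique())
    for sp in species:
        occ = (collapsed[(collapsed["species_id"] == sp) & collapsed["present"]]
               .groupby("year")["pond_id"].nunique()
               .reindex(years).fillna(0).astype(float))
        entry: dict = {}
        if len(occ) >= params.cutoff:
            res = stars(occ, params)
            entry["regime_shifts"] = {
                "shift_years": [int(y) for y in res.shift_years],
                "rsi": [float(res.table.loc[y, "rsi"]) for y in res.shift_years],
                "regime_means": [float(m) for m in res.regime_means],
            }
        av = availability[sp]
        tracking = timeseries_stats.tracking_metrics(
            pd.Series(av["n_occupied"].values, index=av["year"]),
            pd.Series(av["n_available"].values, index=av["year"]))
        entry["tracking"] = tracking
        per_species[sp] = entry
    report["per_species"] = per_species

    # connectivity: Hanski index from last-year populations, occupied vs not
    last = years[-1]
    hy_last = hydro[hydro["year"] == last].set_index("pond_id")["area"]
    conn = {}
    for sp in (([focal] if focal else species[:1])):
        sub = collapsed[(collapsed["species_id"] == sp)
                        & (collapsed["year"] == last)]
        dens = sub.set_index("pond_id")["density"]
        pops = (dens * hy_last).reindex(ponds.index).fillna(0.0)
        idx = conn_mod.hanski_index(ponds, pops, config.alpha_dispersal)
        occupied = sub.set_index("pond_id")["present"].reindex(
            ponds.index).fillna(False)
        conn[sp] = conn_mod.compare_occupied(idx, occupied)
    report["connectivity"] = conn

    # cross-correlation of focal ln density vs occupancy
    if focal:
        f = collapsed[(collapsed["species_id"] == focal) & collapsed["present"]]
        dens = f.groupby("year")["density"].mean().reindex(years)
        occ = f.groupby("year")["pond_id"].nunique().reindex(years).fillna(0)
        with np.errstate(divide="ignore"):
            lnd = np.log(dens.astype(float))
        cc = timeseries_stats.cross_correlation(
            lnd.dropna(), occ.astype(float), max_lag=3)
        report["cross_correlation"] = cc.to_dict("records")

    report = _round_floats(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    points.to_csv(out / "interspecific_points.csv", index=False)
    return report
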