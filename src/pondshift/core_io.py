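"""Domain data model and readers/writers for survey tables, trees and rasters.

The pipeline's universal input is the long-format survey table: one row per
pond x year x season x species with a larval density (individuals/m^2) and a
presence flag (presence means density > 0; there is no detection-probability
model).  Pond attributes and per-year hydrology travel in separate tables.

All tabular I/O is plain UTF-8 CSV with a header row; phylogenies are newick
(read with dendropy); friction rasters are ESRI ASCII grids.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Pond", "FrictionRaster", "SurveySchemaError",
    "SURVEY_COLUMNS", "POND_COLUMNS", "HYDRO_COLUMNS",
    "read_survey", "write_survey", "validate_survey",
    "read_ponds", "read_hydro", "read_tree", "read_raster", "write_raster",
    "season_collapse", "cohort_adjust", "species_year_summary",
]

SURVEY_COLUMNS = ["pond_id", "year", "season", "species_id", "density"]
POND_COLUMNS = ["pond_id", "x", "y", "region", "canopy", "max_area_ever"]
HYDRO_COLUMNS = ["pond_id", "year", "area", "hydroperiod",
                 "dried_prev_fall", "dry_before_sampling"]

CANOPY_CLOSED_COVER = 0.75   # canopy cover above this counts as closed


class SurveySchemaError(ValueError):
    """A required column is missing or malformed."""


@dataclass(frozen=True)
class Pond:
    pond_id: str
    x: float
    y: float
    region: str = "other"
    canopy: str = "open"
    max_area_ever: float = 1.0

    def __post_init__(self):
        if self.max_area_ever <= 0:
            raise ValueError(f"pond {self.pond_id}: max_area_ever must be > 0")
        if self.canopy not in ("open", "closed"):
            raise ValueError(f"pond {self.pond_id}: canopy must be open|closed")


@dataclass
class FrictionRaster:
    values: np.ndarray            # (nrows, ncols), row 0 = north
    cellsize: float
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata: float = -9999.0
    class_map: dict = field(default_factory=lambda: {
        "wetland": 1.0, "forest": 3.0, "open": 10.0, "slope": 100.0})


def _require_columns(df: pd.DataFrame, cols, what: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SurveySchemaError(f"{what} is missing column(s): {missing}")


def validate_survey(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, SURVEY_COLUMNS, "survey table")
    df = df.copy()
    df["year"] = pd.to_numeric(df["year"], errors="raise").astype(int)
    df["density"] = pd.to_numeric(df["density"], errors="raise").astype(float)
    bad = df.index[~np.isfinite(df["density"]) | (df["density"] < 0)]
    if len(bad):
        raise SurveySchemaError(
            f"negative or non-finite density at row(s) {list(bad[:10])}")
    dup = df.duplicated(subset=["pond_id", "year", "season", "species_id"])
    if dup.any():
        raise SurveySchemaError(
            f"duplicate (pond, year, season, species) rows at {list(df.index[dup][:10])}")
    df["present"] = df["density"] > 0
    return df


def read_survey(path) -> pd.DataFrame:
    """Read and validate a long-format survey CSV."""
    return validate_survey(pd.read_csv(path))


def write_survey(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=[c for c in df.columns
                                          if c in SURVEY_COLUMNS + ["present"]])


def read_ponds(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, POND_COLUMNS, "pond table")
    if (df["max_area_ever"] <= 0).any():
        raise SurveySchemaError("max_area_ever must be positive")
    return df.set_index("pond_id")


def read_hydro(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, HYDRO_COLUMNS, "hydrology table")
    if ((df["hydroperiod"] < 0) | (df["hydroperiod"] > 1)).any():
        raise SurveySchemaError("hydroperiod must lie in [0, 1]")
    if (df["area"] < 0).any():
        raise SurveySchemaError("areas must be non-negative")
    for c in ("dried_prev_fall", "dry_before_sampling"):
        df[c] = df[c].astype(bool)
    return df


def season_collapse(survey: pd.DataFrame) -> pd.DataFrame:
    """One record per pond-year-species: the season with maximum density.

    Presence is any-season presence.  Idempotent: collapsing a collapsed
    table is a no-op (the season column becomes ``"max"``).
    """
    survey = validate_survey(survey)
    g = survey.groupby(["pond_id", "year", "species_id"], as_index=False)
    out = g.agg(density=("density", "max"), present=("present", "any"))
    out["season"] = "max"
    return out[["pond_id", "year", "season", "species_id", "density", "present"]]


def cohort_adjust(survey: pd.DataFrame, species_id: str,
                  survivorship: float = 0.002, *, midpoint: float = 0.5,
                  hatch_season: str = "july", age1_season: str = "may") -> pd.DataFrame:
    """Rescale a late-breeding species' densities to a common cohort age.

    Species that overwinter as larvae (bullfrog, green frog) are sampled
    either just after hatching (July of the hatch year) or as yearlings
    (May of the following year), so raw densities are biased relative to
    species sampled mid-larval-period.  Both classes are projected to the
    survivorship midpoint between the age classes: hatch-season densities
    are multiplied by ``survivorship**midpoint``, age-1 densities by
    ``survivorship**(midpoint - 1)``, and age-1 records are re-dated to the
    hatch year.  ``survivorship=1`` is the identity.  Zero densities and
    presence/absence are preserved.
    """
    if not 0 < survivorship <= 1:
        raise ValueError("survivorship must lie in (0, 1]")
    survey = validate_survey(survey)
    if species_id not in set(survey["species_id"]):
        import warnings
        warnings.warn(f"cohort_adjust: species {species_id!r} not in table; no-op")
        return survey
    out = survey.copy()
    sp = out["species_id"] == species_id
    hatch = sp & (out["season"] == hatch_season)
    age1 = sp & (out["season"] == age1_season)
    out.loc[hatch, "density"] *= survivorship ** midpoint
    out.loc[age1, "density"] *= survivorship ** (midpoint - 1.0)
    out.loc[age1, "year"] -= 1
    return out


def species_year_summary(survey: pd.DataFrame,
                         wet_area: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per species-year: ponds occupied, mean density in occupied ponds,
    and (if wet areas are given) the regional population size
    ``sum(density * wet area)``.

    Collapses seasons first.  ``mean_density_occupied`` is NaN when no pond
    is occupied.
    """
    tab = season_collapse(survey)
    occ = tab[tab["present"]]
    g = occ.groupby(["species_id", "year"])
    out = g.agg(n_occupied=("pond_id", "nunique"),
                mean_density_occupied=("density", "mean")).reset_index()
    # include species-years with zero occupancy
    all_sy = tab.groupby(["species_id", "year"]).size().reset_index()[
        ["species_id", "year"]]
    out = all_sy.merge(out, on=["species_id", "year"], how="left")
    out["n_occupied"] = out["n_occupied"].fillna(0).astype(int)
    if wet_area is not None:
        m = tab.merge(wet_area[["pond_id", "year", "area"]],
                      on=["pond_id", "year"], how="left")
        m["pop"] = m["density"] * m["area"].fillna(0.0)
        pop = m.groupby(["species_id", "year"])["pop"].sum().rename(
            "regional_population").reset_index()
        out = out.merge(pop, on=["species_id", "year"], how="left")
    return out


def read_tree(path, *, required_taxa=None) -> dendropy.Tree:
    """Read a newick phylogeny; optionally check tips against a species list."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    if required_taxa is not None:
        tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        missing = set(required_taxa) - tips
        if missing:
            raise ValueError(f"tree is missing surveyed species: {sorted(missing)}")
    return tree


def read_raster(path) -> FrictionRaster:
    """Read an ESRI ASCII grid (there is no raster library in the stack)."""
    text = Path(path).read_text()
    lines = text.strip().splitlines()
    header = {}
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value"):
            header[parts[0].lower()] = float(parts[1])
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"malformed ESRI ASCII grid: missing {key} "
                             f"in header (line {i})")
    vals = np.loadtxt(io.StringIO("\n".join(lines[i:])))
    vals = np.atleast_2d(vals)
    if vals.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"grid body {vals.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})")
    return FrictionRaster(
        values=vals, cellsize=header["cellsize"],
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        nodata=header.get("nodata_value", -9999.0),
    )


def write_raster(raster: FrictionRaster, path) -> None:
    nr, nc = raster.values.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nc}\nnrows {nr}\n"
                 f"xllcorner {raster.xllcorner}\nyllcorner {raster.yllcorner}\n"
                 f"cellsize {raster.cellsize}\nNODATA_value {raster.nodata}\n")
        np.savetxt(fh, raster.values, fmt="%.6g")
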