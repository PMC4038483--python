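"""Synthetic pond metacommunities with drought-driven habitat dynamics.

The generator emulates the statistical structure of a two-region kettle-pond
landscape (~37 ponds in east/west wetland chains, nearest neighbours ~80-120 m
within a region and ~1 km across), a multiyear drought that roughly doubles
the annual probability that a pond dries in the fall (0.36 -> 0.80) and
depresses hydroperiod (0.92 -> 0.59), and the resulting food-web release:
fall-dried open-canopy ponds carry only ~25.5% of the predator biomass of
ponds that stayed wet (14% if also dry the following spring), which raises
the larval carrying capacity from ~3.0 to ~6.2 individuals/m^2.  Closed-
canopy ponds are predator-stable, resource-poor sinks (K ~ 0.9/m^2).

Local dynamics are a stochastic Ricker update toward the pond-year carrying
capacity; regional dynamics are density-dependent colonization through a
negative-exponential dispersal kernel (scale 1/alpha = 125 m) and a
density-dependent extinction risk calibrated so that populations below
1.5 individuals/m^2 face a ~0.40 annual extinction probability.

Every stochastic event (colonization, extinction, reproductive failure by
early drying) is recorded in a TruthLog so parameter- and threshold-recovery
tests can compare estimates with ground truth.  All randomness flows from a
single numpy Generator seeded by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ClimateScenario", "SpeciesParams", "PredatorModel", "TruthLog",
    "generate_landscape", "simulate_hydrology", "simulate_metacommunity",
    "scenario_chorus_frog", "extinction_coefficients",
]


@dataclass(frozen=True)
class ClimateScenario:
    years: tuple = tuple(range(1996, 2011))
    drought_years: tuple = tuple(range(1999, 2008))
    p_dry_fall_base: float = 0.36
    p_dry_fall_drought: float = 0.80
    hydroperiod_base: float = 0.92
    hydroperiod_drought: float = 0.59
    p_spring_dry_given_fall: float = 0.30   # dried fall AND early spring
    #: year-to-year sd of the realized annual drying fraction (reported
    #: spreads: +-0.07 outside the drought, +-0.03 during it)
    p_dry_sd_base: float = 0.07
    p_dry_sd_drought: float = 0.03
    hydroperiod_sd: float = 0.05
    #: breeding-window pond condition (window-max area / max area ever).
    #: Fall-drying ponds refill by spring, so the breeding-season condition
    #: drops far less than hydroperiod does during drought.
    condition_base: float = 0.95
    condition_drought: float = 0.85
    condition_sd: float = 0.15
    #: year-to-year persistence of a pond's drying propensity (Gaussian
    #: copula correlation): ponds differ in how prone they are to fall
    #: drying, but quality still fluctuates from year to year.  The annual
    #: marginal drying probability stays exactly at the scenario value.
    drying_persistence: float = 0.85
    #: spatial autocorrelation of drying propensity between neighbouring
    #: ponds along a wetland chain (shared water table): drought-prone
    #: ponds come in clusters, which is what lets a rare species' refuge
    #: cluster recolonize itself after a local extinction.
    dryness_spatial_corr: float = 0.9
    #: loading of (small) pond size on drying propensity: small shallow
    #: ponds dry first, so outside a drought the reliable high-quality
    #: ponds are small ones (weak colonist sources), while a drought
    #: recruits the large ponds into the fall-drying class and multiplies
    #: the landscape's propagule pressure.
    dryness_area_loading: float = 0.2

    def __post_init__(self):
        for p in (self.p_dry_fall_base, self.p_dry_fall_drought,
                  self.hydroperiod_base, self.hydroperiod_drought):
            if not 0 <= p <= 1:
                raise ValueError("probabilities/fractions must lie in [0, 1]")
        if not set(self.drought_years) <= set(self.years):
            raise ValueError("drought_years must be a subset of years")


@dataclass(frozen=True)
class PredatorModel:
    """Predator biomass by pond drying class, as a multiplier of the
    biomass in ponds that stayed wet.  Drying does not affect closed-canopy
    pond predators (their key predators do not overwinter as larvae)."""
    biomass: dict = field(default_factory=lambda: {
        "wet": 1.0, "dried_fall": 0.255, "dried_fall_and_spring": 0.14})

    def multiplier(self, drying_class: str) -> float:
        return self.biomass[drying_class]


@dataclass(frozen=True)
class SpeciesParams:
    """Demographic and dispersal parameters of one species.

    ``k_open`` is the carrying capacity (individuals/m^2) of an open-canopy
    pond under full predator biomass; predator release scales it up as
    ``k_open * (1 + predator_release * (1 - biomass))``, calibrated by
    default so a fall-dried pond (biomass 0.255) reaches 6.2/m^2.  The wet
    default (2.4) puts realized densities of never-drying ponds just above
    the 1.5/m^2 extinction knee: persistent populations need ponds that dry
    in most falls, which is what makes the system threshold-governed.
    Closed-canopy ponds are fixed at ``k_closed`` (demographic sinks).
    """
    species_id: str
    r: float = 1.8                    # intrinsic growth rate (Ricker); explosive breeder
    k_open: float = 1.4
    k_closed: float = 0.9
    predator_release: float = 4.6015  # (6.2/1.4 - 1) / (1 - 0.255)
    alpha: float = 1.0 / 125.0        # dispersal kernel decay, 1/m
    c: float = 2.5e-4                 # colonization coefficient, 1/individuals
    ext_anchor_lo: tuple = (1.5, 0.40)   # (density, P(extinction))
    ext_anchor_hi: tuple = (4.0, 0.005)  # steep knee: refuges persist
    noise_sd: float = 0.3             # lognormal sd on growth
    colonize_density: float = 0.8     # density founders establish at
    #: breeding-site selection: closed-canopy ponds are avoided by
    #: ovipositing females, scaling their colonization rate down
    canopy_preference_closed: float = 0.3
    init_occupancy: float = 0.5
    init_density: float = 2.0         # starting density of initial ponds
    max_overshoot: float = 6.0        # densities clipped at this multiple of K

    def __post_init__(self):
        if min(self.r, self.alpha, self.c, self.k_open) <= 0:
            raise ValueError("r, alpha, c and k_open must be positive")

    def carrying_capacity(self, canopy: str, drying_class: str,
                          predators: PredatorModel) -> float:
        if canopy == "closed":
            return self.k_closed
        b = predators.multiplier(drying_class)
        return self.k_open * (1.0 + self.predator_release * (1.0 - b))


def extinction_coefficients(params: SpeciesParams):
    """(b0, b1) of P(extinct) = logistic(b0 + b1*ln density) through the
    two anchor points."""
    (d1, p1), (d2, p2) = params.ext_anchor_lo, params.ext_anchor_hi
    l1, l2 = np.log(d1), np.log(d2)
    g1, g2 = np.log(p1 / (1 - p1)), np.log(p2 / (1 - p2))
    b1 = (g2 - g1) / (l2 - l1)
    b0 = g1 - b1 * l1
    return float(b0), float(b1)


@dataclass
class TruthLog:
    """Ground truth of a simulation: initial occupancy and every event."""
    initial: pd.DataFrame            # pond_id, species_id, density at t0
    events: pd.DataFrame             # year, pond_id, species_id, event, detail
    carrying: pd.DataFrame           # pond_id, year, species_id, K

    def replay_occupancy(self, ponds, species, years) -> pd.DataFrame:
        """Reconstruct the occupancy matrix from initial state + events."""
        occ = {(p, s): False for p in ponds for s in species}
        for _, row in self.initial.iterrows():
            occ[(row["pond_id"], row["species_id"])] = row["density"] > 0
        ev = self.events.sort_values("year", kind="stable")
        out = []
        for y in years:
            for _, row in ev[ev["year"] == y].iterrows():
                key = (row["pond_id"], row["species_id"])
                if row["event"] == "colonization":
                    occ[key] = True
                elif row["event"] in ("extinction", "drying_failure"):
                    occ[key] = False
            for (p, s), o in occ.items():
                out.append({"year": y, "pond_id": p, "species_id": s,
                            "occupied": o})
        return pd.DataFrame(out)


def generate_landscape(n_ponds: int = 37, region_split=(0.46, 0.54),
                       canopy_fraction_open: float = 0.6,
                       complex_spacing: float = 180.0,
                       within_complex_sd: float = 45.0,
                       region_separation: float = 3000.0,
                       min_spacing: float = 25.0,
                       area_ln_mean: float = np.log(300.0),
                       area_ln_sd: float = 1.0,
                       seed: int | None = None) -> pd.DataFrame:
    """Two regions (east/west) of clustered wetland micro-complexes.

    Each region holds ~n/5 complexes of ~5 ponds; ponds within a complex
    sit tens of metres apart (``within_complex_sd``), complexes a few
    hundred metres apart (``complex_spacing``), and region centres
    ``region_separation`` metres apart, so within-region nearest
    neighbours are ~50-150 m while cross-region neighbours are ~1 km.
    """
    if n_ponds < 2:
        raise ValueError("need at least two ponds")
    if region_separation <= 0 and n_ponds > 1:
        raise ValueError("degenerate spatial extent")
    rng = np.random.default_rng(seed)
    n_east = int(round(n_ponds * region_split[0] /
                       (region_split[0] + region_split[1])))
    n_east = min(max(n_east, 0), n_ponds)
    rows = []
    for region, n_r, x0 in (("east", n_east, region_separation),
                            ("west", n_ponds - n_east, 0.0)):
        if n_r == 0:
            continue
        # ponds come in wetland micro-complexes: 2-4 ponds tens of metres
        # apart sharing a water table, complexes a few hundred metres apart
        n_cplx = max(2, int(round(n_r / 5)))
        radius = 1.3 * complex_spacing * np.sqrt(n_cplx / np.pi)
        centers = []
        while len(centers) < n_cplx:
            rr = radius * np.sqrt(rng.random())
            th = 2 * np.pi * rng.random()
            p = (x0 + rr * np.cos(th), rr * np.sin(th))
            if all((p[0]-q[0])**2 + (p[1]-q[1])**2 >= complex_spacing**2 / 4
                   for q in centers):
                centers.append(p)
        for k in range(n_r):
            j = k % n_cplx
            cx, cy = centers[j]
            while True:
                px = cx + rng.normal(0, within_complex_sd)
                py = cy + rng.normal(0, within_complex_sd)
                ok = all((px-r["x"])**2 + (py-r["y"])**2 >= min_spacing**2
                         for r in rows)
                if ok:
                    break
            z = rng.normal()
            area = float(np.exp(area_ln_mean + area_ln_sd * z))
            # canopy closure correlates with pond permanence/size: small
            # ephemeral meadow ponds are mostly open, large permanent ponds
            # tend to carry forested margins
            p_open = float(np.clip(canopy_fraction_open - 0.25 * z, 0.1, 0.95))
            rows.append({
                "pond_id": f"{region[0].upper()}{k+1:02d}",
                "x": float(px), "y": float(py), "region": region,
                "complex": f"{region[0]}{j}",
                "canopy": "open" if rng.random() < p_open else "closed",
                "max_area_ever": area,
            })
    return pd.DataFrame(rows).set_index("pond_id")


def simulate_hydrology(landscape: pd.DataFrame, scenario: ClimateScenario,
                       seed: int | None = None) -> pd.DataFrame:
    """Per pond-year drying class, hydroperiod, and breeding-window area."""
    rng = np.random.default_rng(seed)
    rho = scenario.drying_persistence
    # pond drying propensities (low z = dries first): a blend of pond size
    # (small shallow ponds dry first) and a shared water-table component
    # per wetland micro-complex, with unit-normal marginals
    rs = scenario.dryness_spatial_corr
    wa = scenario.dryness_area_loading
    if "complex" in landscape.columns:
        cplx_z = {c: rng.standard_normal()
                  for c in landscape["complex"].unique()}
        shared = np.array([rs * cplx_z[c]
                           + np.sqrt(1 - rs ** 2) * rng.standard_normal()
                           for c in landscape["complex"]])
    else:
        shared = rng.standard_normal(len(landscape))
    spatial = pd.Series(shared, index=landscape.index)
    ln_area = np.log(landscape["max_area_ever"])
    z_area = (ln_area - ln_area.mean()) / max(ln_area.std(ddof=0), 1e-9)
    ws = np.sqrt(max(0.0, 1.0 - wa ** 2))
    pond_z = wa * z_area + ws * spatial
    n_p = len(landscape)
    rows = []
    for year in scenario.years:
        drought = year in scenario.drought_years
        p_dry = scenario.p_dry_fall_drought if drought else scenario.p_dry_fall_base
        p_sd = (scenario.p_dry_sd_drought if drought
                else scenario.p_dry_sd_base)
        p_year = float(np.clip(rng.normal(p_dry, p_sd), 0.0, 1.0))
        h_mean = (scenario.hydroperiod_drought if drought
                  else scenario.hydroperiod_base)
        # rank-based drying, per region: each region's round(p*n) most
        # drought-prone ponds (by persistent latent, jittered year to
        # year) dry this fall, so the realized annual drying fraction
        # tracks the target tightly on both sides of the landscape
        z_year = pd.Series(
            rho * pond_z.to_numpy()
            + np.sqrt(1 - rho ** 2) * rng.standard_normal(n_p),
            index=landscape.index)
        dry_set: set = set()
        for _, reg_ponds in landscape.groupby("region"):
            n_dry = int(round(p_year * len(reg_ponds)))
            zr = z_year[reg_ponds.index]
            dry_set |= set(zr.sort_values().index[:n_dry])
        for pid, pond in landscape.iterrows():
            dried_fall = pid in dry_set
            if dried_fall and rng.random() < scenario.p_spring_dry_given_fall:
                drying_class = "dried_fall_and_spring"
            elif dried_fall:
                drying_class = "dried_fall"
            else:
                drying_class = "wet"
            hydroperiod = float(np.clip(
                rng.normal(h_mean, scenario.hydroperiod_sd), 0.0, 1.0))
            c_mean = (scenario.condition_drought if drought
                      else scenario.condition_base)
            condition = float(np.clip(
                rng.normal(c_mean, scenario.condition_sd), 0.0, 1.0))
            dry_before = rng.random() < max(0.0, 0.8 - hydroperiod) * 0.25
            rows.append({
                "pond_id": pid, "year": year,
                "area": condition * pond["max_area_ever"],
                "hydroperiod": hydroperiod,
                "drying_class": drying_class,
                "dried_prev_fall": drying_class != "wet",
                "dry_before_sampling": bool(dry_before),
            })
    return pd.DataFrame(rows)


def simulate_metacommunity(landscape: pd.DataFrame, hydro: pd.DataFrame,
                           species_params: list[SpeciesParams],
                           predators: PredatorModel | None = None,
                           seed: int | None = None,
                           init_state: pd.DataFrame | None = None):
    """Annual pond-by-species dynamics; returns (survey, truth_log).

    Yearly update per species: (1) occupied ponds grow by a stochastic
    Ricker step toward the pond-year carrying capacity; (2) ponds that dry
    before sampling lose the cohort; (3) occupied ponds go extinct with a
    probability declining logistically in ln density; (4) empty ponds are
    colonized with probability ``1 - exp(-c * S_i)`` where
    ``S_i = sum_j N_j * exp(-alpha * d_ij)`` over the other ponds'
    start-of-year population sizes (density x wet area).  The census
    (survey table) records post-update densities.
    """
    predators = predators or PredatorModel()
    rng = np.random.default_rng(seed)
    ponds = list(landscape.index)
    years = sorted(hydro["year"].unique())
    xy = landscape[["x", "y"]].to_numpy(dtype=float)
    dist = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    hyd = hydro.set_index(["pond_id", "year"])

    n_p = len(ponds)
    surveys, events, kvals, init_rows = [], [], [], []
    state = {}
    for sp in species_params:
        if init_state is not None:
            sub = init_state[init_state["species_id"] == sp.species_id]
            dens = np.zeros(n_p)
            for _, row in sub.iterrows():
                dens[ponds.index(row["pond_id"])] = row["density"]
        else:
            # seed initial populations at near-equilibrium density in the
            # kind of pond that can sustain them: open canopy and prone to
            # fall drying (predator-poor), as of the first simulated year
            open_mask = (landscape["canopy"] == "open").to_numpy()
            first = hyd.xs(years[0], level="year").reindex(ponds)
            good = open_mask & first["dried_prev_fall"].to_numpy(dtype=bool)
            if not good.any():
                good = open_mask
            pick = (rng.random(n_p) < sp.init_occupancy) & good
            if not pick.any():
                pick[np.nonzero(good)[0][rng.integers(0, good.sum())]] = True
            dens = np.where(pick, sp.init_density, 0.0)
        state[sp.species_id] = dens
        for i, p in enumerate(ponds):
            init_rows.append({"pond_id": p, "species_id": sp.species_id,
                              "density": dens[i]})

    for year in years:
        hy = hyd.xs(year, level="year").reindex(ponds)
        areas = hy["area"].to_numpy(dtype=float)
        dry_before = hy["dry_before_sampling"].to_numpy(dtype=bool)
        for sp in species_params:
            b0, b1 = extinction_coefficients(sp)
            dens = state[sp.species_id]
            start_dens = dens.copy()
            K = np.array([
                sp.carrying_capacity(landscape.loc[p, "canopy"],
                                     hy.loc[p, "drying_class"], predators)
                for p in ponds])
            for i, p in enumerate(ponds):
                kvals.append({"pond_id": p, "year": year,
                              "species_id": sp.species_id, "K": K[i]})
            occ = dens > 0
            # (1) growth
            noise = rng.lognormal(-sp.noise_sd ** 2 / 2, sp.noise_sd, n_p)
            grown = dens * np.exp(sp.r * (1 - dens / np.maximum(K, 1e-9)))
            dens = np.where(occ, np.minimum(grown * noise,
                                            sp.max_overshoot * K), dens)
            if not np.isfinite(dens).all():
                bad = ponds[int(np.nonzero(~np.isfinite(dens))[0][0])]
                raise FloatingPointError(
                    f"non-finite density at pond {bad}, year {year}")
            # (2) reproductive failure by early drying
            failed = occ & dry_before
            for i in np.nonzero(failed)[0]:
                events.append({"year": year, "pond_id": ponds[i],
                               "species_id": sp.species_id,
                               "event": "drying_failure", "detail": ""})
            dens[failed] = 0.0
            occ = dens > 0
            # (3) extinction, declining with density
            p_ext = np.zeros(n_p)
            p_ext[occ] = 1.0 / (1.0 + np.exp(-(b0 + b1 * np.log(dens[occ]))))
            ext = occ & (rng.random(n_p) < p_ext)
            for i in np.nonzero(ext)[0]:
                events.append({"year": year, "pond_id": ponds[i],
                               "species_id": sp.species_id,
                               "event": "extinction",
                               "detail": f"density={dens[i]:.3f}"})
            dens[ext] = 0.0
            # (4) colonization of empty, not-failed ponds from start-of-year
            #     population sizes
            pops = start_dens * areas
            S = (np.exp(-sp.alpha * dist) - np.eye(n_p)) @ pops
            pref = np.where(landscape["canopy"].to_numpy() == "closed",
                            sp.canopy_preference_closed, 1.0)
            p_col = 1.0 - np.exp(-sp.c * pref * S)
            empty = (dens == 0) & ~dry_before & (areas > 0)
            col = empty & (rng.random(n_p) < p_col)
            for i in np.nonzero(col)[0]:
                events.append({"year": year, "pond_id": ponds[i],
                               "species_id": sp.species_id,
                               "event": "colonization",
                               "detail": f"S={S[i]:.1f}"})
            dens[col] = sp.colonize_density
            state[sp.species_id] = dens
            for i, p in enumerate(ponds):
                surveys.append({"pond_id": p, "year": year, "season": "may",
                                "species_id": sp.species_id,
                                "density": float(dens[i])})

    survey = pd.DataFrame(surveys)
    survey["present"] = survey["density"] > 0
    truth = TruthLog(
        initial=pd.DataFrame(init_rows),
        events=pd.DataFrame(events, columns=["year", "pond_id", "species_id",
                                             "event", "detail"]),
        carrying=pd.DataFrame(kvals),
    )
    return survey, truth


def default_species_pool() -> list[SpeciesParams]:
    """Focal chorus-frog-like species plus a spread of abundant (well-
    dispersing) and rare (dispersal-limited) background species."""
    pool = [SpeciesParams("PTR")]
    # abundant habitat generalists: viable in most open ponds, disperse well
    for sid, k in [("PCR", 8.0), ("RSY", 9.0), ("HVE", 4.0), ("RCL", 2.0)]:
        pool.append(SpeciesParams(sid, k_open=k, c=1.5e-3,
                                  predator_release=0.5, init_occupancy=0.5))
    # intermediate species
    for sid, k in [("ALA", 3.5), ("NVI", 2.5)]:
        pool.append(SpeciesParams(sid, k_open=k, c=4e-4,
                                  predator_release=0.5, init_occupancy=0.4))
    # rare, dispersal-limited species that persist in a few good ponds
    for sid, k, c in [("AMA", 2.6, 1.2e-4), ("ATI", 2.8, 1.2e-4),
                      ("RPI", 2.0, 1.5e-4)]:
        pool.append(SpeciesParams(sid, k_open=k, c=c,
                                  predator_release=0.5, init_occupancy=0.25))
    return pool


def scenario_chorus_frog(seed: int = 0, *, drought: bool = True,
                         n_ponds: int = 37, burn_in: int = 30,
                         species: list[SpeciesParams] | None = None,
                         climate: ClimateScenario | None = None) -> dict:
    """Canned 15-year two-region scenario with a mid-series drought.

    The metacommunity is first burned in for ``burn_in`` years under the
    base climate so the reported window starts at stochastic equilibrium;
    the reported 15 years (1996-2010) then carry a drought from 1999
    through 2007.  At default parameters the focal species' pond occupancy
    shows an upward regime shift after drought onset (lagging the density
    rise) and a collapse when the drought breaks.  ``drought=False`` keeps
    the base climate throughout (the null world).
    """
    rng = np.random.default_rng(seed)
    s_land, s_m0, s_hydro, s_meta = rng.integers(0, 2**31 - 1, 4)
    scenario = climate or ClimateScenario()
    if not drought:
        scenario = replace(scenario, drought_years=())
    landscape = generate_landscape(n_ponds=n_ponds, seed=int(s_land))
    species = species or default_species_pool()

    # hydrology is simulated in one pass over burn-in + reported window so
    # each pond's drying propensity (hence the refuge cluster) persists
    # across the window boundary
    first = scenario.years[0]
    full_years = tuple(range(first - burn_in, first)) + tuple(scenario.years)
    full = replace(scenario, years=full_years)
    hydro_all = simulate_hydrology(landscape, full, seed=int(s_hydro))
    hydro = hydro_all[hydro_all["year"] >= first].reset_index(drop=True)

    init_state = None
    if burn_in > 0:
        pre_hydro = hydro_all[hydro_all["year"] < first]
        pre_survey, _ = simulate_metacommunity(landscape, pre_hydro, species,
                                               seed=int(s_m0))
        last = pre_survey[pre_survey["year"] == first - 1]
        init_state = last[["pond_id", "species_id", "density"]]

    survey, truth = simulate_metacommunity(landscape, hydro, species,
                                           seed=int(s_meta),
                                           init_state=init_state)
    return {"landscape": landscape, "hydro": hydro, "survey": survey,
            "truth": truth, "species": species, "scenario": scenario,
            "focal": "PTR"}
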