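# pondshift

Analysis toolkit for **distribution–abundance (d–a) relationships in
pond-breeding amphibian metacommunities**: why are locally abundant
species also regionally widespread, and what flips a species between
*rare-and-narrow* and *common-and-widespread*?

The package is built around the analyses used for a 15-year, 37-pond
monitoring study of 13 amphibian species on the E. S. George Reserve
(Michigan), where a multiyear drought dried ponds, collapsed their
predator communities, and sent the chorus frog (*Pseudacris triseriata*)
through a full regime cycle — rare → widespread → rare. It is aimed at
quantitative ecologists who want the component analyses as tested,
reusable functions:

* **`regime_shift`** — sequential t-test regime-shift detection (STARS)
  with the signed Regime Shift Index: for a candidate year with values
  beyond the critical band `mean ± t·√(2σ²_l/l)`, RSI is the
  Huber-weighted mean of the subsequent anomalies beyond the crossed
  level, in σ_l units.
* **`da_models`** — the d–a curve suite: mean, linear, saturating
  `y = a(1−b^x)`, and one-breakpoint piecewise families; AICc ranking
  (`AIC = n·ln(RSS/n)+2K`, error variance counted in K), Akaike weights
  and evidence ratios; breakpoint search with bootstrap CIs;
  phylogenetically independent contrasts; Cook's-distance screening.
* **`availability`** — pond condition (window-max area over
  max-ever area), per-species available/habitable pond sets, constrained
  occupancy, and the category-weighted suitable-pond estimator.
* **`connectivity`** — Hanski incidence-function index
  `S_i = Σ N_j e^{−αd}` and circuit-theory effective resistance on a
  friction raster (sparse Laplacian solves).
* **`timeseries_stats`** — lagged cross-correlations (positive lag =
  first series leads) and availability-tracking diagnostics.
* **`synthetic_data`** — a mechanistic two-region metacommunity
  simulator (drought-driven predator release, density-dependent
  colonization/extinction, event-level ground truth) so every stage is
  testable without field data.
* **`pipeline` / `cli`** — one-command orchestration
  (`pondshift report --seed 0 --out results`).

## Worked example

The bundled 1996–2010 chorus frog pond-occupancy counts
(5, 6, 3, 3, 6, 21, 20, 15, 17, 17, 19, 20, 21, 21, 8):

```python
>>> from pondshift.refdata import CHORUS_FROG_OCCUPANCY
>>> from pondshift.regime_shift import stars, StarsParams
>>> res = stars(CHORUS_FROG_OCCUPANCY, StarsParams(cutoff=4, alpha=0.05))
>>> res.shift_years
[2001, 2010]
>>> res.table.loc[2001, ["rsi", "mean", "length", "confidence"]]
rsi           1.014665
mean              19.0
length               9
confidence    1.44e-08
```

Occupancy jumped from a 4.6-pond regime (1996–2000) to a 19-pond regime
(2001–2009; RSI 1.01, between-regime Welch p ≈ 1.4e−8) and collapsed to 8
ponds in 2010 (RSI −0.57, judged on the single year available at the
series end). Running `analysis/02_model_selection_and_lags.py` adds the
companion results: ln larval density shifted a year *earlier* (2000), the
cross-correlation of ln density with occupancy peaks with density leading
by one year (r = 0.61, p = 0.020), and among the candidate d–a models the
saturating curve carries Akaike weight 0.68 with the two-level step model
the only serious competitor (evidence ratio 2.3) — abundance changes
lead distribution changes across a density threshold.

The numbered scripts under `analysis/` are thin narrative drivers over
the library: `01` the regime tables and cutoff-robustness sweep, `02`
model selection and lags, `03` the synthetic drought scenario and its
no-drought null world, `04` the full pipeline report on synthetic data,
`05` circuit-theory resistance on a synthetic friction landscape. Each
writes its tables under `results/` (bulky regenerable simulation tables
go to `scratch/`).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the signed Regime Shift Index values at the
published change points of the bundled monitoring series — the 2001
occupancy boundary (cutoff 4, α = 0.05) and the 2000 and end-of-series
2010 boundaries of the ln-density series (cutoff 4, α = 0.10) — and
writes them as JSON. The computation is deterministic; `--seed` is
accepted for interface uniformity.

See `docs/methods.md` for the models, conventions, and the documented
judgement calls (and what the synthetic world does and does not emulate).
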