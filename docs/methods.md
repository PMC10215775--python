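# Methods

## Scope and model

`landcarbon` couples three models around a shared raster data core:

1. a **Markov chain** over six land classes, calibrated by
   cross-tabulating two categorical rasters, that projects per-class area
   demand;
2. a **patch-growing cellular automaton** that allocates that demand
   spatially under scenario constraints, using per-class development
   probabilities learned by an expansion-sampling random forest;
3. a **fixed-density carbon account**: each class carries a constant
   per-area carbon density in four pools (aboveground, belowground, soil,
   dead organic matter), so storage is a pure function of the class map and
   change decomposes exactly over the transfer matrix.

The central simplifying assumptions are inherited from this family of
models: densities do not vary in space or time within a class; land
conversion is the only carbon process represented; and future class totals
follow the calibrated transition frequencies. Units are fixed at km² for
areas and t/ha for densities; the single ×100 ha/km² bridge lives in
`grid_core.HA_PER_KM2`. This unit reading is itself verified by a test:
applying the shipped density table to the shipped transfer-matrix margins
reproduces the published basin-wide totals (≈1.15 × 10⁸ t in 2000,
≈1.12 × 10⁸ t in 2020) to a few parts in a thousand, which no other unit
combination does.

## Demand allocation: flows, not nets

The automaton does not chase net per-class totals. It allocates the
calibrated **flow matrix** `F = diag(areas)·P` (km² owed from each source
class to each destination), whose column sums are exactly the Markov
demand. Two reasons:

* observed change is gross, not net — in the embedded 2000→2020 matrix,
  cultivated land both lost 387 km² to construction and gained a similar
  amount from forest and grassland, a structure invisible to net targets;
* per-pair caps make demand satisfaction and constraint safety easy to
  enforce: a pair-flow stops when met, so no class overshoots, and a
  forbidden transition simply has no flow scored.

Totals-only demand is still accepted: it is decomposed into flows by
proportionally assigning each net-surplus class's excess to the
net-deficit classes.

Flow targets in km² are rounded to whole cells by largest remainder,
per source row, so the cell totals are preserved; the residual mismatch is
at most a few cells and sits well inside the demand tolerance.

## The automaton's score and its knobs

For a candidate cell of class *c* and destination *k*:

`score = P_{c,k} · Ω_{c,k} · D_k`

* `P_{c,k}` — random-forest development probability (below);
* `Ω_{c,k}` — fraction of the Moore window (default 3×3, configurable odd
  size) occupied by class *k*, centre excluded, divided by the number of
  in-grid neighbours (shrunken windows at edges), times the scenario's
  per-class neighborhood weight (0–1, the published three-scenario table);
* `D_k` — adaptive inertia, initialised at 1. If a class's remaining net
  inflow gap grew while unmet, `D_k` is multiplied by the gap ratio capped
  at 2; on overshoot it is damped symmetrically (ratio clipped to
  [0.5, 1]); otherwise unchanged. With per-pair caps the inertia only
  shapes the allocation path, never the totals.

Selection: scores must exceed a threshold τ that starts at `tau0 = 0.8`
and decays by 0.9 per iteration; among passing destinations the class is
drawn by roulette wheel (an `argmax` mode exists for debugging). Cells
with `Ω = 0` receive, with probability `p_seed = 0.01`, a uniform(0,1)
seed factor in place of Ω, so new patches can nucleate away from existing
ones. Restricted cells (e.g. water under the trend scenario) never enter
the candidate pool. Convergence: every per-class gap within
`demand_tolerance_cells = 10`; `max_iters = 200` default, after which the
best state is returned with a warning flag. All of these are `CAParams`
fields.

The scenario presets translate qualitative policy rules into multipliers:
up-weight 1.5 for favoured transitions (e.g. into forest/grassland under
ecological protection), down-weight 0.5 for discouraged ones (e.g. into
construction), prohibitions as hard zeros with row renormalisation. The
multiplier values are configurable; the defaults are deliberately mild so
the scenario ordering is driven by direction, not magnitude.

## Suitability learning

One binary random forest per class (expansion vs not, balanced 1:1 with
uniformly sampled negatives, default 100 trees, unlimited depth, fixed
seed; `n_jobs=1` for bit-reproducibility). Per-class probability surfaces
are predicted on the full grid; classes with zero expansion cells fall
back to a constant surface at their persistence frequency. Factor
contributions are impurity importances, with one-hot columns (categorical
drivers such as soil class) summed back to their source driver and each
class row normalised to 1. Because negatives are balanced, the
uninformative prediction is 0.5, not the landscape prior — a property the
tests pin down.

## Spatial statistics

Weights are sparse queen contiguity over the active fishnet cells by
default (rook and k-nearest available), row-standardised for Moran and
bivariate Moran, binary and self-inclusive for Gi*. Cells whose valid
coverage falls below `min_valid_fraction = 0.5` are dropped before weights
are built, to avoid edge-artifact hot spots. Raster cells are assigned to
fishnet cells by centre position, so the fishnet edge (default 2 000 m,
the study scale) need not be a multiple of the cell size; sums (carbon)
are conserved exactly, means (NDVI, impervious fraction) are over valid
cells only.

Moran's I uses the standard double-sum statistic; the vectorised
implementation is pinned to a literal O(n²) oracle at 1e-10 on small
lattices, and to the closed-form checkerboard value (−1 under rook
weights). Permutation inference (default 999 draws) reports both the
directional min-tail `p_sim` and the one-sided `p_greater`, the latter
exactly discrete-uniform under exchangeability — which the test suite
verifies by a KS test over 500 null replicates. Gi* uses the analytic
z-score with fixed class thresholds (±1.65/1.96/2.58) and no FDR by
default. Bivariate local values are `z_x · lag(z_y)` with conditional
permutation of *y*; cluster labels HH/LL/HL/LH are assigned where
p ≤ 0.05.

## Spectral indices

MNDWI = (green − swir1)/(green + swir1) masks water and snow (threshold
default 0); ENDISI = [(2·blue + swir2)/2 − (nir + red + swir1)] over the
matching sum extracts impervious surface (threshold default 0, with an
optional Otsu split). Both are undefined (NaN) at zero denominators and
invariant to uniform band scaling. Accuracy assessment samples 700 points
without replacement, mirroring the study's verification design, and scores
OA and unweighted Cohen's kappa; kappa is computed from the confusion
matrix directly and cross-checked against scikit-learn in the tests.

## Synthetic study areas

The generators exist so every stage has ground truth:

* **Landscapes** — per-class Gaussian-smoothed noise fields with an
  additive bias iterated to hit target class proportions, argmax
  assignment. Autocorrelation length 0 gives an i.i.d. map (verified by
  join counts); the default benchmark uses length 6 cells.
* **Markov transitions** — independent per-cell sampling from P*, with an
  optional multiplicative adjacency boost `(1 + s·f_j)` toward classes
  already present among the 8 neighbours; returns an exact per-transition
  ledger that must equal the cross-tabulation cell for cell.
* **Competitive expansion** — for each directed flow i→k, the N
  highest-scoring class-i cells convert, scored by adjacency + a
  standardised driver-affinity surface + noise. This emulates expansion
  processes (urban growth along development gradients) where change is
  predictable from observables.
* **Drivers** — per-class means + smooth field + white noise, so class
  membership is recoverable with controllable strength.
* **Reflectance** — per-class six-band means (built surfaces bright in
  blue/swir2, vegetation in nir, water green > swir1) + Gaussian noise.

The default benchmark is a 256×256 grid of 30 m cells whose class shares
and transition rates are taken from the embedded 2000→2020 matrix — a
desk-scale landscape shaped like the study area. Analysis runs scale the
fishnet edge to 480 m to keep a study-proportionate number of cells over
the 7.7 km extent.

**What the benchmark does not show.** The generators have no topography,
climate gradients, road networks or multi-scale patch hierarchy; driver
signal strength is set by construction. Passing recovery tests therefore
demonstrates that the estimators and the allocator are correct and
calibrated, not that they would reach any particular accuracy on real
imagery. Published real-data figures that depend on the original rasters
(the 2010 and 2030 carbon totals, the hindcast kappa of 0.8638, Moran's I
around 0.56–0.59, the bivariate values −0.379/0.450, the printed factor
contributions) are targets for qualitative and property-level
reproduction only.

## The simulate-then-validate benchmark

The study validated its simulator by hindcasting the latest map from the
earlier one and scoring agreement. The package's reproducible analogue
demands more: the simulated map must beat the **persistence null** (the
earlier map itself) on Cohen's kappa. Under independent per-cell Markov
sampling, realised change locations are an unpredictable thinning —
no allocator can beat persistence in that regime, and the package does
not pretend to. The validation benchmark therefore uses the competitive
expansion generator with the *directional* version of the study's flow
matrix (the smaller of each opposing flow pair folded into persistence —
the expansion processes the learning stage actually models). On that
benchmark the learned-suitability CA places a majority of conversions
correctly and exceeds the persistence kappa across seeds, with demand gaps
within tolerance and exact seed determinism.

## Numerical and design choices

* Empty Markov rows become identity rows (absent classes cannot
  transition).
* The transfer-matrix CSV import validates the printed Total row/column
  against the cells at 0.011 km² (printed-precision slack).
* The 20-year calibration matrix is the only published one; demands for
  other horizons use `n_steps` of that period, and multi-step flows use
  `diag(a)·Pⁿ`. The study's own future demand used an unpublished
  2010–2020 matrix, so exact future totals are not reproducible by design.
* Mapped-total consistency checks allow a few cells of rounding slack;
  area accounting is otherwise exact.
* Kappa is unweighted Cohen's kappa on all jointly valid cells.
* Fishnet ids are reading-order; the raster origin is the NW corner.
* All stage randomness derives from one top-level seed through named
  substreams (`pipeline.substream`), making pipeline reports byte-stable
  under a fixed seed.

## Problem sizes

Test and acceptance runs use 512² for Markov recovery, 256² for the CA
benchmark and pipeline, 128² for scene extraction and most unit
fixtures — sizes at which every recovery property is comfortably
measurable on a single CPU.

## Known limitations

Fixed carbon densities (no interannual dynamics or spatial heterogeneity
within a class); no reprojection/resampling (same-grid stacks only,
mismatches are errors); no figure-of-merit or multi-resolution map
validation; no auto-tuning of neighborhood weights; scenario multipliers
are stylised stand-ins for unpublished conversion-cost settings; the
GeoTIFF writer stores grid metadata in an ImageDescription tag rather
than full geo-referencing.
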