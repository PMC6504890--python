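# Methods

## The licensing/transition model

A cell is a sequence of states S(tₖ) ∈ {nonresolved, resolved, compacted} on
a uniform grid tₖ from −140 to 90 min in 1-min steps (231 points), with
t = 0 at nuclear envelope breakdown (NEBD). Two latent licensing times gate
the transitions:

* t¹ = −X₁, X₁ ~ Exponential(mean τ₁): resolution becomes possible at or
  before NEBD;
* t² = t¹ + X₂, X₂ ~ Exponential(mean τ₂): compaction becomes possible a
  random delay after licensing 1.

From the first grid point with tₖ ≥ t¹ the cell attempts the
nonresolved → resolved transition each step with probability
p₁ = 1 − e^(−r₁Δt); once resolved *and* tₖ ≥ t², it attempts
resolved → compacted with p₂ = 1 − e^(−r₂Δt). Compaction is absorbing and
can never precede resolution, even when licensing 2 fires first. A
successful draw takes effect from the **following** grid point by default;
an `effect="current"` flag applies it at the draw's own step (at 1-min
resolution the difference is below the data's resolution, but it is pinned
for reproducibility).

Because the per-step Bernoulli chain is memoryless, the first success is
geometric; the simulator draws it directly by inverse CDF, so each cell
consumes exactly four uniforms (two exponential licensing draws, two
geometric first-success draws). This makes single-cell behaviour fully
deterministic under a stubbed uniform stream, and lets the population
simulation evaluate 10,000 cells in well under a millisecond from an
(m × 4) uniform block — cell i uses row i, so the population path and the
single-cell path agree bit for bit. Degenerate rates are exact: r = 0 gives
p = 0 (the transition never fires); huge r saturates at p = 1.

Reported summaries: ST = τ₁·ln2 and TD = τ₂·ln2 (median licensing times),
rate half-lives ln2/r (infinite at r = 0) and per-step probabilities
1 − e^(−rΔt). For τ₁ = 18.0 min, r₁ = 0.065 min⁻¹: ST = 12.5 min, half-life
10.7 min, per-minute probability 0.063.

**Validation.** With compaction off, P(nonresolved; tₖ) has a semi-analytic
form: the licensing density integrates over grid intervals
(w_j = e^{t_j/τ₁} − e^{t_{j−1}/τ₁}, t ≤ 0) and each elapsed step multiplies
a (1−p₁) survival factor. The Monte-Carlo simulator at m = 200,000 agrees
with this independent oracle within 3 binomial standard errors at every
grid point (tested, and recomputed by the acceptance script).

## Fitting

The objective is Σₜ Σₓ (P_model(x;t) − P_obs(x;t))² over observed time
points in t ∈ [−50, +30] min and the three model states. Observed brown
("partially resolved") counts merge into nonresolved before comparison — the
fitted model folds partial resolution into the nonresolved state. Black
("nonresolved and compacted") and undetermined calls are excluded from the
denominator by default (the model has no such states); a
`black_as_nonresolved` flag maps black to nonresolved instead. Time points
are equally weighted regardless of cell count (a count-weighted option
exists but is off by default). Fitting always uses the raw, unsmoothed
proportions.

Numerical choices:

* **Common random numbers.** One fixed simulation seed (`crn_seed`) is
  reused across all objective evaluations of a fit, making the stochastic
  objective a deterministic function of the parameters.
* **Log-parameter transform.** (τ₁, τ₂, r₁, r₂) are optimized on the log
  scale, enforcing positivity without constraints.
* **Wide finite differences.** The CRN surface is piecewise constant at fine
  scales (integer geometric outcomes), so the quasi-Newton optimizer
  (L-BFGS-B by default; Nelder-Mead available) uses a finite-difference step
  of 0.05 on the log scale (~5% relative). At that step the surface's
  macroscopic slope dominates the Monte-Carlo staircase. Dispersed starts
  reach objectives within a few percent of each other on data at the study's
  noise level.
* **Penalty contract.** Non-finite parameter proposals or simulation output
  score a large finite constant (10⁶) and are logged, never raised.

**Bootstrap.** Uncertainty follows the study design: resample the in-window
time points with replacement (as many as observed), refit, repeat B times
(default 300), summarize each parameter by its median and a box plot with
1.5·IQR whiskers. Quartiles use linear interpolation (type 7), pinned
because box statistics are part of reported output. Two caveats are
deliberate and documented: (i) refits start from the configured initial
parameters, not the full-data optimum — a refit started at an optimum of
the piecewise-constant surface stalls immediately and the spread collapses;
(ii) resampling *time points* cannot see cohort-level noise (all time
points share the same cells), so bootstrap IQRs quantify within-cohort
uncertainty only and are much tighter than the cohort-to-cohort spread of
the estimates. Degenerate resamples that collapse onto a single time point
are skipped and logged.

## Dot-configuration classification

Inputs are per-minute 3D centroids (µm) for the two channels, 0–2 per
channel, plus a per-cell NEBD time. z plane indices are converted to µm as
`z_index × 0.75 µm × 0.85`; the 0.85 factor compensates the oil/water
refractive-index mismatch (~0.64 µm effective spacing) and is applied
uniformly before any distance computation.

Per time point: a channel with no centroid makes the call *undetermined*. A
channel is *separated* if it shows a doublet with center distance strictly
above the 0.85-µm sister-separation threshold; a doublet at or below the
threshold is treated as a single object (equality counts as nonresolved —
the source rules use strict inequalities and leave the boundary undefined).
One separated channel → *brown*, labelled with that channel; none → *blue*;
both → *pink* or *red* depending on colocalization of the tetO–lacO pairs
under the minimal-total-distance assignment (the two possible 2×2 pairings
are compared). "Colocalization" is operationalized as centroid distance ≤ a
0.4-µm radius — a configurable proxy for the original volumetric ">50%
overlap" criterion, which centroid data cannot measure. After NEBD, runs of
≥5 consecutive time points in which *every* pairwise centroid distance is
within the colocalization radius are relabelled *black*; shorter runs keep
their per-timepoint call, and the pre-NEBD part of a straddling run is
never relabelled. Note that an all-mutually-colocalized time point
necessarily fails the sister-separation test, so its base call is blue-like,
not red.

Proportion curves count classified states only; undetermined calls never
enter denominators. The per-time-point cell count is carried alongside so
callers can apply the <10-cell display mask; it is metadata, never silently
dropped. Optional smoothing is a centered rolling mean over an odd window
(9 min for display), shrinking at the edges; it preserves the unit sum of
proportions, and the raw series is always retained.

Phases (for per-phase summaries and chi-square comparisons): prophase = the
20 min before NEBD; late G2 = the 120 min before prophase; early G2 = the
first 90 min after the end of S; late S = the last 30 min of S. Condition ×
state count tables are compared with Pearson's chi-square test without
continuity correction. The separation-asymmetry statistic is the fraction of
brown time points in a phase whose separated channel is tetO vs lacO.

## Synthetic cohorts

The generator emulates the statistical structure of the live-imaging data;
it renders centroids, not images.

* **States.** Each cell's three-state trajectory comes from the model above
  at the wild-type parameters τ₁ = 18.0 min, τ₂ = 9.3 min, r₁ = 0.065 min⁻¹.
  No r₂ value is reported for wild type, so r₂ = 0.12 min⁻¹ is a package
  assumption, chosen to put the compaction half-life (5.8 min) in the same
  range as the other kinetic scales.
* **Brown episodes.** A continuous-time alternating renewal overlay: while
  a cell is nonresolved and within 120 min of NEBD, episodes start at rate
  0.125 min⁻¹ and last Exponential(2 min), giving a stationary occupancy of
  λµ/(1+λµ) = 0.20 of eligible time — about 20% of late-G2 time points, with
  episodes lasting a few minutes. The process starts at stationarity so the
  closed-form occupancy is exact from the first minute. Each episode's
  separated channel is tetO with probability 0.8. Calibration tolerances
  count episodes (the independent unit), not time points.
* **Geometry.** Distances are drawn from truncated log-normal bands kept a
  margin away from the classifier thresholds (nonresolved sisters
  0.20–0.60 µm; separated sisters 1.10–1.60 µm; colocalized pairs
  0.02–0.12 µm; non-colocalized pairs 0.65–1.00 µm), so noiseless renderings
  classify back to the truth exactly, and with 0.05-µm isotropic centroid
  noise at least 99% of time points still agree. In resolved/compacted
  states the lacO offsets are perpendicular to the sister-separation axis so
  sister–sister distances never dip below the unit separation.
* **Imperfections.** Undetermined time points at rate 0.05 (one channel
  loses its dots); NEBD times jittered in absolute time only (relative
  alignment stays exact — observed NEBD is treated as error-free);
  per-cell observation spans (30% of cells reach each grid end, the rest
  enter/leave uniformly) give per-time-point counts of roughly 10–50 that
  peak near NEBD, mean ≈ 31, matching the study's per-time-point range.
* **z axis.** Coordinates are emitted as already-corrected µm (`z_um`);
  discrete z-plane quantization is not modelled — with it, the noiseless
  round trip could not be exact.

What passing these tests shows — and does not. The pipeline recovers its
own generating process at realistic cohort sizes and noise; it does not
demonstrate robustness to spot-detection failures, chromatic offsets,
z-anisotropic localization error, or mis-identified NEBD frames, none of
which the generator emulates.

## Scale of the shipped analyses

Single-cohort estimates at the study scale (~50 cells, ~30 per time point)
carry inherent sampling spread — roughly 13% SD for τ₁ and 25% for r₁
across generator seeds — dominated by the τ₁–r₁ trade-off in the
nonresolved decay. The acceptance computation therefore reports the median
over three independent cohorts for parameter recovery, and the
two-condition comparison (wild type vs a condensin-II-depletion-like
parameter set: ST reduced by 5.5 min, r₁ reduced by 40%) uses one cohort
and one B = 50 bootstrap per condition, as in the study design scaled from
B = 300. Bootstrap sizes of 300 remain the library default.

## Known limitations

* The colocalization proxy (centroid distance) is not the original
  volumetric overlap criterion; the radius (0.4 µm) is configurable but has
  no ground-truth calibration.
* Time-point bootstrap understates total uncertainty (see above); cohort
  resampling would capture cell-level noise but is not part of the study
  design this package reproduces.
* The model folds the brown state into nonresolved; episode kinetics are
  generated but not fitted.
* Anaphase, FISH two-probe scoring, spot detection and chromosome-volume
  tracking are out of scope; end-of-S and NEBD times are inputs.
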