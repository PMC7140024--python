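# Methods

## Falling-head permeametry

### Model and assumptions

The permeameter confines a cylindrical tissue specimen (diameter 3 mm,
thickness Δx = 2 mm by default) between porous plates below a vertical pipette
(internal diameter 6 mm) filled to an initial height H(t₀) = 210 mm. Flow
through the specimen is assumed to obey Darcy's law with a constant
permeability coefficient K,

Q = K·A_s·γ·H(t)/Δx,

and continuity between pipette and specimen (A_p·dH/dt = −Q) gives the
closed-form exponential decay

H(t) = H(t₀)·exp[−λ(t−t₀)],  λ = K·(A_s/A_p)·(γ/Δx).

Assumptions: rigid specimen (no compaction, constant Δx), constant K over the
pressure range traversed, negligible plate resistance, quasi-static flow. The
specific weight of the permeating fluid defaults to water at lab temperature,
γ = 9.81×10⁻⁶ N/mm³ (9.81 kN/m³); this value reproduces the device's
documented pressure-gradient window of 1.03–0.49 kPa/mm across 210–100 mm
exactly, and is configurable because the fluid (water/PBS/medium) and
temperature may differ between labs. All internal units are mm, N, s; K is
reported in mm⁴/(N·s) with SI converters available.

### Estimation

Observations are restricted to the closed analysis window [100, 210] mm.
The estimate minimises the mean squared relative residual
I(K) = (1/N)·Σ[1 − H(tᵢ;K)/Hᵢ]². Relative residuals weight all heights in the
window comparably and match a constant-relative-precision reading error.

The decay origin t₀ is the first observation time of the trace *as given*,
before windowing. This matters: with multiplicative noise, the true first
reading (at exactly 210 mm) falls outside the closed window roughly half the
time; anchoring t₀ on the first *in-window* point would then misplace the
model origin and bias K upward by a few percent — an order of magnitude above
the estimator's intrinsic error at 1 % noise (~0.2 % median).

Because K is the single unknown and the objective is smooth and unimodal in
practice, the fit is a bounded scalar search on [0, 100·K_init] (Brent,
relative tolerance 10⁻¹⁰), initialised from the OLS slope of ln H on t. A
non-positive initial rate (flat or rising trace — plausible for
near-impermeable fresh tissue plus jitter) short-circuits to K = 0 with a
warning record rather than an error. Traces need ≥ 3 in-window points.

With repeats, a sample's K is the mean of repeat-level fits; the reliability
summary reports per-sample CV over repeats (the 5-repeat × 8-sample
reference-material protocol) and across-sample dispersion. Group comparisons
use Mann–Whitney by default (permeability distributions are skewed; medians
are reported alongside).

## Dose–response and IC50

Raw signals are treated as an arbitrary monotone viability proxy (plate
readers differ in absorbance vs fluorescence readout). Normalisation divides
each treated well by the mean untreated signal of its (cell line, setting,
drug, timepoint) stratum, ×100, so untreated ≡ 100 %.

The fit is the inhibitory four-parameter logistic on log₁₀ concentration with
slope constrained positive, top initialised (not fixed) at 100 and bottom
bounded in [0, 150] — fixing the top is avoided so incomplete kill and control
drift remain representable, at a known cost in variance (below). Well-level
points are fitted, never replicate means, preserving the error structure. A
three-point multistart over the midpoint guards against edge local minima on
sparse grids. The default analysis timepoint is 72 h; 24/48 h stay available
in tables. Fixed-ratio drug cocktails (e.g. 5FU:leucovorin:irinotecan 25:5:1)
are indexed by the concentration of their principal component so combination
IC50s are commensurate with single-agent values.

**Identifiability on the 4-point decade grid.** The standard screening design
({0.1, 1, 10, 100} µM, triplicates) with ~5-percentage-point well noise is
information-poor for a free-plateau logistic: a Cramér–Rao computation for the
four-free-parameter model puts the per-dataset median relative IC50 error near
26 %, and even with both plateaus fixed the realized least-squares error is
~12 %. The box-constrained fit used here achieves ~18 % median error over
truths spanning IC50 ∈ [0.3, 30] µM and slope ∈ [0.5, 3] — better than the
unbiased free-plateau bound, but users wanting tighter IC50s should add
concentrations near the expected midpoint rather than expect a better
estimator to exist. Single-condition fold changes inherit this variance
(roughly ±40 % on a triplicate plate pair); the recovery tests assert the
levels actually attainable under this design.

## Quantification and cohort filters

Marker percentages are per-image (100·positive/total nuclei) summarised as
mean ± SD across images — the dispersion is deliberately labelled SD, since
"±" in figure captions is often ambiguous. Co-localization uses the same
arithmetic over counted cells. Image segmentation is upstream and out of
scope: the module starts at count tables.

Cohort rules: embryos with cells_at_2h < 100 are excluded ("< 100" read
strictly, so exactly 100 is retained); the 72 h timepoint is dropped for the
whole analysis when the fraction of untreated (DMSO-arm) embryos retaining
cells at 72 h is below 50 % — no embryos are removed by this second rule.
Retention is taken from an explicit flag column when present, otherwise
derived as a positive 72 h fluorescence reading. The exclusion log lists every
removed embryo with the rule that removed it, so retained + logged = input
always. Filtering is idempotent. Fold changes are per-embryo,
signal(t)/signal(0), requiring a positive baseline.

## Reporting statistics

Parametric vs nonparametric is always an explicit caller flag — never
auto-detected from normality tests, which would make the analysis path
data-dependent and hard to pre-register. Student's t is the parametric default
(Welch available as a toggle). Mann–Whitney uses the exact U distribution when
both groups have n ≤ 8 and the pooled data are tie-free; with ties the exact
distribution is invalid, so the tie-corrected normal approximation is used
regardless of n. Multi-group: one-way ANOVA with Bonferroni-corrected pairwise
t tests, or Kruskal–Wallis with Dunn's post-hoc — pairwise z statistics on
joint mid-ranks with the tie-corrected null variance N(N+1)/12 − Σ(t³−t)/(12(N−1))
and Bonferroni family correction (written in-package; no maintained
implementation of Dunn's test ships with scipy/statsmodels). Stars: \*\*\* for
p < 0.001, \*\* for p < 0.01, \* for p < 0.05, strict inequalities, ns
otherwise.

## Synthetic data: what it emulates, and what it does not

Generators are seed-deterministic (one `numpy.random.Generator` per call) and
emit exactly the CSV schemas the readers accept.

* **Filtration traces** sample the closed-form decay uniformly in time over
  the full 210→100 mm descent and apply multiplicative Gaussian noise
  (default sd 1 %), modelling constant relative reading precision on a
  graduated pipette. Not modelled: meniscus effects, specimen compaction,
  temperature drift, operator-paced (non-uniform) sampling.
* **Grouped permeabilities** draw K log-normally per tissue group with
  default medians 50 / 500 / 5000 mm⁴/(N·s) (fresh < recellularized-3DT <
  decellularized) and ln-scale sd 0.5, n = 8 per group. The medians are
  synthetic scale anchors — chosen so a simulated descent completes in minutes
  of simulated time and the groups order reliably — not instrument readings.
* **Plates** put Hill-curve viability plus additive 5-pp noise on the
  {0.1, 1, 10, 100} µM grid with triplicates and noisy untreated controls.
  Edge effects, evaporation gradients and signal saturation are not modelled.
* **Count tables** are binomial per image (default 400 nuclei, 10 images).
  Spatial correlation within sections is not modelled, so real between-image
  SDs will exceed binomial SDs.
* **Embryo cohorts** draw cells at 2 h ~ Poisson(200) (at that mean the
  <100-cell filter removes <1 % — the filter only bites when injection
  efficiency drops), per-arm Bernoulli retention at 72 h (default untreated
  retention 0.45, mirroring the regime where the 72 h timepoint is dropped),
  and log-normal multiplicative fluorescence decline per 24 h (defaults:
  control 0.95, 2D-dose 0.93 — a dose too weak to act in vivo,
  indistinguishable from control — 3D-dose 0.4). Arm effects are parameters,
  not hard-coded outcomes.

Passing tests on this synthetic data demonstrates estimator correctness and
calibration under the stated noise models — not robustness to the systematic
artifacts listed above, which real instruments add.

## Numerical choices and degenerate inputs

* Analysis window boundaries are closed (heights exactly 100 or 210 mm are
  kept).
* A predicted log-decay below 10⁻¹² over a trace's span is treated as zero
  permeability (guards against ±1e-17 polyfit slopes on constant traces).
* 4PL fits report `converged=False` rather than raising when the optimizer
  stalls or bottom > top; flat responses and <3 distinct positive
  concentrations raise typed errors.
* Bonferroni is min(1, m·p); post-hoc p-values never undercut raw ones.
* The pipeline is deterministic given config + inputs; `summary.json` reruns
  byte-identically, and the run manifest records input hashes, config and
  seed.

## Problem sizes used in the checks

Recovery and calibration checks use 200 simulated traces (50 points each),
the 5×8 reliability protocol with a 1000-replicate sampling oracle, 200
scenario runs for the group-significance rate, 100 plates for IC50 recovery,
and 1000 null replicates for the t-test's type-I error — sizes at which the
binomial uncertainty on the checked rates is well inside the asserted bands.

## Known limitations

* K is a lumped Darcy coefficient; no uncertainty interval beyond repeat-level
  dispersion is produced (a profile-likelihood interval would be a natural
  extension).
* The IC50 design limitation above: on 4-point decade grids, fold-change
  estimates from single plate pairs carry ~tens-of-percent uncertainty.
* The caudal-region boundary for fluorescence integration is taken as given;
  inputs must be already-integrated signals.
* Statistical tests assume independent observations; repeated images from one
  scaffold section violate this and will understate p-values.
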