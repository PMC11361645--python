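# Methods

## Observation models

**Association.** Mixing nucleotide-free GTPase at concentration `c`
(µM) with a fluorescent nucleotide analog at 0.2 µM produces a
fluorescence rise `F(t) = F0 + A(1 − e^(−k_obs t))` with
`k_obs = k_on·c + k_off`. The pseudo-first-order approximation requires
the protein in excess over the reporter; the generators and fitters
enforce `c ≥ 5 × reporter`. Running a ladder of protein concentrations
(default {1, 2, 4, 6, 8, 10} µM, configurable) and regressing `k_obs`
on `c` by ordinary least squares gives `k_on` as the slope. The
intercept is left free rather than pinned to the independently measured
`k_off`: theory predicts intercept ≈ `k_off`, so a free intercept both
avoids biasing the slope when that prediction is imperfect and yields a
consistency check for free.

**Dissociation.** A chase with a 200-fold molar excess of unlabeled
nucleotide makes reporter rebinding negligible, so the decay is a
single exponential `F(t) = F∞ + A·e^(−k_off t)` with half-life
`ln2/k_off`.

**Hydrolysis.** Intrinsic hydrolysis of protein-bound GTP is modeled as
one first-order process, `f_GTP(t) = e^(−k_cat t)`, ignoring nucleotide
re-exchange during the assay — appropriate because the assay reports a
single observed rate constant per condition. Default sampling: six
points spanning three half-lives, matching the experimental design.

**Noise.** Trace noise is additive Gaussian with sd equal to a fraction
of the amplitude (default 1%); instrument noise figures are not
published, and 1% makes parameter recovery nontrivial but stable.
Hydrolysis fractions get absolute Gaussian noise (default sd 0.02) and
are clipped to [0, 1]. Default trace duration is `5/rate` (≥ 99% of the
amplitude developed) with 500 uniform samples; no acquisition rate is
published, and denser sampling only sharpens the fits.

## Fitting

Nonlinear fits use trust-region least squares (`scipy.optimize.curve_fit`,
`method="trf"`) with the rate bounded positive. Initialization: offset
from the first (association) or last (dissociation) decile of samples,
amplitude from the signal range, rate from the time at which the
decaying component halves. Standard errors come from the covariance of
the objective at the optimum. Degenerate inputs (flat signal, zero
rate) return `converged=False` with best-effort numbers instead of
raising; a trace whose trend contradicts the requested model (falling
signal fed to the association fit, or vice versa) raises a
mode-mismatch error. On noiseless generator output every fit recovers
its generating parameter to ≤ 1e-6 relative error (tested), and the
OLS line agrees with the closed-form normal equations to 1e-10
(tested against an independent brute-force oracle).

`K_d = k_off/k_on` (µM). "No binding observed" (T30N with mGppNHp) is
represented as an absent `k_on` with a machine-readable reason code,
never as zero, and forces an absent `K_d`.

### Kinetics table and fold-changes

`build_kinetics_table` emits per-variant `k_on`, `k_off`, `K_d`,
`k_cat` plus a fold-change block in which every ratio is a quotient of
table entries. One subtlety: the `Kd_uM` column is recomputed from the
rate columns, but when rates are transcribed from a publication they
are rounded to 2–3 significant figures, and a ratio of two re-derived
`K_d` values compounds four roundings. The packaged data therefore also
carries the affinities as originally reported (`Kd_reported_uM`,
computed by the source from unrounded rates), and K_d ratios prefer
that column when both operands are present. For the wild type the two
routes differ visibly (GDP/GppNHp affinity ratio 9.2 reported vs 7.9
from rounded rates); all other packaged ratios agree within a few
percent.

## Three-state cycle model

States: nucleotide-free (F), GDP-bound (D), GTP-bound (T), with
clamped nucleotide pools (protein ≪ nucleotide, no depletion; defaults
500 µM GTP, 50 µM GDP ≈ the 10:1 cellular ratio, configurable).
Hydrolysis routes T directly to D (product GDP stays bound), the
standard single-turnover scheme. The steady state is closed-form:

    T/F = k_on_GTP·[GTP] / (k_off_GTP + k_cat)
    D/F = (k_on_GDP·[GDP] + k_cat·(T/F)) / k_off_GDP

normalized to sum 1. Degenerate limits are handled explicitly: an
absorbing D state (`k_off_GDP = 0` with any influx) gives `f_GDP = 1`;
an absorbing T state gives `f_GTP = 1`. Note that for `k_cat > 0` the
large-[GTP] limit of `f_GTP` is not 1 but `r1/(1+r1)` with
`r1 = k_off_GDP/k_cat`, because hydrolysis keeps recycling T into D —
8/9 ≈ 0.889 for wild-type constants.

`integrate_cycle` is a numerical oracle, not the implementation: it
integrates the same linear system with an implicit Radau method
(rtol 1e-10, atol 1e-12, analytic Jacobian) and is checked against the
closed form to 1e-6 over randomized parameter sweeps (rates log-uniform
in [1e-4, 1]).

**Classification.** The verbal criterion "accumulates GTP-loaded" is
operationalized as: label `non_classical_GTP_loaded` iff
`r1 = k_off_GDP/k_cat ≥ 5` *and* steady-state `f_GTP > 0.5`, else
`classical`. Both thresholds are package definitions (configurable);
`k_cat = 0` makes r1 undefined and forces the non-classical label with
a reason code. Wild-type TTN5 constants give r1 = 8.0 and
f_GTP = 0.86 → non-classical; a slow-exchange comparator
(`k_off_GDP = 1e-5 s⁻¹`) lands classical with f_GDP ≈ 0.99.

## Colocalization

Pearson is the product-moment correlation over (optionally masked)
pixels; overlap is `Σab/√(Σa²Σb²)`. Object-based analysis thresholds at
`mean + 2·sd` (relative threshold and the 4-px minimum object area both
configurable — the reference plugin's exact settings are not
published), labels by 8-connectivity, and takes intensity-weighted
centroids. Matching is greedy one-to-one by increasing centroid
distance with a 3 px default tolerance (no tolerance value is published
for the distance-based method); greedy matching is deterministic and
mirrors common plugin behavior, at the cost of occasionally differing
from optimal assignment in dense scenes. Percentages are reported in
both directions (A-in-B and B-in-A), mirroring the YFP/mCherry and
mCherry/YFP convention.

Published coefficients for the original micrographs (Pearson 0.63–0.78,
object overlaps 15–75%) depend on image data that is not distributed
and are context only; the package's imaging claims are validated on
synthetic ground truth instead.

## Synthetic data: what it does and does not emulate

Generators are pure functions of their arguments including the seed.
Image pairs place `round(f·n)` shared spot centers (sub-pixel jitter
≤ 0.5 px) and keep all other centers ≥ `min_separation` (default 10 px)
from the other channel, so a 3 px matcher recovers the true fraction
exactly on clean images; spots are isotropic Gaussians (σ = 2 px) of
equal amplitude on optional Gaussian background. Real data differ in
ways the fixtures deliberately omit: photobleaching and instrument
dead time in traces; nucleotide re-exchange during hydrolysis assays;
and in images, variable spot brightness and shape, structured
background, chromatic shift and dense clustering. Passing tests
therefore demonstrate correctness of the estimators under their stated
models, not robustness to every experimental artifact.

## Problem sizes

Defaults used by the test suite and the acceptance script: 500-sample
traces, 6-concentration ladders, 6-point hydrolysis courses, 20
replicate seeds per stochastic estimate, 100 random draws for the
ODE-vs-closed-form sweep, 256×256 images with 20 objects. These sizes
give stable medians while keeping a full run in well under a minute.

## Known limitations

- Single-exponential fits only; no multi-exponential or global
  (shared-parameter) fitting, no GEF/GAP-stimulated kinetics, no
  dead-time correction.
- The cycle model assumes clamped pools and dilute protein; it cannot
  describe nucleotide depletion or protein-concentration effects.
- Two dissociation rates were reported for T30N–mGppNHp in different
  contexts (0.026 and 0.004 s⁻¹); the packaged table uses 0.004 and
  stores 0.026 as `k_off_alternate` without adjudicating.
- TIFF output is 16-bit scaled by default, which quantizes intensities;
  use `dtype="float32"` for lossless round-trips.
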