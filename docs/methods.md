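# Methods

## The measurement model

The Amide III absorption band of gingival crevicular fluid (GCF), roughly
1330–1185 cm⁻¹, is a superposition of sub-bands associated with protein
secondary-structure elements. The package models the baseline-corrected band
as a sum of twelve Gaussian components

    A(ν) = Σₖ aₖ · N(ν; cₖ, σₖ²),   σₖ = wₖ / (2√(2 ln 2)),

where aₖ is the integral intensity (area), cₖ the center and wₖ the FWHM of
component k. Each component is pinned to a narrow literature window and
carries a fixed class assignment: components I–V β-sheet, VI–VII random
coil, VIII–IX β-turn, X–XII α-helix. The component count is fixed at twelve
for every sample, so fitted shares are comparable across samples; areas may
reach zero but components are never dropped.

The quantity carried downstream is the relative content
rₖ = 100·aₖ/Σⱼaⱼ, which is invariant to overall intensity scaling and hence
robust to portion-to-portion intensity variation.

## Pre-treatment

1. **Smoothing** — Savitzky–Golay local polynomial, order 2, window 25
   points. Boundary windows are fitted on the truncated support (no
   reflection), so band cropping and smoothing commute away from the edges.
2. **Baseline** — asymmetric least squares: the baseline z minimizes
   Σ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²z)² with wᵢ = p for points above the baseline and
   1−p below. Defaults: p = 0.001, λ = 10⁶ (suitable for cm⁻¹-gridded FTIR;
   exposed in configuration, and the area-preservation checks pass for
   λ ∈ [10⁵, 10⁷] on band-sized phantoms). The iteration stops when the
   asymmetric weights stabilize — fewer than a 0.01 fraction of points
   switch sides of the baseline between iterations. A norm-based
   relative-change criterion was rejected: it is dominated by the large
   smooth part of the trace and can halt the iteration before the weights
   have begun to discriminate peak from baseline.
3. **Cropping** — restriction to 1185–1330 cm⁻¹.

## Deconvolution

**Initialization.** Candidate peak positions are local minima of the
Savitzky–Golay-smoothed second derivative, confirmed by a local maximum of
the fourth derivative within 2 cm⁻¹. Each library component takes the
candidate nearest its window midpoint within the window extended by
2 cm⁻¹ of slack; otherwise it falls back to the window midpoint, so twelve
initializations always exist. The slack matters in practice: fitted centers
published for real GCF samples can sit a fraction of a cm⁻¹ outside the
nominal literature windows, and a slack equal to the center box keeps such
components recoverable. Initial FWHM is the midpoint of the FWHM box.
Initial areas start from local height × FWHM and are then refined by one
non-negative least-squares solve with the initial shapes held fixed;
without this linear refinement the overlap between neighbours inflates the
height-based guesses and the constrained fit can stall in a local minimum.

**Fitting.** All 36 parameters are optimized by bounded least squares
(trust-region reflective, analytic Jacobian) with centers boxed ±2 cm⁻¹
around their *initialized* positions, FWHM inside [7, 19] cm⁻¹ and areas
non-negative. The default FWHM box is wider than the strict 7–10 cm⁻¹
preset (`FitConstraints.strict()`) because observed Amide III component
widths reach ~18 cm⁻¹; the strict preset is retained for sensitivity
analyses. After convergence the boxes are re-centered on the fitted
parameters and the fit re-run while the cost improves by more than 1%
(at most 4 rounds). This polish lets components whose true position sits at
the edge of the first box settle exactly; at the noise floor the relative
improvement gate stops it immediately, so noisy fits are not dragged along
the ill-conditioned valley. Fit quality is the reduced criterion
χ² = RSS/(N−36) with unit weights.

**Portion protocol.** For repeated portions of one sample the preliminary
derivative analysis runs once, on the smoothed portion-average spectrum,
and every portion is fitted from that shared anchor with the polish loop
disabled. Anchoring all portions to one preliminary estimate makes the
across-portion scatter of the shares reflect measurement noise rather than
re-initialization jitter.

**Identifiability.** Neighbouring components are separated by 8–12 cm⁻¹ at
FWHM 10–18 cm⁻¹, so the unconstrained 36-parameter problem is severely
ill-posed. A linearized (Cramér–Rao) analysis at the reference parameters
shows that with additive noise at 1% of the band maximum the standard
deviation of some relative shares — most extremely the exchange between the
two random-coil components VI and VII — is unbounded for practical
purposes (10³–10⁴ share points): the data alone do not determine that
split. The box constraints around the derivative-initialized centers bound
the error to a few share points, but the residual allocation error is
noise-driven *bias* along a flat χ² valley, which portion averaging does
not remove. Consequences: noiseless reconstructions are recovered exactly
(the global minimum is the truth and the boxes contain it), while under 1%
noise portion-mean shares for the most overlapped components can deviate
from truth by more than their across-portion scatter. Reported
per-component scatter below ~0.3 share points should not be read as
absolute accuracy of the decomposition; only the constrained protocol, held
fixed across samples, makes shares comparable.

## Stage-1 screening

The spectral matrix holds one row per sample (portion-averaged by default)
and one column per retained wavenumber. PCA is computed by SVD of the
centered matrix, by default standardized to unit column variance
(correlation-matrix PCA, the convention under which the Kaiser criterion —
retain eigenvalues > 1 — applies). Retention is Kaiser tie-broken by the
scree elbow, located at the maximum second difference of the explained-%
profile.

Per (component, factor) association follows the conventions of the R
multivariate ecosystem: one-way ANOVA of the scores (F, R² = SS_between /
SS_total, p), and for each factor level the contrast estimate
x̄_level − x̄ with standard error √(MSW·(1/n_level − 1/N)) on N−k degrees of
freedom. This contrast is defined for singleton levels too, which matters
for cohorts in which a clinical stratum contains one sample. The v-test
links a level to a quantitative variable:
v = (x̄_level − x̄)/√((s²/n_level)·(N−n_level)/(N−1)) with s² the overall
population variance, referenced to the standard normal. Euclidean level
barycenter distances are computed in the retained score space, both
level-to-level and level-to-overall-center; raw p-values are reported
(flagging threshold 0.05, configurable).

## Stage-2 comparison

Two samples are compared per component and measure (area and relative %)
with a two-sided two-sample t-test computed from across-portion summary
statistics — Welch by default, pooled optional — and Bonferroni adjustment.
The default family multiplies the number of pairwise comparisons in the run
by twelve components by the measures tested, the conservative reading when
samples are reused across pairs; per-comparison and per-measure policies
are selectable. When raw portions are unavailable, published ± values may
be supplied directly as the SD field of the summaries.

## Synthetic cohorts

The generator emulates the study conditions: 17 participants with the
published clinical factor codes, ten portions per sample, the 12-Gaussian
band, a smooth (default flat or gently sloped linear) baseline and
portion-level variability. Per-participant parameters are drawn around the
across-sample mean of the reference parameter sets: centers perturbed
(SD 0.5 cm⁻¹) and clipped to their windows, FWHM perturbed (SD 0.5 cm⁻¹)
within [7, 19], areas perturbed with the per-component across-portion
scatter reported for the reference samples. Portion variability is a single
multiplicative intensity factor N(1, 0.05²) plus additive Gaussian noise,
default 0.5% of the noiseless band maximum. Structured effects (e.g. a
caries-linked shift of component V) are injected as additive share-point
changes for participants matching a factor level. Everything is seeded;
identical seeds give bit-identical cohorts.

What the generator does **not** emulate: Amide I/II bands, water-vapor
lines, ATR penetration-depth effects, instrument line-shape convolution,
correlated (pink) noise, or baseline shapes beyond low-order polynomials.
Tests passing on these cohorts therefore validate the pipeline's numerics
and statistics, not robustness to every artifact of measured spectra.

## Problem sizes used in the checks

Noiseless reference recovery runs on the 291-point default grid
(1185–1330 cm⁻¹ at 0.5 cm⁻¹, finer than the nominal 4 cm⁻¹ instrument
resolution for stable derivative initialization). Noisy-recovery checks use
20 seeded cohorts (four reference samples × five seeds, ten portions each)
at 1% additive noise. The error-rate studies of the comparison stage run at
the component-parameter level — portion shares drawn around sample
parameters — with 500 null and 200 power replicates; this isolates the
statistical stage, whose behavior is independent of how the portion shares
were obtained, at a problem size that keeps the whole suite fast.

## Known limitations

- The VI/VII (random coil) area split is data-unidentified at realistic
  noise; see the identifiability note above.
- The ALS baseline is estimated on the full recorded range before cropping;
  strong out-of-band features influence the in-band baseline only through
  the smoothness penalty, but pathological neighbours (e.g. a saturated
  Amide II edge) are not specially handled.
- JCAMP-DX ingestion is not implemented; spectra exchange as two-column CSV.
- Kaiser retention assumes correlation-matrix eigenvalues; covariance-PCA
  users get a warning, not a conversion.
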