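# Methods

This note documents the models behind each analysis stage, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical decisions a user should know before
trusting a number.

## Filament representation

A filament is an ordered list of subunits on the *genetic* (one-start)
helix; subunit `i+2` is the neighbour up the same long-pitch strand,
`i+1` the laterally adjacent subunit on the opposite strand. Residue
numbering follows mature skeletal α-actin (1–375), in which H40 lies in
the D-loop (38–52). PDB author numbering is taken at face value, with
an integer offset available for structures numbered differently.
Coordinates are Å throughout; persistence lengths are converted to μm
(1 μm = 10⁴ Å) only when reported. Centres of geometry are unweighted
means over heavy atoms by default (Cα-only by option); hydrogens are
always excluded. "Standard deviation" in pooled frame × subunit tables
is the population SD (divide by n), switchable to the n−1 convention.

## Persistence length

The estimator is the tangent-correlation fit: for a trace with segment
length `b`, `⟨t_i · t_{i+k}⟩ = exp(−k b / L_p)`, so the slope of
`ln⟨cos θ_k⟩` vs `k` gives `L_p = −b/slope`. Correlations for all
separations are computed at once by FFT autocorrelation of the tangent
series, averaged over frames and positions.

*Fit range.* The default range is `k = 1 .. k*` with `k*` the largest
separation at which the mean correlation still exceeds 0.9 (at least
two points). This deliberately confines the fit to the initial decay:
at large separations the log-correlation estimate is dominated by a few
long-wavelength bending modes, so its errors are large and strongly
correlated across `k`. In simulation (L_p = 10 μm, b = 55 Å, 2000
nodes, 500 frames) the slope error grows from ≈0.4 % sd with a ~50-
segment range to ≈4.6 % sd when the fit is extended to where the
correlation reaches 0.5. Both the threshold and `k*` are settable.

*Uncertainty.* Per-frame L_p estimates are formed with the same fit,
the series is blocked at its Flyvbjerg–Petersen plateau (below), and
the quoted sd is the standard deviation of the plateau-level block
means. This stays meaningful when frames are autocorrelated. Note it
is a spread of single-frame estimates, not a standard error of the
pooled estimate; for independent frames the pooled estimate is far more
precise than the sd suggests.

*Degenerate input.* If the fitted slope magnitude falls below 1e−12
the decay is unresolvable at the trace length; the result is flagged
`beyond_resolvable` with `L_p = inf` rather than an arbitrary large
number.

## Helical symmetry and crossover length

Per frame, the axis direction is the normal of the least-squares plane
through the second differences `p_{i+2} − 2 p_{i+1} + p_i` of the
subunit COGs. For an ideal helix the axial component of `p_i` is linear
in `i`, so these vectors are *exactly* perpendicular to the axis; the
estimator is therefore exact for noise-free helices with n ≥ 4 and
degrades gracefully with noise. (A total-least-squares line through
the COGs was rejected: for a finite helix its direction is biased by
the non-vanishing covariance cross-terms, ~5 mrad for 13 subunits at
25 Å radius, enough to corrupt the rise in the 4th decimal.) With only
three subunits a helix is not identifiable at all; the code falls back
to the principal axis of the points without an exactness guarantee.

The rise is the mean axial spacing of consecutive COG projections. The
twist is the mean signed angle between the axis-perpendicular parts of
*consecutive difference vectors* — these rotate by exactly the twist
per subunit and are independent of where the axis sits, so no axis
centre needs to be estimated. Sign convention: negative = left-handed
about the axis oriented from the first to the last subunit (F-actin's
genetic helix is ≈ −166°). Subunits on the axis (zero radius) make the
twist undefined and raise an error.

The crossover length is the half-period of the two-start helix,
`L_c = 180·h/(180 − |φ|)`: the long-pitch phase advances by
`180 − |φ|` degrees per subunit, so strands cross every
`180/(180 − |φ|)` subunits. Valid only for `0 < |φ| < 180`.

Ensemble means and SDs are over frames, with block-averaging
diagnostics attached when at least 8 frames exist.

## Block averaging

`block_average` implements successive pairwise blocking: at level `ℓ`
the series is the means of `2^ℓ`-sample blocks and
`SE_ℓ = sqrt(var_ℓ/(n_ℓ − 1))`. For autocorrelated data the SE curve
rises with block size and plateaus once blocks are effectively
independent. The plateau is the first level whose SE changed by less
than 5 % from the previous level (a constant series plateaus at SE 0);
if no level qualifies the last one is used and the result is flagged
unconverged. At high levels the SE estimate itself is noisy (relative
sd ≈ 1/√(2 n_blocks)), so calibration checks should aggregate several
independent series; a single AR(1) series of 2¹⁴ samples leaves ~13 %
sampling noise on the plateau SE.

## Synthetic-data generators

All generators are pure functions of a frozen parameter object that
includes the seed.

*Worm-like chain.* Bend angles between successive tangents are drawn
from `f(θ) ∝ exp(−L_p θ²/(2b))·sin θ` on [0, π] (harmonic bending
energy with the spherical measure) by inverse-CDF lookup on a 10⁻⁴ rad
grid — rejection-free and reproducible; azimuths are uniform. This
gives `⟨cos θ⟩ = exp(−b/L_p)` up to O((b/L_p)²), negligible at
filament stiffness (b/L_p ~ 10⁻³). Defaults b = 55 Å (the
subunit-COG node spacing of F-actin) and frame counts of a few hundred
match the analysis conditions used throughout. Frames are independent
by default so the block-average plateau is known; an AR(1) knob `rho`
correlates the underlying Gaussian copula of the bend draws across
frames to exercise block averaging nontrivially.

*Helix ensemble.* Ideal lattice (default 13 subunits, 27.5 Å rise,
−166.15° twist, 25 Å radius) plus iid Gaussian displacement per
coordinate (default study condition 0.5 Å).

*Peak profiles.* One or two Gaussian components on a linear background
with additive Gaussian noise. Additive Gaussian noise is an assumption;
no detector noise model is implied. The two-population composite
(narrow component that shifts between conditions over a broad static
one) emulates co-existing filament populations in a fibre.

*Speed samples.* Gaussian mixtures truncated at zero by redrawing
negatives (clipping would distort the component shapes). Default
two-population condition: weights 0.58/0.42, means 2.5/4.5 μm/s, sd
0.4 μm/s, n ≥ 100 per condition as in typical motility experiments.

*Synthetic subunit.* For the contact/CG stage, a 375-residue Cα-only
blob (radius 27 Å ≈ half the ~55 Å monomer span, COG 25 Å off-axis)
with the D-loop placed on the +z face and its along-strand target
regions (130–150, 161–175, 345–357, 369–375) on the −z face, so that a
27.5 Å-rise filament reproduces the interface geometry the contact
analysis assumes. It has no secondary structure or chemistry: contact
*counts* on it demonstrate the operation, not actin's real contact
census. Consequently, passing tests show the estimators are correct
and calibrated on data satisfying their assumptions — they do not show
that real filaments satisfy those assumptions.

## Sub-pixel peak fitting

The window is anchored at the profile argmax (ties to the lower pixel)
and spans ±3 or ±4 pixels; `A·exp(−(x−μ)²/2σ²) + c` is fitted by
bounded nonlinear least squares (μ constrained to the window, σ > 0).
The constant `c` is the minimal baseline once the linear flank
background has been removed. σ is reported in pixels; it is the width
quantity compared between conditions.

*Accuracy limit.* For σ = 5 px and noise 2 % of amplitude, the Fisher
information of the ±4 px window gives sd(μ̂) ≈ 0.081 px — a median
|error| of ≈0.055 px for any unbiased estimator (the μ-gradient is
orthogonal to the even-parity A/σ/c gradients, so the bound does not
depend on whether the baseline is fitted). The least-squares fit
operates essentially at this bound (measured median ≈0.06 px). Fits of
broad peaks (σ ≈ 9–10 px) through such narrow windows are
ill-conditioned; their centres carry several-fold larger errors, and
±3 vs ±4 window disagreement is then a useful instability diagnostic.
For smooth noise-free two-Gaussian composites the systematic window
dependence of the centre is small (≲0.06 px over physically plausible
separations); large window-to-window divergence in real data indicates
noise plus composite structure, not a clean two-Gaussian shape.

*Spacing shifts.* With the small-angle relation `d ∝ 1/R` the percent
spacing change is `(R_rest/R_act − 1)·100`, positive when the
reflection moves toward the pattern centre (filament extension). The
pattern-centre pixel is always user-supplied calibration — camera
geometry is never assumed.

*Asymmetry.* The score is the normalised third central moment of
baseline-subtracted intensity over the window, plus the left/right
half-area imbalance about the fitted centre. Both are 0 for symmetric
peaks and negate under mirroring; the *sign* for a given composite
depends on window truncation and should not be over-interpreted.

## Speed mixtures and the decision procedure

k = 1 uses the closed-form Gaussian MLE; k = 2 runs EM (tolerance 1e−8
on the log-likelihood, up to 2000 iterations) from a median-split
initialisation with per-restart jitter, best of 10 seeded restarts.
`BIC = −2 logL + (3k−1) ln n` decides the model order — a reproducible
criterion for the mono- vs biphasic call. The unconstrained k = 2
likelihood is unbounded (a component can collapse onto one point); a
restart whose component sd falls below 1e−6 of the sample sd is
abandoned, converged restarts are preferred, and if every restart
slides into the singularity (typical for unimodal data) the best
interior state reached before collapse is returned flagged
`converged=False` — that interior optimum is the meaningful quantity
for model comparison. Components are reported in ascending-mean order.
Threshold splits count ties as "below" and report them separately, so
both strict fractions stay recoverable.

Group comparison: KS normality per group against a Gaussian with the
group's own mean and sd; if either p < 0.05, Mann–Whitney (two-sided),
else Student's unpaired t. Plain KS with estimated parameters is
anti-liberal; a Monte-Carlo Lilliefors correction is available by flag,
with plain KS kept as the default convention. Two constant, equal
groups return p = 1 with a flag. On Gaussian nulls the procedure's
empirical type-I error is ≈0.05 (the gate essentially never fires).

## Pipeline

Configs are YAML/JSON validated against a schema that rejects unknown
keys. All stage seeds derive deterministically from the master seed via
SHA-256, so a rerun with the same config is byte-identical
(`report.json` carries the config hash, derived seeds and library
versions). A failing stage aborts the run, names itself, and leaves a
`FAILED` marker beside any partial outputs.

## Problem sizes

Defaults used by the test-suite and the reproduction script: WLC
ensembles of 2000 nodes × 500 frames (20 seeds per stiffness level for
recovery curves), helix ensembles of 500 frames, block-average
calibration on 2¹⁴-sample series (median over 25 replicates), 100
simulated reflections for sub-pixel accuracy, 500-speed samples with
25–50 seeds for model-selection rates, and 2000 replicates for the
type-I error. The shipped demo trims the WLC ensemble to 800 × 150 so
the whole pipeline completes in well under a minute.

## Known limitations

* Only the conformational-ensemble persistence-length estimator is
  provided (no Fourier bending-mode or time-correlation analysis).
* Mechanics treats the filament as a finite trace; periodic images are
  not unwrapped.
* 2D detector images are out of scope; profiles arrive as 1D traces.
* The generators are statistical stand-ins — a mutation enters only as
  different parameter values, never as chemistry.
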