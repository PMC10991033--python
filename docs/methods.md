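# Methods

This note documents the statistical machinery behind `envmra`: the models,
the estimators and their numerical choices, the calibrations, what the
synthetic phantoms do and do not emulate, and the known limitations.

## Envelope models

A Rayleigh component is parameterised by its echo power `σ²` (so
`E[x²] = σ²`), the convention in which the second-moment normalization
constraint `α_L σ²_L + α_M σ²_M + α_H σ²_H = 1` is linear. Mixtures keep a
fixed three-slot representation `(L, M, H)` with non-decreasing powers;
degenerate cases carry zero rates rather than a separate type, because the
non-MRA rule inspects `α_L = α_H = 0` on a three-component fit. Raw moments
use the exact closed form `E[xᵏ] = Σ_c α_c σ_cᵏ Γ(1 + k/2)` (Gamma
function, no tables), which doubles as the Monte-Carlo test oracle.

## Moment statistics and the component-count test

Each ROI is normalized by its own sample second moment and summarised by
the raw moments of orders (1, 3, 4, 5). The test statistic against a null
model is `D² = (m − μ)ᵀ Σ⁻¹ (m − μ)` with `μ` the null's theoretical
moments and `Σ` its moment covariance at the effective sample count
`n_eff`; both stages (`D₁` vs Rayleigh, `D₂` vs the fitted two-component
mixture) use the same four orders.

**Normalization correction.** Because the data are divided by their own
sample second moment, the moment estimators are not iid means. `Σ` applies
a first-order delta-method correction,
`m̃_k ≈ m_k − (k/2) μ_k (m₂ − 1)`, expanded from exact model moments.
Verified against simulation: entrywise agreement of the predicted and
empirical covariance within a few percent at n = 500, and a stage-1
rejection rate of 4.6–4.8% at the 9.49 threshold (the uncorrected iid
covariance gives 2.9%).

**Chi-square approximation quality.** `D₁` is χ²₄ only asymptotically. The
order-5 sample moment is strongly skewed (skewness of `x⁵` under Rayleigh
≈ 11), so at n_eff = 500 the *shape* of the D₁ distribution still deviates
from χ²₄ (KS distance ≈ 0.10, falling to ≈ 0.04 by n = 10⁴) even though
the 95th percentile — the only quantile the decision uses — is accurate.
This is a property of the statistic, not of the covariance.

**Thresholds.** `threshold_d1()` recomputes the upper-5% χ²₄ point (9.49 at
two decimals). The two-component threshold 4.53 is a shipped constant
calibrated as a mean acceptance quantile over two-component parameter
combinations; `calibrate_threshold_d2()` re-derives a comparable constant
by simulation for other moment orders or sample sizes.

## Parameter estimation

Estimation is moment matching by exhaustive grid search plus local
refinement — deterministic, derivative-free, and robust for a four-point
objective:

* Grid: mixture rates in steps of 0.02 over the simplex (boundaries
  included, so collapse is representable); `σ²_L ∈ [0.01, 1)` and
  `σ²_H ∈ (1, 50]` on ×1.1 geometric grids; the remaining power eliminated
  by the normalization constraint and the ordering enforced as
  feasibility. Ties break toward the smallest `α_H`, then the smallest
  `σ²_H`.
* The scan uses a fixed quadratic form (the Rayleigh-null covariance,
  whitened once), so ~5·10⁵ three-component candidates are one vectorized
  nearest-neighbour query (~10 ms per ROI); the candidate table is built
  once per grid configuration and the argmin does not depend on `n_eff`.
* Three-component refinement: pattern search with halved steps (two
  levels), bounded to the declared parameter box.
* Two-component refinement: a deterministic Nelder–Mead polish in
  `(rate, log σ²_lo)` minimizing the **plug-in** `D₂` — the distance the
  4.53 threshold is applied to, with the covariance evaluated at the
  candidate itself. Two reasons: grid-resolution residuals are amplified
  by `n_eff` (at n = 10⁵ they alone exceed the threshold and would push
  genuine two-component data to the three-component branch), and the fixed
  Rayleigh weighting mis-weights directions for strongly non-Rayleigh
  data. With the polish, true two-component mixtures (power ratio ≥ 4,
  `α_H ≥ 0.2`, n = 10⁵) are accepted and assigned the M+H combination in
  ≈ 100% of replicates.
* An ill-conditioned plug-in covariance at a candidate (possible for
  near-degenerate fits) reads as "no usable two-component fit" and the
  flow proceeds to the three-component stage.

The one-component fit is forced to `σ² = 1` by the normalization; misfit
appears in `D₁`, not in the fitted scale. The collapse tolerance for the
non-MRA rule is `α ≤ 0.01`, covering refinement jitter around exact grid
zeros; the moment checks are strict inequalities against the exact
Rayleigh values `√π/2` and `Γ(2.5)` (mixtures can only move `m₁` down and
`m₃` up, so the coherent side is unambiguous).

## Effective sample count

PSF convolution correlates neighbouring pixels, so `Σ` must count
independent speckle realisations rather than pixels. The geometric count —
ROI area over the 1.9 × 2.4 mm resolution-cell area, i.e. 9 cells per
5.7 × 7.2 mm ROI — is correct for the ROI-mean *power* (measured
empirical n_eff ≈ 10), but the per-ROI normalization removes exactly that
correlated power mode: the residual normalized-moment fluctuations carry
roughly an order of magnitude more effective degrees of freedom (measured
≈ 80 per ROI). A single scalar cannot calibrate all four moments at once,
so the package calibrates at the decision point: `n_eff = scale × 9` with
`scale` chosen so the empirical 95th percentile of `D₁` on homogeneous
phantoms equals 9.49 (`calibrate_n_eff_scale()`; shipped default 5.4 for
the default PSF/ROI geometry, giving a stage-1 rejection rate of 5.0% on
held-out homogeneous frames). Frames with genuinely uncorrelated pixels
use `n_eff_policy="raw"`.

## ROI pipeline

ROIs have constant physical size and overlap by half an ROI by default
(dense parametric maps; set the stride fraction to 1.0 for independent-ROI
statistics). The two-component combination needs the neighbourhood
normal-tissue power: pass 1 computes provisional decisions with reference
power 1 (the normalized Rayleigh value), pass 2 re-resolves the assignment
with the median `σ²_M` over each ROI's 8-neighbourhood, taken from
Rayleigh (power 1) and three-component (fitted `σ²_M`) neighbours, falling
back to the frame-global median and then to 1. Vessel exclusion is a
user-supplied mask. Per-ROI failures are logged and excluded from every
numerator and denominator. Non-MRA ROIs are excluded from all
MRA-parameter products; ROIs without an H component embed at the origin of
the fibrosis-parameter plane.

## HLSF

The filter grid is anchored at the origin with half-open 0.5 × 0.5 cells
(boundary points belong to the upper cell). "Top 90% of probability mass"
is realised greedily: cells in descending reference density, ties broken
by cell index, accumulated until the covered mass reaches the target —
so the covered mass slightly overshoots 90% and a held-out healthy sample
leaves ≈ 9% of its points outside. The density floor (0.001, strict `<`)
is applied to the *evaluated sample's own* histogram, removing isolated
outlier points from both counts; applied to the reference instead it would
reshape the filter rather than the fraction, which does not match its role
in the fraction's definition. Filters serialise to JSON with a schema tag.

## Synthetic phantoms

Speckle is simulated as a per-pixel circular complex Gaussian scatterer
field with class-dependent power, convolved with a unit-energy Gaussian
PSF (1.9 × 2.4 mm FWHM by default — the resolution cell implied by the
3 × 3-cell ROI), envelope = magnitude. This reproduces fully developed
speckle exactly in homogeneous regions and a controllable correlation
length; it does not model attenuation, depth-dependent gain, scan
conversion, discrete-scatterer-density effects, or acoustic propagation.
Class powers default to {L: 0.25, M: 1, H: 6} (fibrosis-to-parenchyma
power ratio 6). Fibrotic strands are connected curvilinear H structures;
nodules are L discs; lipid patches are FAT blobs whose coverage is
enforced to ±20% by rejection resampling.

The coherent lipid echo is a deterministic phasor of magnitude
`A √(local power)` (default A/σ = 2) added **after** the PSF acts on the
diffuse field: a pre-convolution constant phasor would be amplified by the
kernel's coherent gain (`‖k‖₁/‖k‖₂ ≈ 15`), producing a near-constant
envelope instead of the intended Rician statistics, whereas the
post-convolution term preserves the specified local coherent-to-diffuse
ratio exactly. Fat blobs default to 6–10 mm radii — larger than the ROI —
because the non-MRA *area fraction* is meaningful only when lipid regions
dominate whole ROIs; sub-ROI blobs read as power mixtures instead.

What passing phantom tests shows — and does not show. The phantoms verify
the statistical chain end to end (envelope laws, mixture recovery,
coherent-signature detection, filter coverage, healthy-vs-fibrotic
ordering) under ideal speckle. They do not certify performance on clinical
data, where attenuation, 8-bit quantization (an optional stage is
provided), vessel structures, and mixed pathology add effects the
generator deliberately omits.

## Numerical conventions

* Exact tie in the two-component combination assignment → M+H
  (conservative toward detecting fibrosis; ties have measure zero).
* `σ²_M` reference for the assignment and the three-component fit: the
  reference is used only by the assignment, never to constrain the fit.
* Frame I/O: raw little-endian float32 + JSON sidecar (bit-exact round
  trip), or bare CSV with caller-supplied spacing; parametric maps use
  fixed colour scales (`α_H` 0–1, power ratio 1–10).
* All simulation entry points take explicit seeds; fits are deterministic
  functions of the moment vector.

## Study sizes

The shipped studies use sizes that resolve their tolerances: 10,000 ROIs
at n = 500 for null calibration (binomial s.e. ≈ 0.2% on a 5% rate), 200
replicates at n = 10⁵ for recovery bias (s.e. ≈ 0.003 on `α_H`) and
detection rates, 20 splits of a 4,000-point reference for filter
coverage, and 10 paired 90-ROI frames for the discrimination ordering.

## Known limitations

* The non-MRA false-positive rate on correlated homogeneous speckle is
  ≈ 3% (the heavier-than-χ² tail of `D₁` feeds the later stages more often
  than the iid analysis suggests); clinical healthy livers show non-MRA
  fractions of the same order, so treat small non-MRA fractions as a
  floor, not signal.
* `D₁`'s bulk distribution is not χ²₄ at moderate `n_eff` (see above);
  only the decision quantile is calibrated.
* The `n_eff` calibration factor is specific to the PSF/ROI geometry it
  was calibrated for; recalibrate when either changes.
* The power-ratio estimate `σ²_H/σ²_M` is recovered with larger relative
  error than `α_H` (the moment objective is flat in that direction at
  moderate separation); treat mapped ratios as semi-quantitative.
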