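# Methods

This note documents the models, conventions and numerical choices behind
`ecsmap`, in the order data flow through the pipeline. All quantitative
claims below are checked by the test suite or recomputed by
`scripts/acceptance.py`; nothing here reports a number the code does not
itself produce.

## Confined-diffusion simulator (`ecsmap.synthetic`)

**Model.** A tracer performs 2D Brownian motion with free diffusion
coefficient `D` inside a bounded domain — a disc, a rectangle, or a channel
defined by a centerline polyline plus half-width with optional dead-end
stubs (the geometry family needed to emulate wide oriented corridors versus
narrow dead-ended neuropil). Positions are recorded every `Δt = 0.03 s` for
up to 500 frames, matching typical quantum-dot video rates. Independent
Gaussian localization noise (default `σ_loc = 0.03 µm` per axis, a typical
single-particle localization precision) is added to the recorded positions
only; blinking is modeled as Bernoulli per-frame detection, which removes
frames without truncating the track.

**Boundaries.** Proposals falling outside the domain are reflected
specularly about the violated boundary and the reflection is iterated until
the point is interior: coordinate folding for rectangles, radial reflection
about the circle for discs, reflection about the tube wall along the normal
from the nearest centerline point for channels. Specular reflection
preserves the uniform equilibrium law of reflected Brownian motion, which
the tests verify through the radial CDF on a disc.

**Discretization.** Each frame interval is integrated in `n_substeps = 4`
Brownian substeps. With single-step integration the reflection rule
over-weights the near-wall region when the per-frame rms step
`√(4DΔt)` is comparable to the domain size, biasing the measured plateau;
four substeps reduce this bias below the Monte-Carlo noise at the problem
sizes used here. A per-frame rms step exceeding half the smallest domain
dimension is rejected outright (the stepper could tunnel through walls).

**Ground truth.** Every cohort records the analytic MSD plateau
`E|r₁−r₂|²` of its domain when closed-form (disc: `R²`; rectangle:
`(Lx²+Ly²)/6`), and the exact `s²` scaling of the plateau under linear
scaling `s` is used as the digestion analogue (`s = √3` triples the
plateau).

## MSD and confinement (`ecsmap.diffusion`)

The MSD estimator uses all overlapping frame pairs; pairs spanning interior
blinking gaps are kept as long as both endpoints exist. The diffusion
coefficient is the slope/4 of an OLS line with intercept through the first
four MSD points; the intercept absorbs the `4σ_loc²` noise floor so `D` is
unbiased, and negative slopes are reported with a flag rather than silently
clamped. The confinement area averages the MSD over the closed lag window
[0.8 s, 1.0 s] (lags 27–33 at 30 ms) per trajectory, then takes the
unweighted mean across trajectories of a recording; a pair-pooled variant is
available (`method="pooled"`). Tracks too short to reach the window
contribute to `D` but not to confinement.

The percent-change-in-confinement statistic is the symmetric percent
difference `(t−u)/((t+u)/2)·100`, computed over all treated × untreated
recording pairs within one region; it is antisymmetric under group exchange
and bounded in (−200, 200). A pair with both areas zero is defined as 0 and
counted separately.

*Caveat on plateau readout.* The window average equals the analytic plateau
only when the domain decorrelates well before 0.8 s (relaxation time
~`R²/(3.4·D)` for a disc); the validation studies use domain sizes for
which this holds, and the residual few-percent undershoot is inside the 10%
recovery tolerance. The demo configuration sizes its domains accordingly.

## Shape analysis (`ecsmap.shape`)

Clouds are summarized by the eigen-decomposition of their sample covariance;
axis scales are `2√eigenvalue`, but only the ratio and long-axis angle are
consumed, so the scale constant is immaterial. The `√2` axis-ratio threshold
separates punctate ("0D", assigned zero length) from elongated ("1D")
clouds; collinear clouds (zero short axis) are 1D.

The 1D summary is an equal-length-segment polyline minimizing

    J = (1/N) Σᵢ dist(pᵢ, polyline)² + λ · k·s

parameterized by (start vertex, common segment length `s`, per-segment
headings), which enforces the equal-length constraint exactly (machine
precision, tested at 1e-6 relative). Optimization is derivative-free Powell
from multiple starts: two principal-axis-aligned starts (forward/backward)
plus random heading perturbations, 8 starts for final fits, 2 for
cross-validation fits, with a budget of 120 function evaluations per
parameter. `λ` defaults to 0.1 × the mean nearest-neighbor distance of the
cloud — a scale-aware choice that keeps the residual and length terms
commensurate — and is always reported in output. For two points at distance
`d` the exact optimum retreats `λ` from each endpoint, giving
`J* = λd − λ²`; this closed form is frozen in the tests.

**Segment count.** For each candidate `k` the points are split into random
halves; each half's fit is scored by mean squared point-to-polyline distance
on the other half, averaged over folds and `n_repeats` splits (defaults: 5
in the API, 2 in the large selection studies). Because CV estimates are
noisy and the candidate models are nested, "ties broken toward smaller k" is
realized by the one-standard-error parsimony rule: the smallest `k` within
one fold-SE of the CV minimum is selected (`se_rule=False` restores the
strict argmin). A time-block split (first half vs second half of acquisition
order) is available behind a flag.

## Orientation statistics (`ecsmap.orientation`)

Segment orientations are axial (period π), so angles are doubled before any
circular fit — a von Mises law on raw axial data would be ill-defined; a
direct no-doubling mode exists behind a flag for comparison. Lengths enter
the likelihood as weights renormalized to the segment count (`n_eff`), which
makes AIC invariant to uniform length rescaling and comparable across areas.
The three candidate models have 0 (uniform), 2 (von Mises: μ, κ) and 4
(orthogonal mixture: μ, κ₁, κ₂, w) free parameters. κ is obtained by
inverting the Bessel ratio `A₁(κ) = I₁/I₀` by bisection, capped at 500 for
degenerate (single-orientation) data. The mixture is fitted by EM with four
μ starts spread over the half-circle; its second center is fixed at μ + π/2
in orientation space. Selection minimizes `AIC = 2p − 2 logL`, ties to fewer
parameters. With equal weights and concentrations the mixture's two
components are exchangeable, so μ is identified only modulo π/2; recovery is
assessed accordingly.

Under a true uniform law, AIC still selects a concentrated model in roughly
the χ² tail fraction implied by the 2·p penalty (≈10–15%); the validation
requirement is ≥80% correct per class at n = 500, κ = 4, which the
selection study meets for all three classes.

## Width analysis (`ecsmap.width`)

Profiles are 1-pixel-wide axis-aligned lines at integer offsets equally
spaced between `margin` and `size − margin` (3 lines per image for compact
cell-body layers, 6 split across dendritic/axonal axes for neuropil, as in
the imaging protocol being emulated). A width is a maximal foreground run
bounded by background on both sides, in integer pixels × pitch (default
19.53 nm); no sub-pixel interpolation is attempted, since the input is a
binarized raster and interpolation would fabricate precision.
Border-touching runs are discarded because their true extent is unknown.
The foreground phase is ECS by convention; an inversion flag covers the
opposite convention.

The synthetic image generator draws cell bands (stripes) or a cell-block
mosaic separated by ECS gaps whose integer-pixel widths follow a constant or
lognormal law; it records the realized width of every bounded gap it draws,
so measured and true widths agree exactly by construction on stripe
fixtures, and the pooled measured median recovers the generator median
within 10% at ≥200 gaps on mosaics.

## Statistics (`ecsmap.stats`)

Two-group comparisons use the two-sided Mann-Whitney U test; k-group
comparisons use Kruskal-Wallis followed by Dunn's pairwise z tests on pooled
mean ranks with tie correction and Bonferroni adjustment (Dunn's test is
implemented in-package; Mann-Whitney, Kruskal-Wallis and Kolmogorov-Smirnov
come from scipy). Groups tied to a single constant are degenerate and
reported with p = 1 and a flag. The Kruskal-Wallis type-I error is verified
at 5% ± 1.5% over 1000 null simulations.

## Pipeline and reproducibility (`ecsmap.pipeline`)

One YAML configuration drives simulate → filter → diffusion → shape →
orientation → width → report. Every stage writes its tables (CSV with a
metadata header carrying the tool version) before the next starts; all
randomness derives from the single config seed through spawned
`SeedSequence` children, so identical configs give byte-identical outputs.
The run report records row counts in/out at each stage, test results, and a
hash of the canonicalized config.

The demo configuration emulates the study design at desk scale: a wide
oriented channel region ("CA1-like") and a narrow dead-ended region
("CA3-like"), two conditions where digestion scales the narrow domain by √3
and the wide one only mildly, so the percent-change contrast and the
orientation-model contrast both reproduce qualitatively.

## Problem sizes

Validation studies use 50–200 tracks × 100–500 frames, 100-seed selection
studies with clouds of 60–80 points and k ∈ 1..4, 100 orientation sets ×
n = 500 segments, and ~12 mosaic images for width pooling. These sizes keep
the whole validation suite at a few minutes on one CPU while leaving
all recovery checks limited by estimator bias rather than Monte-Carlo noise.

## What the synthetic data does not capture

No photophysics beyond Bernoulli detection (no intensity-dependent
localization error), no 3D motion or optical sectioning, no motion blur
within the 30 ms exposure, no spatially varying ECS geometry within one
domain, and no wavelet-segmentation artifacts in the binarized images.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated generative model, not robustness to every property of real
tissue data.
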