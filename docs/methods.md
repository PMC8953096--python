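# Methods

## The measurement problem

Quantitative T2 relaxometry measures the transverse relaxation of the
MRI signal across a train of echoes.  Tissues containing more than one
water compartment (collagen-bound vs free water in disk, muscle,
marrow, pulp) do not decay monoexponentially; a two-pool model

S(TE) = A_s · exp(−TE / T2_s) + A_l · exp(−TE / T2_l)

separates a short component (T2_s, amplitude A_s) and a long component
(T2_l, A_l).  The component *fractions* are f_s = A_s/(A_s+A_l) and
f_l = 1 − f_s.  `t2biexp` fits this model voxel by voxel on multi-echo
magnitude volumes, assembles short/long T2, amplitude and fraction
maps, and compares ROI means between two clinical groups
(temporomandibular joints with vs without disk displacement).

The default echo grid is the 8-echo turbo-spin-echo protocol TE =
13, 26, …, 104 ms.  This grid bounds what is estimable: it carries
useful sensitivity for T2 roughly between ~5 ms (first echo) and a few
hundred ms (last echo), which drives several numerical choices below.

## Voxelwise fitting

**Objective.**  Weighted mean squared error,
MSE = Σᵢ wᵢ (Sᵢ − Ŝᵢ)² / n, with one non-negative weight per echo
normalised to mean 1.  Weights are wᵢ ∝ 1/σᵢ², with σᵢ given or
estimated as the per-echo standard deviation of ≥ 20 background
voxels.  The purpose of the weights is to equalise the influence of
echoes with different noise levels; with uniform noise they reduce to
uniform weights.  The reconstruction is strictly voxel-independent —
no spatial regularisation — so boundaries of uniform regions cannot be
blurred by the fit.

**Optimiser.**  Powell's conjugate-direction method, implemented in
`optimize.py`: cycle over a direction set initialised to scaled
coordinate axes, line-minimise along each direction, and replace the
direction of largest single decrease by the cycle's net displacement
when Powell's acceptance test holds.  The line search brackets the
minimum by geometric expansion and polishes with bounded Brent
(scipy's `minimize_scalar(method="bounded")`).  Defaults: relative
function tolerance 1e-11 per cycle, absolute parameter tolerance 1e-8,
at most 60 cycles inside fits.  Parameter bounds — amplitudes ≥ 0, T2
∈ [0.01, 2000] ms — are enforced by clipping the parameter vector
inside the objective, keeping the search space unconstrained and the
objective continuous.

**Initialisation and multistart.**  Biexponential least squares is
multimodal (the classic two-exponential exchange/collapse degeneracy),
so the 4-parameter fit is multistarted deterministically from:

1. a two-segment log-linear split — the last three echoes seed the
   long pool, the log of the early-echo residual seeds the short pool;
2. four fixed points of a coarse (T2_s, T2_l) lattice — (10, 80),
   (30, 150), (15, 120), (45, 90) ms — each with amplitudes set to
   their weighted non-negative-least-squares optimum for that T2 pair
   (amplitudes enter the model linearly, so NNLS gives the exact
   conditional optimum);
3. a split of the voxel's monoexponential solution, when available
   (amp/2 each at 0.5× and 1.8× the mono T2).

The best restart wins; on noise-free data the search short-circuits
once the MSE reaches a near-zero threshold.  Because the two-pool
model nests the one-pool model, a fitted biexponential MSE above the
mono MSE signals an optimiser failure: such voxels are refitted with
extra, deterministically jittered lattice starts before the
mono-beats-bi rule is allowed to fire.  Components are order-normalised
(swap with amplitudes) after the fit so T2_s ≤ T2_l; ordering by
constraint would kink the objective.

**Degeneracy classification.**  A voxel is demoted from biexponential
to monoexponential when any of four rules fires (logical OR, order
irrelevant): a T2 component at zero; |T2_l − T2_s| < 1 ms; an
amplitude at zero; or mono MSE < biexponential MSE.  "Zero" needs
tolerances in floating point: a T2 counts as zero at ≤ 0.01 ms (the
lower search bound) and an amplitude at ≤ 1e-6 of the amplitude sum.
The MSE comparison is on raw weighted MSE with no
degrees-of-freedom penalty — with a perfect optimiser the nested model
could never strictly win, so a mono win is exactly the collapse signal
the rule is meant to capture.  A voxel with no positive signal at all
is *degenerate* (fitting is skipped).  Demoted voxels get NaN in all
biexponential maps and `validity=False`; ROI statistics ignore them.

## Synthetic phantoms and cohorts

The study's clinical volumes are not public, so the generator emulates
their statistical structure.  A phantom is a small voxel grid
(default 32×32×1 — matrix size does not change per-voxel physics, and
desk-scale tests need seconds, not the acquisition's 560×560) with
non-overlapping rectangular ROIs.  Each ROI voxel draws its truth from
a tissue distribution: normals truncated at > 1 ms for T2 (re-drawn
until T2_s < T2_l) and to (0.01, 0.99) for the short fraction;
amplitudes are (f_s, 1 − f_s), i.e. the amplitude sum is normalised to
1 per voxel so that amplitudes *are* fractions — the reference values
report fractions, not raw signal units.  With zero SDs a draw equals
the configured means exactly, giving noise-free identity phantoms.

The bundled reference table covers seven stomatognathic structures ×
two groups (disk displacement / no displacement) with ROI-mean
means and across-study SDs for short/long T2 and the short fraction,
from a published 1.5 T TMJ study of 18 + 32 joints.  Two quirks of the
printed table are deliberately *not* reproduced: printed short/long
fraction means do not always sum to exactly 1 (e.g. disk
0.708 + 0.279), and one pulp row is internally inconsistent (short
fraction 0.773 vs long 0.515); the generator enforces f_l = 1 − f_s,
which the fraction definition requires per voxel.

Noise is additive Gaussian per echo by default — the high-SNR
approximation of magnitude MRI noise — with a Rician option
(magnitude of the complex signal with Gaussian noise on both
quadratures; on empty background this gives the Rayleigh floor
σ√(π/2)).  Between-subject variability is modelled at the ROI-mean
level using the across-study SDs; within-ROI voxel scatter is a
separate knob defaulting to 0 because no voxelwise scatter is
published.  Cohorts are therefore drawn as one ROI-mean parameter set
per subject × structure (18 displaced, 32 non-displaced by default);
all randomness flows through explicit seeds.

What a green test does *not* establish: the phantoms have no anatomy,
no partial-volume mixing, no stimulated-echo or B1 effects of real
turbo-spin-echo trains, and no spatially correlated noise.  Green
means the *estimator and statistics* behave as claimed under the
stated generative model, not that the clinical values are reproduced
from real data.

## ROI statistics

ROI summaries are means/sample-SDs over valid in-mask voxels only.
Repeated segmentations are combined by averaging the two tracings'
means (the average of the two measurements enters analysis — masks are
not unioned).  Group comparison is a pooled-variance Student t-test on
subject-level ROI means, df = n_a + n_b − 2, two-sided; Welch's form
is available behind a flag.  Pooled rather than Welch is the default
because recomputing the strongest reference contrast (retrodiscal
short T2, 22.6 ± 5.2 in 18 vs 17.6 ± 3.0 in 32) from the printed
summaries gives p = 7.6e-5 under pooling — matching the printed
"0.0001" — versus ~8e-4 under Welch.  Significance uses Bonferroni
α = 0.05/4 = 0.0125 (four components per structure), with
0.0125 ≤ p < 0.05 reported as a trend.  Normality: Shapiro–Wilk
(scipy; validated against R's `shapiro.test` to 6 decimals).
Reliability: intersection-over-union for repeated masks, Cohen's κ
for categorical ratings (sklearn; the all-agree single-class edge case
returns the 0/0 limit 1.0).  Left and right joints of one patient are
treated as independent observations, matching the reference design.

## Known limitations (measured, not hidden)

At SNR 100 (Gaussian σ = 1% of the first-echo signal) the
biexponential problem on this 8-echo grid is poorly conditioned in the
long component: the Cramér–Rao bound gives per-voxel standard
deviations of ~26–43 ms for T2_l (25–37% relative) and ~3–6.5 ms for
T2_s at the reference operating points.  The weighted-LS estimate of
T2_l is heavy-tailed to the right (a few percent of voxels pin at the
2000 ms bound), so the ROI *mean* of T2_l is biased upward by tens of
percent even though the ROI *median* recovers the truth to ~2%; the
short-T2 ROI mean is much better behaved but still carries a
skew-driven upward bias, measured over 2000 voxels as +2.0% for the
medial pterygoid operating point and +4.9% for the hardest one (pulp,
near-equal fractions).  These are properties of the estimator itself — the fits
agree voxel-for-voxel with an independent Levenberg–Marquardt
cross-check started at the truth — and they bound what any
mean-recovery test can demand at this SNR.  The test suite asserts a
CRLB-derived budget for the short-T2 median error (< 1.4× the
theoretical floor) and documents where the mean-based 2% recovery
claims sit relative to these limits.
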