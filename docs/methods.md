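# Methods

## Scope and data model

The package analyses nuclear auxin pathway (NAP) protein dynamics in
germinating Marchantia gemmae at four levels: per-nucleus fluorescence
quantification, Aux/IAA (MpIAA) turnover kinetics, MpARF1:MpARF2
stoichiometry statistics, and an ODE model of ARF competition predicting the
transcription of a hypothetical auxin-regulated gene. All inputs can be
produced by the synthetic generators with known ground truth; the same code
paths accept real per-nucleus tables or TIFF stacks with the documented
schemas.

## Synthetic data: what it emulates and what it does not

`synthetic.make_image_stack` renders nuclei as isotropic Gaussian blobs
(σ = radius/2, truncated at 3σ, discrete kernel normalized to unit sum so
the integrated signal equals the ground-truth intensity exactly) on a
uniform background, one whole nucleus per z-plane (round-robin). Placing
each nucleus in a single plane makes the maximum-intensity projection retain
its full integral, which keeps the quantification oracle exact; it does not
emulate optical sectioning of a 3-D nucleus. Noise follows a standard camera
model in fixed order — per-nucleus multiplicative lognormal (expression
variability), Poisson shot noise on expected counts, additive Gaussian read
noise — each stage independently switchable. The detectors in the emulated
experiments are photon counters whose noise characteristics are not
published; all CVs here are free parameters. Default scene brightness
(8 000–30 000 a.u. integrated per nucleus on background 10) puts recovery
accuracy in the regime limited by mask geometry rather than shot noise.
Not emulated: gemma morphology, chlorophyll autofluorescence, time-gated
detection, spectral cross-talk (the emulated fluorophore pair is spectrally
separated), or 3-D point-spread functions. Passing tests therefore
demonstrate correctness of the measurement chain, not robustness to those
real-data effects.

Decay traces are `(1 − plateau)·2^(−t/t½) + plateau` with multiplicative
lognormal noise; the packaged fixture `params/mpiaa_decay.json` stores the
measured MpIAA rate constant (t½ = 6.5 min) so no test hard-codes it. ARF
fold-change time courses use exponential-to-plateau declines configured
declaratively in `params/arf_shapes.yaml`: ARF1 (τ = 8 h, plateau 0.15) and
ARF2 (τ = 3 h, plateau 0.005) decline with ARF2 reaching undetectability
earlier, ARF3 stays flat — the qualitative behaviour of the measured
accumulation profiles. Fold change at t = 0 is exactly 1 by definition of
the dormant reference. Expression tables plant exact numbers of up/down/
low-count genes; low-count genes carry differential-looking statistics so
the count filter is load-bearing in tests.

All generators are pure functions of their arguments including the seed;
ground truth never depends on the seed.

## Image quantification

Conventions: 0-based (row, col) pixels, 8-connectivity, scalar per-image
background (median of non-nucleus pixels) — a rolling-ball surface is out of
scope. Segmentation is Gaussian smooth → Otsu → connected components → area
filter, with an optional distance-transform watershed for touching nuclei.
Two choices matter for accuracy:

- **Log-scale detection.** `quantify_image` thresholds `log1p` of the
  channel-sum projection. Nucleus brightness spans an order of magnitude,
  and a linear Otsu threshold set by bright nuclei can swallow dim ones
  entirely.
- **Label expansion.** An Otsu mask stops roughly 1.5σ from the centre and
  would clip ~1/3 of a Gaussian blob's integral. Final labels are expanded
  by twice the median equivalent label radius (`expand_labels`, which never
  merges labels), extending masks past 3σ; noiseless recovery is then exact
  to machine precision and the cost is extra background pixels inside the
  mask.

Integrated intensity is Σ max(pixel − background, 0) over the label. The
detection floor is decided on the *unclipped* signed sum, which is zero-mean
with SD `noise_sd·√area` under no signal (the clipped sum carries a positive
bias ≈ 0.4·noise_sd·area that would hide dim nuclei); a nucleus is censored
when the signed sum is below `floor_sd` (default 3, the conventional limit)
times that null SD. `noise_sd` is the robust MAD-based SD of non-nucleus
pixels. Near the floor, relative errors of uncensored dim signals are
dominated by background noise integrated over the mask — visible in the
analysis as a heavy error tail for late-time ARF2.

Per-image summaries use the **mean** (not sum) of per-nucleus intensities so
fold change is robust to nucleus-count differences between images; whether
the original quantification averaged or summed is not documented, and this
is the package's choice. Images with < 30 quantified nuclei are flagged.
Nucleus correspondence across time points supports both re-identification
(stable ids per gemma) and mutual-nearest-centroid tracking with a
displacement cap.

## Decay kinetics

The default model is the one-component exponential with plateau fixed at 0;
a free plateau is opt-in (and needs ≥ 4 points). Nonlinear least squares
(`scipy.optimize.curve_fit`) is initialized from a log-linear regression on
the positive values — deterministic and exact for noiseless input, giving
residuals at machine precision. The rate is bounded k ≥ 0: protein turnover
cannot amplify signal, so rising traces report `converged=False` with k = 0
rather than a negative rate; fitted rates below 1e−6/min are snapped to 0
and the half-life reported as infinite. The 95% CI on k comes from the
asymptotic covariance. Flat-control checks (proteasome-inhibitor and
photostability controls) compare the *fitted* fractional decline over the
window against a 10% default threshold, which is robust to noise on the
final frame.

## Stoichiometry statistics

Ratios and tests operate on log2(ARF1/ARF2): the two channels enter
symmetrically and paired per-nucleus differences are approximately normal.
Censored points (denominator below floor or flagged) become NaN — never
infinite — and are excluded pairwise. The paired Student's *t* test runs per
time point against the dormant state without multiplicity correction by
default, matching per-time-point reporting; a Holm-adjusted column is
available. Zero-variance difference vectors are reported as degenerate
(p = 1 for zero shift, infinite statistic for a constant shift) instead of
erroring. No absolute-concentration calibration is attempted: fluorophore
brightness differences make cross-channel ratios relative. Anatomical
region selection (e.g. transition-zone nuclei) is an input mask, not
inferred.

## NAP competition model

State variables are total MpIAA `I` and reporter mRNA `m`; everything else
is algebraic. Design choices, in the package's own terms:

- **TIR1 folded into δ_Imax.** TIR1 levels change slowly relative to IAA
  turnover; auxin enters through the saturable factor `a/(K_aux + a)`.
  δ_I0 + δ_Imax is calibrated to ln 2 / 6.5 min so the saturating-auxin
  effective half-life equals the measured MpIAA turnover.
- **Exact pairwise sequestration.** ARF1–IAA binding is solved by the stable
  quadratic root at every step (mass conservation to rounding); the complex
  binds DNA with ARF1's affinity but contributes no activation.
- **Quasi-equilibrium promoter.** Binding is fast relative to transcription
  and decay, so promoter states are probabilities. The single-site closed
  form is the partition function over {empty, A1f, A1·IAA, A2}; for
  multiple independent identical sites the per-site marginal is unchanged
  and the promoter activation weight is `φ_act^h` with h configurable
  (default 1), rather than assuming all-sites-bound activation. The 4ⁿ
  microstate enumeration (`occupancy_bruteforce`, capped at n = 8) is kept
  as an independent oracle and agrees with the closed form to < 1e−10.
- **ARF inputs.** Measured fold-change profiles are interpolated per
  replicate with PCHIP — C1, passes through the knots, monotone between
  them, no overshoot, hence non-negative for non-negative data — with
  constant extrapolation beyond the last knot, and scaled by s1, s2.
  s2/K_2 ≫ s1/K_1 by default, reflecting ARF2 excess over ARF1 in dormant
  apical-notch nuclei; with the defaults the dormant activation occupancy is
  ~0.003, i.e. output starts near basal.
- **Scenarios.** `arf2_degradation_off` (and the ARF1 analogue) freeze that
  ARF's input at its t = 0 value — in-silico loss of proteasomal
  degradation. Initial conditions are the t = 0 steady state (dormant
  gemmae are treated as equilibrated). Because freezing ARF2 can only raise
  the repressor level relative to the declining profile, the degradation-on
  transcription rate dominates the frozen-ARF2 trajectory pointwise by
  construction; with the default parameters the frozen trajectory stays
  within ~6% of its initial near-basal value while the normal trajectory
  rises ~3-fold.
- **Numerics.** Minutes inside the integrator, hours at the I/O boundary;
  LSODA with rtol 1e−8/atol 1e−10, dense reporting on a uniform 201-point
  grid. Auxin defaults to a constant saturating level (10·K_aux).

Out of scope: MpARF3 and non-canonical ARF/IAA species, spatial modelling,
parameter inference from transcriptomes, and feedback of transcription onto
NAP components (none was observed in the underlying system).

## Expression filters

Thresholds are strict as specified in one constants table: total read count
< 45 excluded; differential iff |log2FC| > 1 and padj < 0.05; boundary cases
(count 44 vs 45, log2FC exactly 1.0, padj exactly 0.05) fall on the
non-differential side. Concordance classifies genes differential in both of
two contrasts as common (same sign) or opposite (opposite sign) and returns
the per-gene fold-change pairs for plotting. DE statistics themselves
(shrinkage, dispersion estimation) are upstream tools' responsibility; this
package consumes their output schema.

## Problem sizes and test design

The test suite regenerates all fixtures programmatically. Sizes were chosen
to keep each property statistically meaningful at desk scale: 20 scenes of
10 nuclei for segmentation recovery; 200 seeds with half-lives drawn from
[2, 60] min over a 30-min window for kinetics recovery (median relative
error < 5% at 2% noise); 1000 null datasets (n = 20 nuclei) for type-I
calibration of the paired test and 100 for power at a log2 shift of 1.0
(SD 0.3); a 10×10×10 concentration grid × site counts 1–4 for the occupancy
oracle. In the noisy image-recovery check, per-nucleus accuracy is asserted
against the *rendered* intensity (truth × that nucleus's multiplicative
noise draw) with the median error vs nominal truth bounded separately — the
multiplicative draw itself is irreducible scatter, not pipeline error.

## Known limitations

- Segmentation assumes well-separated, roughly circular nuclei; dense
  tissue would need the watershed path plus tuned area bounds.
- The censoring rule models the detection floor but not detector
  nonlinearity or saturation.
- Model concentrations are in arbitrary units; only ratios and the
  calibrated IAA half-life are anchored, so simulated transcription rates
  are comparable across scenarios, not absolutely.
- PCHIP profiles treat replicate time courses independently; no
  hierarchical sharing across replicates.
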