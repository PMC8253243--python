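# Methods

This package re-implements, as testable library code, the quantitative
readouts of a mouse gray-matter-encephalitis phenotyping battery: infrared
thermography of a social-recognition arena, trajectory analytics for
circular arenas, diffusion- and perfusion-MRI model fitting, voxelwise
morphometry statistics, and the cohort-level assays (startle/PPI,
blood–brain-barrier quantification, flow-cytometry gating).  No animal data
ship with it; a synthetic-data module generates every input with known
ground truth, and all validation is against that truth channel.

## Thermography and the Centralization Index

A calibrated thermal camera views a circular arena from above; frames are
temperature maps in °C.  Per frame the pipeline

1. min–max normalizes the frame to [0, 255] (mask construction only —
   temperatures are always read from the raw calibrated frame);
2. binarizes the normalized values inside the arena ROI.  The default
   cutoff is the **triangle method** computed on the arena pixels.  The
   animal occupies roughly 1% of the ROI, and for such extremely unbalanced
   histograms two-class Otsu is unstable: its between-class variance is
   nearly tied between the (background | animal) cut and the
   (background+tail | body) cut, and it flips to the latter as the tail
   cools — silently deleting the tail from the mask.  The triangle method
   is designed for a dominant background mode with a small warm tail and is
   stable across tail temperatures; Otsu and a fixed threshold remain
   available via `SegmentationConfig`;
3. removes noise by opening-by-reconstruction (erosion with a radius-1 disk,
   then exact binary reconstruction, implemented as keeping the connected
   components that survive the erosion) plus a 20-px minimum-size filter —
   this erases speckle without nibbling the animal's outline, so noiseless
   masks are recovered exactly;
4. keeps the single largest connected component as the whole-body mask
   (frames with none are flagged invalid, never raised);
5. splits body from tail by a morphological opening with a disk wider than
   the tail half-width (default radius 3 px), keeping the largest opened
   component, then dilating it back inside the whole mask by the same
   radius so the thin rim the opening shaves off the body outline returns
   to the body.  Residual tail fragments below 15 px are treated as rim
   remnants.  A literal "reconstruction of the opened seed inside the whole
   mask" would regrow the tail too (the mask is one connected component),
   which is why the bounded dilation is used instead.  A temperature check
   (tail should be the cooler compartment) only flags implausible splits.

The Centralization Index is CI = mean body temperature / mean tail
temperature per frame; it rises under stress-related peripheral
vasoconstriction (the tail cools, the core does not).  Because a ratio of
Celsius values is not unit-invariant the unit is recorded in the output
metadata.  Window statistics (mean, SD, valid-frame count over a time
window) support anticipation analyses; any trial phase with more than half
its frames invalid is surfaced as a warning.

`area_fraction` provides the generic densitometric readout (fraction of ROI
pixels at or above a uniform threshold) used for stain-coverage
quantification.

## Arena analytics

Zones are circles, annuli and annular sectors (quadrants are 90° sectors);
open-field center/mid/periphery default to equal-width annulus thirds of
the arena radius, and social-recognition interaction zones are annular
sectors of configurable depth (default 5 units) in front of each of the
five inserts — the tracker's own zone geometry is not published, so these
are explicit, configurable defaults.  A sample at time *t* stands for the
interval [*t*, *t*+1/rate), which makes exhaustive disjoint zones partition
the trial duration exactly.  A *visit* is a maximal run of in-zone samples
after merging gaps ≤ 0.2 s, kept if ≥ 0.5 s (both configurable; commercial
tracker conventions are unpublished).  Total zone time counts all in-zone
samples regardless of visit qualification.  Latency to first entry is
always paired with a censoring flag when the zone was never entered.  The
social-recognition readout compares the stranger insert against the mean of
the four acquainted stimulus inserts as percentages of total interaction
time.  The six-trial schedule (3 habituations with empty inserts, 2
exposures with five stimuli, 1 memory trial with one stimulus replaced by a
stranger; 300 s confined initiation + 300 s free interaction each) is
provided as data.  Water-maze learning curves average four 90-s-capped
trials per day; probe metrics are the target-quadrant specialization of
zone occupancy plus path length.

## Diffusion MRI (IVIM)

Signal model: S(b) = S0·[f·e^(−b·D*) + (1−f)·e^(−b·ADC)], separating
capillary pseudo-diffusion (perfusion fraction f, pseudo-diffusion
coefficient D*) from tissue diffusion (ADC), all in mm²/s, on the 19-value
b grid (10–200 in fine steps, 300–900 in 100s; 7 values exceed 200 s/mm²).

The default estimator is the segmented two-step fit:

1. **ADC** by log-linear least squares on b > 200 s/mm² with
   signal-proportional weights (delta method: additive signal noise σ
   becomes log-domain noise σ/S, so weighting residuals by S restores
   homoscedasticity);
2. **S0, f, D*** by bounded nonlinear least squares over all b with the ADC
   fixed (f ∈ [0, 1], D* ∈ (ADC, 0.1 mm²/s]; initial values f₀ from the
   high-b intercept deficit, D*₀ = 10·ADC);
3. one **refinement pass** (the `fit_ivim_segmented` default): the fitted
   perfusion compartment is subtracted and the ADC re-fitted on the
   corrected signal over the *full* b range, then step 2 repeats.  The
   capillary compartment has not fully decayed at b = 300 (≈0.7% of the
   signal at the defaults), which biases the plain high-b ADC upward by
   ≈1.5% and the f estimate downward by ≈0.005; the refinement removes most
   of that bias at essentially unchanged noise sensitivity.

A joint free-ADC fit is available behind a flag; at realistic SNR it is
ill-conditioned (the two exponentials trade off) and noticeably noisier
than the segmented fit, which is why the segmented form is the default.
Non-convergence is reported via a validity flag with diagnostics, never
silently patched.  Known limitation: at SNR 50 on single-trace data the
median absolute error of f is ≈0.02 and is dominated by ADC-estimation
noise from the seven high-b points — verified to sit at the exact-MLE
variance for that design — so sub-0.02 precision requires averaging (e.g.
over diffusion directions) upstream of the fit.

## Perfusion MRI (DSC)

R2* = 1/T2* is fitted per time point by log-linear regression over the
three echo times (1, 2.15, 3.3 ms); ΔR2*(t) subtracts the pre-bolus
baseline median (configurable window).  The bolus curve is fitted with the
gamma variate ΔR2*(t) = K·(t−t0)^α·e^(−(t−t0)/β), initialized by detecting
the peak, placing t0 at the last pre-peak sample below 5% of the peak, and
log-linearizing (ln y regressed on ln(t−t0) and (t−t0)); all four
parameters are then refined by bounded least squares.  Perfusion indices
use the closed forms CBV = K·β^(α+1)·Γ(α+1) (curve area),
MTT = β·(α+1) (first moment relative to t0), CBF = CBV/MTT — so
CBF·MTT = CBV holds to machine precision by construction, and CBV is
cross-checked against quadrature in the tests.  No arterial input function
is deconvolved; values are relative units, as in direct gamma-variate
perfusion readouts.  The radial acquisition's temporal resolution is
1/(TR·spokes) (9 ms × 201 spokes → 0.55 frames/s).

## Voxelwise morphometry statistics

Jacobian-determinant maps (local volume change from nonlinear registration;
registration itself is out of scope) are Gaussian-smoothed at FWHM 0.1 mm
(σ = FWHM/√(8 ln 2), kernels renormalized at mask boundaries), compared
voxelwise by a two-sample Student t-test, and the two-sided p-values are
Benjamini–Hochberg adjusted across in-mask voxels.  The signed z-score is
the two-sided normal quantile of q carrying the sign of the group-A−group-B
effect; volume reductions in group A are therefore negative, and the
significance mask applies z < −2.57 — the magnitude whose two-sided tail is
1%, truncated (not rounded) to two decimals, matching the display
convention that pairs a 1% FDR with |z| = 2.57.  A one-sided z convention
is available via the q→z helper.  BH adjustment is cross-checked in the
tests against an independent loop-based step-up implementation, and
false-discovery control is exercised on planted-effect simulations (false
positives counted outside the truth region dilated by two voxels, because
smoothing legitimately spreads true signal past the region edge).

## Cohort statistics

* **%PPI** = 100 − (startle after prepulse / startle after pulse-only)×100,
  computed per prepulse intensity (70/75/80 dB against the 120 dB pulse)
  after averaging amplitudes within each intensity per animal; animals with
  any negative %PPI are flagged excluded (non-performers), and a
  non-positive pulse-only response invalidates the animal.
* **Test selection**: Shapiro–Wilk on each group at α = 0.05; both p ≥ α →
  two-sided Welch t, otherwise two-sided Mann–Whitney U.  "Both groups
  normal" is the explicit tie-break for the case where only one group
  rejects.  All-tied data short-circuit to p = 1 with a note.  The choice
  is a pure function of the samples and is recorded in the result.
* **BBB assays**: water content = 100·(wet−dry)/wet; tracer concentrations
  come from a least-squares (exact for two points) fluorescence standard
  curve, replicate columns averaged first, out-of-range readings flagged as
  extrapolated, and values normalized so controls average 1.
* **Gating**: boolean marker classification with per-marker thresholds
  (−/+ at 1.0; −/low/high at 1.0/3.0 on the synthetic intensity scale —
  instrument thresholds are rig-specific, so these defaults are calibrated
  to the generator's intensity model).  Blood panel (within the
  scatter-derived lymphocyte pre-gate, carried as a boolean column):
  T-helper CD4+CD8−, cytotoxic T CD8+CD4−, B B220+CD11b−CD8−CD4−, myeloid
  CD11b+B220−CD8−CD4−, frequencies as % of lymphocytes.  Brain panel
  (within the single-cell pre-gate): leukocytes CD45ʰⁱCD11b−, microglia
  CD45ˡᵒCD11bʰⁱ, macrophages CD45ʰⁱCD11bʰⁱ; CD4/CD8 T cells within
  leukocytes; CD19+ B and CD138+ plasma cells within CD4−CD8− leukocytes.
  Events matching no class are counted as "ungated", never dropped, so
  classes plus ungated always partition the parent gate.  Bead correction
  scales counts by beads added / beads recorded.
* **Fold change**: values divided by the control mean (controls average 1).

## Synthetic data: what it emulates and what it does not

The thermal generator renders a warm body ellipse (36 °C) with a thin
constant-width tail (30 °C) on a ~22 °C background at 640×480 px, moving on
an Ornstein–Uhlenbeck velocity walk reflected at the arena wall (integrated
at ≤0.1 s sub-steps so reflections stay well-posed at any frame rate), with
i.i.d. Gaussian pixel noise — the camera's real noise spectrum, emissivity
variation, fur gradients and posture changes are *not* modeled, so passing
recovery tests demonstrates correctness of the segmentation logic, not
field performance on real fur.  Temperatures accept callables of time to
script scenarios such as anticipatory tail cooling.  Trajectory scripts park
the animal at an interior point of a peripheral zone for exact intervals
while the free path is confined away from all scripted zones, giving exact
occupancy oracles.  MRI generators emit the analytic models plus Gaussian
noise (no Rician floor, no motion).  Flow-event intensities place class
levels > 6 SD from every threshold so truth labels are exact by
construction.  Cohort tables draw normal or moment-matched lognormal group
effects.  All generators are bitwise reproducible from their seed, and at
zero noise the emitted data match the analytic truth to ≤1e−9 relative
error (frames are stored as float64 in memory; the TIFF interchange format
is float32).

## Validation problem sizes

The benchmark suite (shared by `tests/test_acceptance.py` and
`scripts/acceptance.py`) uses: 100 default-scene thermography sessions of
10 s at 2 Hz plus one 400-s cooling/flat session pair at 0.25 Hz for the
anticipation contrast; 200 diffusion replicates at SNR 50; three bolus
shapes for the DSC closed forms; 1000 random p-vectors for the BH oracle
and 20 planted-effect map pairs (16³ voxels, n = 8 + 8) for
false-discovery control; 100 random tracks for the occupancy oracle; and
10⁴-event tables per panel for gating.  These sizes give stable stochastic
summaries while keeping a full run in a few minutes on one CPU.

## Known limitations

Single-animal scenes only (stimulus mice sit behind inserts and are outside
the tracked ROI); no pose estimation or emissivity correction; no image
registration, AIF deconvolution or Rician-noise modeling; mixed-model
repeated-measures ANOVA is delegated to standard statistics packages rather
than re-implemented.
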