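# Methods

This note records the models, conventions, and numerical choices behind
`reconqc`, and what the synthetic experiments do and do not demonstrate.

## Inputs and region of interest

The unit of analysis is one examination consisting of two single-frame
DICOM series of the same anatomy: an AI-based reconstruction (test image
`I`) and a standard reconstruction (reference image `Î`), acquired
consecutively at matched table positions. Slices are matched across arms
by greedy nearest-position matching with a 0.5 mm tolerance (slices are
nominally 3 mm apart, so any sub-slice tolerance gives the same pairing);
unmatched slices are reported, never silently dropped. Intensities are
used as stored (after any DICOM rescale slope/intercept); no inter-arm
intensity normalisation is applied, because the two reconstructions come
from the same acquisition chain. An optional per-pair max-normalisation
flag exists but is off by default.

Every metric is computed on the central square region of interest whose
side is one third of the image matrix (ceil convention: 214 px for a
640 px matrix, `RoiSpec.third_of`). The crop offset is
`floor((dim − roi)/2)`, extra pixel to the bottom/right — fixed for
bit-reproducibility. The central third contains the anatomy of interest
and discounts the periphery most affected by inter-series motion.

## Paired metrics

MSE, pSNR (peak taken as `max(Î)`, the reference maximum, because MR
intensities have no nominal bit-depth peak; identical images yield an
infinite sentinel that is flagged and excluded downstream), SSIM
(windowed 11 × 11 Gaussian, σ = 1.5, population statistics, constants
c₁ = (0.01·D)², c₂ = (0.03·D)² with D the joint maximum; a
global-statistics mode evaluates the closed form once and serves as an
oracle), VIF (pixel-domain multi-scale variant: 4 scales, Gaussian
windows of size 2^(5−s)+1, GSM noise parameter σ_N² = 2; exactly 1 for
identical images, undefined for a constant reference), SAM (angle between
flattened intensity vectors, arccos argument clipped to [−1, 1]),
Bhattacharyya coefficient/distance, chi-square distance (½·Σ(p−q)²/(p+q)
over occupied bins), Frobenius norm of the difference, weighted Jaccard
similarity (Σmin/Σmax) and Bray–Curtis dissimilarity (Σ|I−Î|/Σ(I+Î)).

Histogram-based paired metrics use 256 equal-width bins over
[0, joint max] by default (`HistogramSpec`); bin count and range policy
are configurable. Each metric is isolated behind one function with a
brute-force double-loop oracle in the test suite, so a definitional
discrepancy is a one-line fix.

Undefined values (zero reference, zero-norm vector, disjoint histogram
supports) and infinite sentinels are recorded as flagged missing values
per slice; they never abort an exam.

## Unpaired metrics

Computed on each arm separately. **Entropy**: −Σ p_k log₂ p_k of the ROI
intensity histogram. The *metric* default matches the paired histogram
convention (256 bins, joint-max range); the *charted* entropy uses a
fixed intensity range (256 bins over [0, 4 × nominal tissue intensity] by
default, values clipped, `RunConfig.entropy_hist`). The distinction
matters for longitudinal monitoring: a per-image maximum is a sample
extreme whose fluctuation would leak into the chart statistic, whereas a
fixed quantisation range — the analogue of converting to a fixed bit
depth — makes exam-to-exam entropy differences reflect the intensity
distribution, not the noise maximum. **Tenengrad**: mean squared Sobel
gradient magnitude over interior pixels (boundary excluded); a
central-difference mode exists for closed-form checks. **BRISQUE**:
36 features (GGD shape/variance of MSCN coefficients plus AGGD
shape/mean/left/right-variance of four pairwise-product orientations, at
native and half resolution; the image is rescaled to [0, 255] before
MSCN so features are invariant to global intensity scaling). The quality
score is a pluggable regressor; the shipped toy model (JSON, trained by
`scripts/build_brisque_model.py` on a seeded ladder of clean synthetic
phantoms) scores the standardised feature deviation from the clean-image
centre, so higher = worse. Absolute BRISQUE values are comparable only
within this package, not to published scores from opinion-trained models.

A note on MSCN statistics: for a pure Gaussian-noise image the fitted GGD
shape comes out near 2.9, not 2.0 — dividing by the locally estimated
deviation lightens the tails. The moment-matching *fit* itself recovers
shape 2 on Gaussian samples; tests check both facts separately.

## Control charts

Per-slice metric values are natural-log transformed (nonpositive and
infinite values become flagged missing); the per-exam statistic is the
arithmetic mean of the finite log values (median mode available). The
baseline for each metric (and arm) is the mean and sample SD (n−1) of the
reference exam statistics, pooled across scanners by default (per-scanner
grouping available). Rules 2–4 are evaluated at exams where rule 1 has
fired — they are escalations of the ±2σ warning — with a switch for
always-on evaluation; rules 3 and 4 require same-side excursions (the
standard Western Electric reading). Consecutiveness is chronological
within one chart. A perturbation batch makes a metric *sensitive* when
any rule 2–4 violation occurs in the batch.

Under an i.i.d. normal null the rules fire at their nominal rates
(rule 1 ≈ 4.55%, rule 2 ≈ 0.27%); the acceptance suite verifies this on
10,000 simulated exam means, and verifies the rule engine against an
independent window-scanning oracle on 1,000 random sequences.

## Perturbation surrogates

The reference protocol re-reconstructs raw k-space with vendor tools;
raw data and the vendor model are not available here, so image-space
surrogates with the same qualitative signatures are applied to the AI
arm: RR1 = 3 × 3 median filter (edge-preserving smoothing, "stronger
denoising"); RR2 = re-injection of the slice's high-frequency residual
`I − median₃(I)` at gain 1 ("weaker denoising", roughly doubles residual
noise); RR3 = unsharp mask (amount 1.5, σ 1.5) followed by Gaussian
smoothing (σ 2.0), clipped at zero ("edge enhancement + smoothing").
Relative difference maps are `|O − P| / max(O) · 100` (percent).
Surrogate strengths are frozen tuning constants chosen so that, on the
synthetic cohort, the perturbations reproduce the expected chart
behaviour (paired metrics sensitive, strongest for RR3; entropy
unaffected); they are not claims about any vendor parameter mapping.

## Synthetic cohort

The generator renders the full study design: 50 reference exams,
8 constancy exams, and 5 held-out exams per scanner on 4 scanners, each
re-rendered under all three RR kinds (structure 50 + 8 + 4 × 5 × 3). An
exam is a stack of 21–33 slices (drawn uniformly) at 3 mm spacing,
640 × 640 px by default. Each slice contains:

* a body ellipse at nominal tissue intensity 100 (background ≈ 2);
* a three-layer "rectal wall" ring — dark lumen (−0.75 × tissue), bright
  fluid-like mucosa (+1.0, texture-free, the stable intensity peak),
  darker muscle (−0.35) — with a fixed anatomical edge width (~1 mm), so
  edge sharpness does not depend on render resolution;
* two-scale tissue texture: a dominant coarse field (SD 0.30 × tissue,
  correlation length size/16) for regional anatomical contrast, and a
  weak fine-detail field (SD 0.02 × tissue, correlation ~1 mm) standing
  in for trabecular/vascular structure.

The standard arm adds Rician noise at 5% of tissue intensity (magnitude
MR convention, SNR 20 — typical for a multi-average T2w-TSE); the AI arm
is mildly unsharp-masked (amount 0.4, σ 1 px — the super-resolution
flavour) with Rician noise at 0.8% (heavily denoised). Exam-level
anatomy parameters (intensity, body axes, ring size, layer contrast,
texture amplitudes, per-exam noise factors ±10%) are drawn per exam;
multiplicative amplitudes are drawn **log-uniformly**, because the
charted statistics respond roughly linearly in the log of these
amplitudes, so symmetric bounded draws in log-space give the symmetric,
light-tailed exam distributions that ±kσ limits presuppose. Texture
fields are simulated once per exam with wrap boundaries and circularly
shifted per slice (wrap-mode filtering commutes with the shift, so the
AI sharpening can be precomputed exactly); Rician noise is fresh per
slice. The whole cohort is a pure function of the master seed, with
per-exam seeds derived from (seed, role, index) so cohorts extend
without reshuffling. Exams are recipes rendered on demand: a fully
materialised 640 px cohort would need ~9 GB.

An optional inter-arm pixel shift emulates patient motion between the
two acquisitions (off by default).

### What the synthetic experiments show — and what they do not

Passing the end-to-end tests shows that the *framework* behaves
correctly: baselines summarise a reference cohort, the rules fire at
their nominal rates under the null, constancy exams from the reference
distribution stay in control, and reconstruction-type perturbations are
detected by paired metrics but not by entropy. It does **not** show that
the same sensitivities hold on clinical images: the phantom lacks real
anatomical variation between patients, motion, susceptibility and bias
fields, multi-coil noise correlation, and vendor reconstruction
behaviour. Absolute metric values and baseline widths from the synthetic
cohort must not be used as clinical reference limits.

## Problem sizes and replication

The scaled replay used by the acceptance tests and `scripts/acceptance.py`
renders 256 × 256 slices with the ROI at its defined proportion (86 px)
and restricts metrics to the chart-relevant representatives (MSE, pSNR,
SSIM; entropy), keeping a full 178-exam experiment to ~30 s. The
acceptance suite repeats the replay over master seeds 0–9 and requires
the headline behaviour (clean constancy, RR3 detected by all three paired
metrics, entropy silent) in at least 9 of 10 seeds; single marginal
failures (a base exam near −2σ tipped over by a ~0.1σ residual shift)
remain possible, which is the same false-alarm behaviour a real chart
would exhibit.

## Numerical conventions

* CSV outputs use a fixed float format (`%.12g`) and fixed row order, so
  reruns are byte-identical.
* Histogram upper edges are closed (the maximum lands in the last bin).
* arccos arguments are clipped to [−1, 1]; BC is clipped to ≤ 1 before
  the logarithm.
* VIF's degenerate-neighbourhood handling follows the reference
  pixel-domain treatment (ε = 1e−10).
* Baselines need ≥ 2 exams; zero-spread baselines raise a degenerate
  baseline error rather than dividing by zero.
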