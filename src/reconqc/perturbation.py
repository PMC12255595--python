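"""Image-space surrogates for reconstruction perturbations.

The sensitivity protocol re-reconstructs exams with deliberate changes to
the AI reconstruction: RR1 raises the denoising strength, RR2 lowers it,
and RR3 adds an extra edge-enhancement + smoothing filter.  Vendor
reconstruction operates on raw k-space; this module provides documented
image-space surrogates with the same qualitative signatures (RR1 smoother,
RR2 noisier, RR3 over-filtered), applied to the AI arm of an exam:

* RR1 — edge-preserving smoothing (median filter) at a high strength;
* RR2 — partial re-injection of the slice's own high-frequency residual,
  an estimate of the noise the AI denoiser removed;
* RR3 — unsharp masking followed by Gaussian smoothing, clipped at zero.

All three operators are deterministic and shape-preserving, and leave a
constant image (approximately) unchanged.  Surrogate strengths are tuning
constants frozen in the default spec; they are not claims about any
vendor parameter mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, median_filter

from .errors import ValidationError

RR_KINDS = ("RR1", "RR2", "RR3")


@dataclass(frozen=True)
class PerturbationSpec:
    """Which perturbation to apply and how strongly.

    rr1_median_size
        Window of the RR1 edge-preserving median smoother (pixels).
    rr2_noise_gain
        Fraction of the estimated removed noise RR2 re-injects; 1.0 roughly
        doubles the residual noise level.
    rr3_unsharp_amount, rr3_unsharp_sigma
        Edge-enhancement strength and blur scale of the RR3 unsharp mask.
    rr3_smooth_sigma
        Gaussian smoothing applied after the RR3 enhancement.
    """

    kind: str
    rr1_median_size: int = 3
    rr2_noise_gain: float = 1.0
    rr3_unsharp_amount: float = 1.5
    rr3_unsharp_sigma: float = 1.5
    rr3_smooth_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in RR_KINDS:
            raise ValidationError(f"unknown perturbation kind {self.kind!r}")
        if (
            self.rr1_median_size < 2
            or self.rr2_noise_gain <= 0
            or self.rr3_unsharp_amount <= 0
            or self.rr3_unsharp_sigma <= 0
            or self.rr3_smooth_sigma <= 0
        ):
            raise ValidationError("perturbation strength parameters must be positive")


def _check(I: np.ndarray) -> np.ndarray:
    I = np.asarray(I, dtype=np.float64)
    if I.ndim != 2:
        raise ValidationError("image must be 2-D")
    return I


def apply_rr1(I: np.ndarray, spec: PerturbationSpec) -> np.ndarray:
    """Stronger denoising: edge-preserving median smoothing."""
    I = _check(I)
    return median_filter(I, size=spec.rr1_median_size, mode="nearest")


def apply_rr2(I: np.ndarray, spec: PerturbationSpec) -> np.ndarray:
    """Weaker denoising: re-inject the slice's residual noise estimate.

    The high-frequency residual ``I - median3(I)`` estimates the noise the
    denoiser left in the image; adding ``gain`` times this residual back
    makes the output strictly noisier than the input while preserving
    anatomy.  Output clipped at zero (MR magnitude images are nonnegative).
    """
    I = _check(I)
    residual = I - median_filter(I, size=3, mode="nearest")
    return np.clip(I + spec.rr2_noise_gain * residual, 0.0, None)


def apply_rr3(I: np.ndarray, spec: PerturbationSpec) -> np.ndarray:
    """Additional edge enhancement then smoothing.

    Unsharp masking ``I + a*(I - G_sigma(I))`` overshoots at edges; the
    subsequent Gaussian smoothing emulates the over-filtered appearance.
    Output clipped at zero.
    """
    I = _check(I)
    enhanced = I + spec.rr3_unsharp_amount * (
        I - gaussian_filter(I, spec.rr3_unsharp_sigma, mode="nearest")
    )
    out = gaussian_filter(enhanced, spec.rr3_smooth_sigma, mode="nearest")
    return np.clip(out, 0.0, None)


_APPLIERS = {"RR1": apply_rr1, "RR2": apply_rr2, "RR3": apply_rr3}


def apply_perturbation(I: np.ndarray, spec: PerturbationSpec) -> np.ndarray:
    """Dispatch on ``spec.kind``."""
    return _APPLIERS[spec.kind](I, spec)


def relative_difference(original: np.ndarray, perturbed: np.ndarray) -> np.ndarray:
    """Percent relative difference map, |O - P| / max(O) * 100.

    The map visualises where a perturbation changed the image, scaled to
    the original image's maximum intensity.
    """
    original = _check(original)
    perturbed = _check(perturbed)
    if original.shape != perturbed.shape:
        raise ValidationError("images must share a shape")
    peak = float(original.max())
    if peak <= 0:
        raise ValidationError("original image must have positive maximum")
    return np.abs(original - perturbed) / peak * 100.0
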