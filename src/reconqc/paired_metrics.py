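"""Full-reference image quality metrics.

Eleven paired metrics comparing a test image ``I`` (the AI-based
reconstruction) against a reference image (the standard reconstruction of
the same slice): MSE, pSNR, SSIM, VIF, SAM, Bhattacharyya coefficient and
distance, chi-square distance, Frobenius norm, weighted Jaccard similarity,
and Bray-Curtis dissimilarity.

All functions take two arrays of identical shape with finite nonnegative
entries and return a scalar.  Metrics with an identity sentinel at
degenerate inputs (pSNR of identical images, BD of disjoint histograms)
return ``inf``; downstream aggregation flags those rather than crashing.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.signal import fftconvolve
from skimage.metrics import structural_similarity

from .errors import UndefinedMetricError, ValidationError
from .types import (
    PAIRED_METRICS,
    Arm,
    HistogramSpec,
    RoiSpec,
    SeriesPair,
    SliceMetricRecord,
)
from .image_io import extract_central_roi


def _check_pair(I: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    I = np.asarray(I, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if I.shape != ref.shape:
        raise ValidationError(f"shape mismatch: {I.shape} vs {ref.shape}")
    if I.ndim != 2:
        raise ValidationError("images must be 2-D")
    if not (np.all(np.isfinite(I)) and np.all(np.isfinite(ref))):
        raise ValidationError("images must be finite")
    if np.any(I < 0) or np.any(ref < 0):
        raise ValidationError("intensities must be nonnegative")
    return I, ref


def mse(I: np.ndarray, ref: np.ndarray) -> float:
    """Mean squared error, (1/N) * sum((I - ref)^2)."""
    I, ref = _check_pair(I, ref)
    return float(np.mean((I - ref) ** 2))


def psnr(I: np.ndarray, ref: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB: 10*log10(max(ref)^2 / MSE).

    The peak is the maximum of the reference image, not a nominal bit-depth
    value, because MR magnitude intensities have no fixed dynamic range.
    Identical images give ``inf`` (flagged downstream, excluded from the
    log-transform); an all-zero reference is undefined.
    """
    I, ref = _check_pair(I, ref)
    peak = float(ref.max())
    if peak == 0.0:
        raise UndefinedMetricError("pSNR undefined: reference image is all zero")
    err = mse(I, ref)
    if err == 0.0:
        return math.inf
    return float(10.0 * math.log10(peak**2 / err))


def dynamic_range(I: np.ndarray, ref: np.ndarray) -> float:
    """Joint dynamic range used by SSIM: max intensity over both images."""
    return float(max(I.max(), ref.max()))


def ssim(
    I: np.ndarray,
    ref: np.ndarray,
    k1: float = 0.01,
    k2: float = 0.03,
    window_policy: str = "gaussian",
    data_range: float | None = None,
) -> float:
    """Structural similarity index.

    ``window_policy='gaussian'`` (default) is the windowed variant of the
    reference implementation: an 11x11 Gaussian window (sigma 1.5), local
    statistics with population normalisation, and the mean of the local
    SSIM map.  ``window_policy='global'`` evaluates the SSIM formula once
    from the global means, variances, and covariance — useful as a direct
    oracle for the printed closed form.

    The stabilising constants are c1 = (k1*D)^2, c2 = (k2*D)^2 with D the
    dynamic range (joint max by default, since MR intensities are not bound
    by a bit depth).
    """
    I, ref = _check_pair(I, ref)
    D = dynamic_range(I, ref) if data_range is None else float(data_range)
    if D <= 0:
        raise UndefinedMetricError("SSIM undefined: zero dynamic range")
    if window_policy == "global":
        mu_i, mu_r = I.mean(), ref.mean()
        var_i, var_r = I.var(), ref.var()
        cov = ((I - mu_i) * (ref - mu_r)).mean()
        c1, c2 = (k1 * D) ** 2, (k2 * D) ** 2
        return float(
            (2 * mu_i * mu_r + c1)
            * (2 * cov + c2)
            / ((mu_i**2 + mu_r**2 + c1) * (var_i + var_r + c2))
        )
    if window_policy != "gaussian":
        raise ValidationError(f"unknown window_policy {window_policy!r}")
    return float(
        structural_similarity(
            I,
            ref,
            data_range=D,
            gaussian_weights=True,
            sigma=1.5,
            win_size=11,
            use_sample_covariance=False,
            K1=k1,
            K2=k2,
        )
    )


def _gaussian_kernel_2d(n: int, sigma: float) -> np.ndarray:
    ax = np.arange(n) - (n - 1) / 2.0
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def vif(
    I: np.ndarray,
    ref: np.ndarray,
    sigma_nsq: float = 2.0,
    n_scales: int = 4,
    eps: float = 1e-10,
) -> float:
    """Visual information fidelity, pixel-domain multi-scale variant.

    Ratio of the mutual information the test image preserves about the
    reference to the information content of the reference, under a Gaussian
    scale mixture source model with additive neural noise variance
    ``sigma_nsq``.  Equals 1 for identical images, is typically below 1 for
    degraded images, and can exceed 1 when the test image is an enhanced
    (e.g. contrast-stretched) version of the reference.
    """
    I, ref = _check_pair(I, ref)
    num = 0.0
    den = 0.0
    dist, src = I, ref
    for scale in range(1, n_scales + 1):
        n = 2 ** (n_scales - scale + 1) + 1
        kern = _gaussian_kernel_2d(n, n / 5.0)
        if scale > 1:
            src = fftconvolve(src, kern, mode="valid")[::2, ::2]
            dist = fftconvolve(dist, kern, mode="valid")[::2, ::2]
        if min(src.shape) < n:
            raise ValidationError(
                f"image too small for {n_scales}-scale VIF at scale {scale}"
            )
        mu1 = fftconvolve(src, kern, mode="valid")
        mu2 = fftconvolve(dist, kern, mode="valid")
        s1 = fftconvolve(src * src, kern, mode="valid") - mu1 * mu1
        s2 = fftconvolve(dist * dist, kern, mode="valid") - mu2 * mu2
        s12 = fftconvolve(src * dist, kern, mode="valid") - mu1 * mu2
        s1 = np.maximum(s1, 0.0)
        s2 = np.maximum(s2, 0.0)

        g = s12 / (s1 + eps)
        sv = s2 - g * s12
        # degenerate local neighbourhoods, as in the reference treatment
        g = np.where(s1 < eps, 0.0, g)
        sv = np.where(s1 < eps, s2, sv)
        s1 = np.where(s1 < eps, 0.0, s1)
        sv = np.where(s2 < eps, 0.0, np.where(g < 0, s2, sv))
        g = np.where(s2 < eps, 0.0, np.maximum(g, 0.0))
        sv = np.maximum(sv, eps)

        num += float(np.sum(np.log10(1.0 + g * g * s1 / (sv + sigma_nsq))))
        den += float(np.sum(np.log10(1.0 + s1 / sigma_nsq)))
    if den == 0.0:
        raise UndefinedMetricError(
            "VIF undefined: reference carries no information (constant image)"
        )
    return num / den


def sam(I: np.ndarray, ref: np.ndarray) -> float:
    """Spectral angle mapper in radians.

    Both images are flattened to intensity vectors; the result is the angle
    between them, arccos of the normalised dot product.  Invariant to global
    intensity scaling of either image.
    """
    I, ref = _check_pair(I, ref)
    v1 = I.ravel()
    v2 = ref.ravel()
    n1 = float(np.linalg.norm(v1))
    n2 = float(np.linalg.norm(v2))
    if n1 == 0.0 or n2 == 0.0:
        raise UndefinedMetricError("SAM undefined: zero-norm intensity vector")
    c = float(np.dot(v1, v2) / (n1 * n2))
    return float(math.acos(min(1.0, max(-1.0, c))))


def _normalised_histograms(
    I: np.ndarray, ref: np.ndarray, hist: HistogramSpec
) -> tuple[np.ndarray, np.ndarray]:
    if hist.range_policy == "fixed":
        hi = float(hist.fixed_max)
    else:
        hi = float(max(I.max(), ref.max()))
    if hi <= 0.0:
        hi = 1.0  # both images all zero: everything lands in bin 0
    p, _ = np.histogram(I, bins=hist.n_bins, range=(0.0, hi))
    q, _ = np.histogram(ref, bins=hist.n_bins, range=(0.0, hi))
    return p / p.sum(), q / q.sum()


def bhattacharyya(
    I: np.ndarray, ref: np.ndarray, hist: HistogramSpec = HistogramSpec()
) -> tuple[float, float]:
    """Bhattacharyya coefficient BC and distance BD between ROI histograms.

    BC = sum(sqrt(p*q)) in [0, 1]; BD = -ln(BC).  Identical histograms give
    (1, 0); disjoint supports give (0, inf) with the infinity flagged
    downstream.
    """
    I, ref = _check_pair(I, ref)
    p, q = _normalised_histograms(I, ref, hist)
    bc = float(np.sum(np.sqrt(p * q)))
    bc = min(bc, 1.0)
    bd = math.inf if bc == 0.0 else float(-math.log(bc))
    return bc, bd


def chi_square_distance(
    I: np.ndarray, ref: np.ndarray, hist: HistogramSpec = HistogramSpec()
) -> float:
    """Chi-square distance between ROI histograms.

    0.5 * sum((p - q)^2 / (p + q)) over bins where p + q > 0; lies in
    [0, 1] for normalised histograms and is 0 iff the histograms agree.
    """
    I, ref = _check_pair(I, ref)
    p, q = _normalised_histograms(I, ref, hist)
    mask = (p + q) > 0
    return float(0.5 * np.sum((p[mask] - q[mask]) ** 2 / (p[mask] + q[mask])))


def frobenius_norm(I: np.ndarray, ref: np.ndarray) -> float:
    """Frobenius norm of the difference image, sqrt(sum((I - ref)^2))."""
    I, ref = _check_pair(I, ref)
    return float(np.sqrt(np.sum((I - ref) ** 2)))


def weighted_jaccard(I: np.ndarray, ref: np.ndarray) -> float:
    """Weighted Jaccard similarity, sum(min(I, ref)) / sum(max(I, ref))."""
    I, ref = _check_pair(I, ref)
    denom = float(np.sum(np.maximum(I, ref)))
    if denom == 0.0:
        raise UndefinedMetricError("WJS undefined: both images are all zero")
    return float(np.sum(np.minimum(I, ref)) / denom)


def bray_curtis(I: np.ndarray, ref: np.ndarray) -> float:
    """Bray-Curtis dissimilarity, sum(|I - ref|) / sum(I + ref)."""
    I, ref = _check_pair(I, ref)
    denom = float(np.sum(I + ref))
    if denom == 0.0:
        raise UndefinedMetricError("BCD undefined: both images are all zero")
    return float(np.sum(np.abs(I - ref)) / denom)


def compute_paired_slice(
    I: np.ndarray,
    ref: np.ndarray,
    hist: HistogramSpec = HistogramSpec(),
    metrics: tuple[str, ...] = PAIRED_METRICS,
) -> dict[str, tuple[float, str]]:
    """All requested paired metrics for one ROI pair.

    Returns metric -> (value, flag).  Undefined metrics are flagged, not
    raised; infinite sentinels are flagged ``"infinite"``.
    """
    out: dict[str, tuple[float, str]] = {}
    bc_bd: tuple[float, float] | None = None

    def _get_bc_bd() -> tuple[float, float]:
        nonlocal bc_bd
        if bc_bd is None:
            bc_bd = bhattacharyya(I, ref, hist)
        return bc_bd

    for name in metrics:
        try:
            if name == "mse":
                val = mse(I, ref)
            elif name == "psnr":
                val = psnr(I, ref)
            elif name == "ssim":
                val = ssim(I, ref)
            elif name == "vif":
                val = vif(I, ref)
            elif name == "sam":
                val = sam(I, ref)
            elif name == "bc":
                val = _get_bc_bd()[0]
            elif name == "bd":
                val = _get_bc_bd()[1]
            elif name == "chi2d":
                val = chi_square_distance(I, ref, hist)
            elif name == "fn":
                val = frobenius_norm(I, ref)
            elif name == "wjs":
                val = weighted_jaccard(I, ref)
            elif name == "bcd":
                val = bray_curtis(I, ref)
            else:
                raise ValidationError(f"unknown paired metric {name!r}")
        except UndefinedMetricError:
            out[name] = (math.nan, "undefined")
            continue
        out[name] = (val, "infinite") if math.isinf(val) else (val, "")
    return out


def compute_paired(
    pair: SeriesPair,
    roi: RoiSpec = RoiSpec(),
    hist: HistogramSpec = HistogramSpec(),
    metrics: tuple[str, ...] = PAIRED_METRICS,
) -> list[SliceMetricRecord]:
    """Per-slice paired metric records for one exam.

    One record per metric per slice pair, in fixed metric order so output
    tables are byte-stable given identical inputs.  A metric undefined for
    one slice yields a flagged missing record for that slice only.
    """
    records: list[SliceMetricRecord] = []
    for idx, (ai, std) in enumerate(pair.pairs):
        I = extract_central_roi(ai, roi)
        ref = extract_central_roi(std, roi)
        for name, (val, flag) in compute_paired_slice(I, ref, hist, metrics).items():
            records.append(
                SliceMetricRecord(
                    exam_id=pair.exam_id,
                    scanner_id=pair.scanner_id,
                    slice_index=idx,
                    metric=name,
                    arm=Arm.PAIRED,
                    value=val,
                    flag=flag,
                )
            )
    return records
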