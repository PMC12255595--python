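"""No-reference image quality metrics: entropy, Tenengrad, BRISQUE.

These are computed on a single ROI, separately for the AI-based and the
standard arm, so each arm gets its own control chart.

The BRISQUE score depends on a trained quality regressor.  Published
absolute BRISQUE values come from a model trained on a natural-image
opinion database; those weights are an external artifact, so the model here
is pluggable: a versioned JSON file holds feature normalisation and
weights, and the package ships a small toy model trained on a synthetic
distortion ladder.  Within-repository trends (noisier image -> higher
score) are meaningful; absolute values are not comparable to published
BRISQUE numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.ndimage import convolve, sobel
from scipy.special import gamma as gamma_fn

from .errors import ConfigError, DegenerateInputError, ValidationError
from .types import (
    UNPAIRED_METRICS,
    Arm,
    HistogramSpec,
    ImageSlice,
    RoiSpec,
    SliceMetricRecord,
)
from .image_io import extract_central_roi

N_BRISQUE_FEATURES = 36


def _check_image(I: np.ndarray) -> np.ndarray:
    I = np.asarray(I, dtype=np.float64)
    if I.ndim != 2:
        raise ValidationError("image must be 2-D")
    if not np.all(np.isfinite(I)):
        raise ValidationError("image must be finite")
    if np.any(I < 0):
        raise ValidationError("intensities must be nonnegative")
    return I


def entropy(I: np.ndarray, hist: HistogramSpec = HistogramSpec()) -> float:
    """Shannon entropy of the intensity histogram, in bits.

    -sum(p_k * log2(p_k)) with p_k the fraction of pixels in bin k; empty
    bins contribute zero.  A constant image has entropy 0; an image with
    equal counts in all bins attains the maximum log2(n_bins).
    """
    I = _check_image(I)
    if I.size == 0:
        raise ValidationError("empty image")
    if hist.range_policy == "fixed":
        hi = float(hist.fixed_max)
        I = np.minimum(I, hi)  # clip, as fixed-depth quantisation would
    else:
        hi = float(I.max())
    if hi <= 0.0:
        return 0.0  # constant zero image: single occupied bin
    h, _ = np.histogram(I, bins=hist.n_bins, range=(0.0, hi))
    p = h[h > 0] / I.size
    return float(-np.sum(p * np.log2(p)))


def tenengrad(I: np.ndarray, operator: str = "sobel") -> float:
    """Tenengrad sharpness: mean of squared gradient magnitude.

    (1/N) * sum(gx^2 + gy^2) over interior pixels; boundary pixels, where
    the gradient stencil is truncated, are excluded from the mean.  The
    default gradient operator is the 3x3 Sobel kernel, the common choice
    for this focus measure; ``operator='central'`` uses unit-spacing
    central differences instead.
    """
    I = _check_image(I)
    if I.shape[0] < 3 or I.shape[1] < 3:
        raise ValidationError("image must be at least 3x3 for gradients")
    if operator == "sobel":
        gx = sobel(I, axis=1, mode="nearest")
        gy = sobel(I, axis=0, mode="nearest")
    elif operator == "central":
        gy, gx = np.gradient(I)
    else:
        raise ValidationError(f"unknown gradient operator {operator!r}")
    core = (slice(1, -1), slice(1, -1))
    return float(np.mean(gx[core] ** 2 + gy[core] ** 2))


# ---------------------------------------------------------------------------
# BRISQUE: MSCN coefficients + asymmetric generalised Gaussian fits
# ---------------------------------------------------------------------------

_GGD_GAMMAS = np.arange(0.2, 10.001, 0.001)
_GGD_RHO = (gamma_fn(1.0 / _GGD_GAMMAS) * gamma_fn(3.0 / _GGD_GAMMAS)) / (
    gamma_fn(2.0 / _GGD_GAMMAS) ** 2
)


def _fit_ggd(x: np.ndarray) -> tuple[float, float]:
    """Moment-matching fit of a zero-mean generalised Gaussian.

    Returns (shape, variance).  shape == 2 corresponds to a Gaussian.
    """
    sq = float(np.mean(x**2))
    ab = float(np.mean(np.abs(x)))
    if sq == 0.0 or ab == 0.0:
        raise DegenerateInputError("all-zero coefficients in GGD fit")
    rho = sq / ab**2
    shape = float(_GGD_GAMMAS[np.argmin((_GGD_RHO - rho) ** 2)])
    return shape, sq


def _fit_aggd(x: np.ndarray) -> tuple[float, float, float, float]:
    """Moment-matching fit of an asymmetric generalised Gaussian.

    Returns (shape, mean, left variance, right variance), the four BRISQUE
    features of one pairwise-product orientation.
    """
    left = x[x < 0]
    right = x[x > 0]
    if left.size == 0 or right.size == 0:
        raise DegenerateInputError("one-sided coefficients in AGGD fit")
    sigma_l = float(np.sqrt(np.mean(left**2)))
    sigma_r = float(np.sqrt(np.mean(right**2)))
    gamma_hat = sigma_l / sigma_r
    r_hat = float(np.mean(np.abs(x)) ** 2 / np.mean(x**2))
    R_hat = r_hat * (gamma_hat**3 + 1) * (gamma_hat + 1) / (gamma_hat**2 + 1) ** 2
    shape = float(_GGD_GAMMAS[np.argmin((_GGD_RHO - R_hat) ** 2)])
    const = np.sqrt(gamma_fn(1.0 / shape) / gamma_fn(3.0 / shape))
    mean = (sigma_r - sigma_l) * (
        gamma_fn(2.0 / shape) / gamma_fn(1.0 / shape)
    ) * const
    return shape, float(mean), sigma_l**2, sigma_r**2


def _mscn(I: np.ndarray, c: float = 1.0) -> np.ndarray:
    """Mean-subtracted contrast-normalised coefficients.

    Local mean and deviation come from a 7x7 Gaussian window (sigma 7/6).
    The image is first rescaled to [0, 255] so the stabilising constant c
    acts at a fixed relative level and features are invariant to global
    intensity scaling.
    """
    peak = I.max()
    if peak == I.min():
        raise DegenerateInputError("constant image: MSCN undefined")
    I = I / peak * 255.0
    ax = np.arange(7) - 3.0
    g = np.exp(-(ax**2) / (2.0 * (7.0 / 6.0) ** 2))
    kern = np.outer(g, g)
    kern /= kern.sum()
    mu = convolve(I, kern, mode="nearest")
    sigma = np.sqrt(np.abs(convolve(I * I, kern, mode="nearest") - mu * mu))
    return (I - mu) / (sigma + c)


def brisque_features(I: np.ndarray) -> np.ndarray:
    """36-element BRISQUE feature vector.

    At each of two scales (native and 2x downsampled): the GGD shape and
    variance of the MSCN coefficients (2 features) plus AGGD shape, mean,
    left variance and right variance of the four pairwise-product
    orientations — horizontal, vertical and the two diagonals (16
    features).  Deterministic, and invariant to global intensity scaling.
    """
    I = _check_image(I)
    feats: list[float] = []
    img = I
    for scale in range(2):
        if scale == 1:
            img = img[::2, ::2]
        m = _mscn(img)
        feats.extend(_fit_ggd(m.ravel()))
        for a, b in (
            (m[:, :-1], m[:, 1:]),      # horizontal neighbours
            (m[:-1, :], m[1:, :]),      # vertical
            (m[:-1, :-1], m[1:, 1:]),   # main diagonal
            (m[:-1, 1:], m[1:, :-1]),   # anti-diagonal
        ):
            feats.extend(_fit_aggd((a * b).ravel()))
    out = np.asarray(feats, dtype=np.float64)
    assert out.shape == (N_BRISQUE_FEATURES,)
    return out


@dataclass
class BrisqueModel:
    """Pluggable BRISQUE quality regressor.

    The score is a weighted mean absolute deviation of the standardised
    features from the model's pristine-image feature centre: higher means
    worse quality.  ``feature_means`` and ``feature_scales`` standardise
    the 36 features; ``weights`` weight their contributions.
    """

    feature_means: np.ndarray
    feature_scales: np.ndarray
    weights: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.feature_means = np.asarray(self.feature_means, dtype=np.float64)
        self.feature_scales = np.asarray(self.feature_scales, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        for v in (self.feature_means, self.feature_scales, self.weights):
            if v.shape != (N_BRISQUE_FEATURES,):
                raise ConfigError(
                    f"BRISQUE model vectors must have length {N_BRISQUE_FEATURES}"
                )
        if np.any(self.feature_scales <= 0):
            raise ConfigError("BRISQUE feature scales must be positive")

    @classmethod
    def load(cls, path: str | Path) -> "BrisqueModel":
        path = Path(path)
        if not path.is_file():
            raise ConfigError(f"BRISQUE model file not found: {path}")
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            feature_means=d["feature_means"],
            feature_scales=d["feature_scales"],
            weights=d["weights"],
            provenance=d.get("provenance", str(path)),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": 1,
                    "feature_means": self.feature_means.tolist(),
                    "feature_scales": self.feature_scales.tolist(),
                    "weights": self.weights.tolist(),
                    "provenance": self.provenance,
                },
                fh,
                indent=1,
            )


def default_brisque_model() -> BrisqueModel:
    """The toy model shipped with the package.

    Trained (see ``scripts/build_brisque_model.py``) on a seeded synthetic
    distortion ladder: feature centre and scales from clean phantom slices,
    unit weights.
    """
    with resources.files("reconqc.data").joinpath("brisque_toy_model.json").open() as fh:
        d = json.load(fh)
    return BrisqueModel(
        feature_means=d["feature_means"],
        feature_scales=d["feature_scales"],
        weights=d["weights"],
        provenance=d.get("provenance", "shipped toy model"),
    )


def train_toy_model(clean_images: list[np.ndarray], provenance: str = "") -> BrisqueModel:
    """Fit the toy model's feature centre and scales from pristine images.

    Scales are the per-feature SD across the clean set (floored at 1e-6 so
    standardisation never divides by zero); weights are uniform.
    """
    if len(clean_images) < 2:
        raise ValidationError("need at least 2 clean images to fit scales")
    F = np.stack([brisque_features(im) for im in clean_images])
    return BrisqueModel(
        feature_means=F.mean(axis=0),
        feature_scales=np.maximum(F.std(axis=0, ddof=1), 1e-6),
        weights=np.ones(N_BRISQUE_FEATURES),
        provenance=provenance,
    )


def brisque_score(I: np.ndarray, model: BrisqueModel | None = None) -> float:
    """BRISQUE quality score under the given (or shipped toy) model.

    Higher = worse quality.  Deterministic for a fixed image and model.
    """
    if model is None:
        model = default_brisque_model()
    f = brisque_features(I)
    z = (f - model.feature_means) / model.feature_scales
    return float(np.mean(model.weights * np.abs(z)))


def compute_unpaired_slice(
    I: np.ndarray,
    hist: HistogramSpec = HistogramSpec(),
    metrics: tuple[str, ...] = UNPAIRED_METRICS,
    brisque_model: BrisqueModel | None = None,
) -> dict[str, tuple[float, str]]:
    """All requested unpaired metrics for one ROI; metric -> (value, flag)."""
    out: dict[str, tuple[float, str]] = {}
    for name in metrics:
        try:
            if name == "entropy":
                val = entropy(I, hist)
            elif name == "tenengrad":
                val = tenengrad(I)
            elif name == "brisque":
                val = brisque_score(I, brisque_model)
            else:
                raise ValidationError(f"unknown unpaired metric {name!r}")
        except DegenerateInputError:
            out[name] = (float("nan"), "undefined")
            continue
        out[name] = (val, "")
    return out


def compute_unpaired(
    slices: list[ImageSlice],
    roi: RoiSpec = RoiSpec(),
    hist: HistogramSpec = HistogramSpec(),
    metrics: tuple[str, ...] = UNPAIRED_METRICS,
    brisque_model: BrisqueModel | None = None,
) -> list[SliceMetricRecord]:
    """Per-slice unpaired records for one arm of one exam."""
    if metrics and "brisque" in metrics and brisque_model is None:
        brisque_model = default_brisque_model()
    records: list[SliceMetricRecord] = []
    for idx, sl in enumerate(slices):
        I = extract_central_roi(sl, roi)
        for name, (val, flag) in compute_unpaired_slice(
            I, hist, metrics, brisque_model
        ).items():
            records.append(
                SliceMetricRecord(
                    exam_id=sl.exam_id,
                    scanner_id=sl.scanner_id,
                    slice_index=idx,
                    metric=name,
                    arm=sl.arm,
                    value=val,
                    flag=flag,
                )
            )
    return records
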