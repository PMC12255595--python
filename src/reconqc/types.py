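"""Core value types shared across the package.

The atomic input is an :class:`ImageSlice` — one 2-D magnitude MR image with
position and identity metadata.  Slices from the two reconstruction arms of
one exam (the AI-based reconstruction and the standard reconstruction of the
same anatomy) are matched by table position into a :class:`SeriesPair`, the
unit on which paired metrics are computed.  Per-slice metric values are
carried as :class:`SliceMetricRecord`; per-exam aggregates as
:class:`ExamStatistic`; reference statistics as :class:`Baseline`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np

from .errors import ValidationError


class Arm(str, enum.Enum):
    """Which reconstruction a slice (or record) belongs to.

    ``PAIRED`` is used on metric records only: a full-reference metric
    consumes both arms and yields a single value.
    """

    AI = "ai"
    STANDARD = "standard"
    PAIRED = "paired"


PAIRED_METRICS: tuple[str, ...] = (
    "mse",
    "psnr",
    "ssim",
    "vif",
    "sam",
    "bc",
    "bd",
    "chi2d",
    "fn",
    "wjs",
    "bcd",
)

UNPAIRED_METRICS: tuple[str, ...] = ("entropy", "tenengrad", "brisque")

ALL_METRICS: tuple[str, ...] = PAIRED_METRICS + UNPAIRED_METRICS


@dataclass
class ImageSlice:
    """One 2-D magnitude image plus the metadata needed for pairing.

    Parameters
    ----------
    pixels
        2-D array of finite, nonnegative intensities (arbitrary MR units).
    slice_position_mm
        Out-of-plane coordinate used to match slices between arms.
    exam_id, scanner_id
        Opaque identifiers; all slices of one series share both.
    arm
        Which reconstruction produced the slice.
    acquired_at
        Acquisition timestamp; orders exams chronologically on charts.
    """

    pixels: np.ndarray
    slice_position_mm: float
    exam_id: str
    scanner_id: str
    arm: Arm
    acquired_at: datetime | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"slice pixels must be 2-D, got ndim={self.pixels.ndim}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("slice pixels must be finite")
        if np.any(self.pixels < 0):
            raise ValidationError("slice pixels must be nonnegative")
        self.arm = Arm(self.arm)

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]


@dataclass
class SeriesPair:
    """Position-matched AI/standard slice pairs for one exam."""

    exam_id: str
    scanner_id: str
    pairs: list[tuple[ImageSlice, ImageSlice]]
    unmatched_ai: list[ImageSlice] = field(default_factory=list)
    unmatched_standard: list[ImageSlice] = field(default_factory=list)
    acquired_at: datetime | None = None

    @property
    def n_slices(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class RoiSpec:
    """Central region of interest on which every metric is computed.

    The default 214 x 214 px is one third of a 640 x 640 acquisition matrix
    and covers the anatomy of interest while discounting peripheral regions
    most affected by inter-series motion.
    """

    height_px: int = 214
    width_px: int = 214

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 1:
            raise ValidationError("ROI dimensions must be positive")

    @classmethod
    def third_of(cls, n_rows: int, n_cols: int | None = None) -> "RoiSpec":
        """ROI spanning the central third of each image dimension.

        ``third_of(640)`` reproduces the canonical 214 x 214 px region.
        """
        if n_cols is None:
            n_cols = n_rows
        return cls(-(-n_rows // 3), -(-n_cols // 3))  # ceil: third_of(640) -> 214


@dataclass(frozen=True)
class HistogramSpec:
    """Binning used by the histogram-based metrics (entropy, BC, BD, chi2D).

    ``joint_max`` bins both images over [0, max of both]; ``fixed`` uses an
    explicit upper bound (e.g. a nominal bit depth).  Histograms are
    normalised to sum to 1 before any histogram metric is evaluated.
    """

    n_bins: int = 256
    range_policy: str = "joint_max"
    fixed_max: float | None = None

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValidationError("n_bins must be >= 2")
        if self.range_policy not in ("joint_max", "fixed"):
            raise ValidationError(f"unknown range_policy {self.range_policy!r}")
        if self.range_policy == "fixed" and not (
            self.fixed_max is not None and self.fixed_max > 0
        ):
            raise ValidationError("fixed range policy requires fixed_max > 0")


@dataclass
class SliceMetricRecord:
    """One metric value for one slice (paired) or one slice + arm (unpaired).

    ``flag`` is empty for ordinary finite values; otherwise it names why the
    value is missing or special (``"infinite"`` for the pSNR/BD sentinels,
    ``"undefined"`` when the metric had no defined value for that slice).
    """

    exam_id: str
    scanner_id: str
    slice_index: int
    metric: str
    arm: Arm
    value: float
    flag: str = ""


@dataclass
class ExamStatistic:
    """Per-exam summary of one metric: the plotted point on a control chart."""

    exam_id: str
    scanner_id: str
    metric: str
    arm: Arm
    mean_log_value: float
    n_slices_used: int
    acquired_at: datetime | None = None


@dataclass
class Baseline:
    """Reference mean/SD for one metric (and arm); defines control limits.

    Control limits sit at ``mu +/- k * sigma`` for k in {1, 2, 3}.
    """

    metric: str
    arm: Arm
    group_key: str
    mu: float
    sigma: float
    n_exams: int
    exam_ids: list[str] = field(default_factory=list)

    def limit(self, k: float) -> tuple[float, float]:
        return self.mu - k * self.sigma, self.mu + k * self.sigma


@dataclass
class RuleViolation:
    """One control-chart rule firing.

    rule_id 1 is the +/-2 SD warning; 2 the 3-SD rule; 3 the twice-2-SD
    rule (two consecutive exams beyond the same 2-SD limit); 4 the
    four-1-SD rule (four consecutive exams beyond the same 1-SD limit).
    """

    rule_id: int
    metric: str
    arm: Arm
    exam_ids: list[str]
    side: str  # "high" or "low"
    limit_value: float
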