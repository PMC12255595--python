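"""Synthetic paired-exam cohort generator.

No image data accompany the monitoring protocol, so the full experiment —
a reference cohort to set baselines, constancy exams to chart against
them, and perturbed re-reconstructions for sensitivity testing — is
exercised on simulated exams.  Each exam is a stack of pelvis-like phantom
slices (an elliptical body, a concentric-ring structure standing in for
the rectal wall, and low-frequency tissue texture) rendered twice:

* standard arm — the phantom plus Rician noise at ``noise_sd_standard``
  (magnitude MR noise convention);
* AI arm — a mildly unsharp-masked (super-resolution-like) phantom plus
  Rician noise at the lower ``noise_sd_ai`` (denoised).

Noise SDs are expressed as fractions of the phantom tissue intensity.
Exam-to-exam anatomical variability (body size, ring size, layer contrast,
texture amplitude, overall intensity) drives the between-exam spread of
the metric statistics that the control limits are built from.

The whole cohort is a pure function of :class:`CohortConfig`: per-exam
seeds are derived from ``(master_seed, role, index)`` so cohorts are
reproducible and extensible without reshuffling.  Exams are described by
lightweight :class:`ExamRecipe` objects and rendered to pixels on demand
(``Cohort.realise``), since a fully materialised cohort at the default
640 x 640 matrix would not fit comfortably in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ValidationError
from .perturbation import RR_KINDS, PerturbationSpec, apply_perturbation
from .types import Arm, ImageSlice, SeriesPair

_ROLE_CODES = {"reference": 1, "constancy": 2, "perturbation_base": 3}

DEFAULT_SCANNERS = ("1.5T-A", "1.5T-B", "3T-A", "3T-B")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and image-model parameters of the synthetic cohort.

    Defaults mirror the monitored study: 50 reference exams, 8 constancy
    exams, 5 perturbation exams per MR system on 4 systems (each rendered
    under all three RR perturbations), 21-33 slices per exam at 3 mm
    spacing, 640 x 640 px slices.
    """

    n_reference: int = 50
    n_constancy: int = 8
    n_perturbation_per_system: int = 5
    scanner_ids: tuple[str, ...] = DEFAULT_SCANNERS
    slices_min: int = 21
    slices_max: int = 33
    image_size: int = 640
    tissue_intensity: float = 100.0
    noise_sd_standard: float = 0.05  # fraction of tissue intensity
    noise_sd_ai: float = 0.008
    ai_sharpen_amount: float = 0.4
    ai_sharpen_sigma: float = 1.0
    texture_amplitude: float = 0.30  # coarse texture, fraction of tissue
    fine_texture_amplitude: float = 0.02  # fine detail, fraction of tissue
    inter_arm_shift_px: float = 0.0  # optional motion between arms
    slice_spacing_mm: float = 3.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_reference, self.n_constancy, self.n_perturbation_per_system) < 1:
            raise ValidationError("cohort counts must be positive")
        if not (0 < self.slices_min <= self.slices_max):
            raise ValidationError("invalid slices range")
        if self.image_size < 32:
            raise ValidationError("image_size too small")
        if not (0 <= self.noise_sd_ai < self.noise_sd_standard):
            raise ValidationError(
                "noise_sd_ai must be below noise_sd_standard (the AI arm is denoised)"
            )


@dataclass(frozen=True)
class ExamRecipe:
    """Everything needed to render one exam deterministically."""

    exam_id: str
    scanner_id: str
    role: str  # reference | constancy | perturbation
    seed_index: int
    order: int  # chronological position in the cohort
    rr_kind: str | None = None


def _exam_seed(master_seed: int, role: str, index: int) -> np.random.SeedSequence:
    base_role = "perturbation_base" if role == "perturbation" else role
    return np.random.SeedSequence(
        entropy=(int(master_seed), _ROLE_CODES[base_role], int(index))
    )


def _ring_layers(
    x: np.ndarray, y: np.ndarray, ring_radius: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Soft masks of the ring's lumen, mucosa, and muscle layers.

    Layer boundaries have a fixed anatomical edge width (10-90% transition
    about 0.022 of the half-FOV, ~1 mm) so edge sharpness is a property of
    the anatomy, not of the render resolution.
    """
    r = np.sqrt((x - 0.02) ** 2 + (y - 0.12) ** 2)
    r1, r2, r3 = ring_radius * 0.4, ring_radius * 0.8, ring_radius

    def edge(r0: float) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(np.clip((r - r0) / 0.005, -60.0, 60.0)))

    lumen = edge(r1)
    inner = edge(r2) - lumen
    outer = edge(r3) - edge(r2)
    return lumen, inner, outer


def generate_phantom_slice(
    seed: int | np.random.SeedSequence,
    size: int = 640,
    tissue_intensity: float = 100.0,
    body_axes: tuple[float, float] = (0.82, 0.62),
    ring_radius: float = 0.12,
    layer_contrast: float = 1.0,
    mucosa_brightness: float = 1.0,
    texture_amplitude: float = 0.30,
    fine_texture_amplitude: float = 0.02,
) -> np.ndarray:
    """One pelvis-like phantom slice.

    An outer body ellipse at tissue intensity, a three-layer concentric
    ring standing in for the rectal wall — dark lumen, bright fluid-filled
    mucosa, darker muscle layer — and two-scale tissue texture inside the
    body: a coarse low-frequency field carrying most of the intensity
    variance (regional anatomy) plus a weaker fine-detail field
    (trabecular and vascular structure) that reconstruction filters can
    plausibly alter.  ``layer_contrast`` scales the dark layers;
    ``mucosa_brightness`` sets the bright layer separately because the
    fluid-like mucosal signal is the stable intensity peak of the slice.
    Deterministic per seed; nonnegative everywhere.
    """
    rng = np.random.default_rng(seed)
    ax = np.linspace(-1.0, 1.0, size)
    x, y = np.meshgrid(ax, ax)

    soft = size / 60.0  # edge softness in "pixels" of the unit grid

    def soft_mask(d: np.ndarray) -> np.ndarray:
        # d < 0 inside; logistic edge a few pixels wide
        return 1.0 / (1.0 + np.exp(np.clip(d * soft * 8.0, -60.0, 60.0)))

    a, b = body_axes
    body = soft_mask(np.sqrt((x / a) ** 2 + (y / b) ** 2) - 1.0)

    img = 0.02 + 0.98 * body  # relative units: background 0.02, tissue 1.0

    # concentric "rectal wall" ring slightly below centre; layer boundaries
    # have a fixed anatomical edge width (0.02 of the half-FOV) so edge
    # sharpness is a property of the anatomy, not of the render resolution
    lumen, inner, outer = _ring_layers(x, y, ring_radius)
    img = img + (
        layer_contrast * (-0.75 * lumen - 0.35 * outer)
        + mucosa_brightness * inner
    ) * body

    def unit_field(sigma: float) -> np.ndarray:
        f = gaussian_filter(rng.standard_normal((size, size)), sigma, mode="wrap")
        sd = f.std()
        return f / sd if sd > 0 else f

    # fluid layers (lumen, mucosa) are homogeneous: no tissue texture there
    tex_mask = body * (1.0 - 0.95 * (lumen + inner))
    img = img + texture_amplitude * unit_field(size / 16.0) * tex_mask
    img = img + fine_texture_amplitude * unit_field(size / 213.0) * tex_mask

    return np.clip(img, 0.0, None) * tissue_intensity


def _rician(base: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of the phantom plus complex Gaussian noise of SD ``sd``."""
    if sd == 0.0:
        return base.copy()
    n1 = rng.standard_normal(base.shape) * sd
    n2 = rng.standard_normal(base.shape) * sd
    return np.sqrt((base + n1) ** 2 + n2**2)


def generate_exam(
    seed: int | np.random.SeedSequence,
    config: CohortConfig = CohortConfig(),
    exam_id: str = "exam",
    scanner_id: str = "scanner",
    acquired_at: datetime | None = None,
) -> SeriesPair:
    """Render one paired exam: AI and standard stacks at matched positions.

    Exam-level anatomy parameters (body size, ring size, layer contrast,
    texture amplitude, intensity scale, slice count) are drawn once per
    exam; each slice perturbs the ring size and texture slightly along the
    stack.  The standard arm is the phantom plus Rician noise; the AI arm
    is the unsharp-masked phantom plus weaker Rician noise.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    size = config.image_size
    # Bounded uniform draws for the exam-level anatomy so that between-exam
    # variability dominates the charted statistics with light tails, as for
    # the patient-to-patient variation the reference band is meant to span.
    # Multiplicative parameters are drawn log-uniformly: the charted
    # statistics respond roughly linearly in the log of these amplitudes,
    # so symmetric bounded draws in log-space give symmetric, light-tailed
    # exam distributions — what a patient reference band is assumed to be.
    def logu(spread: float) -> float:
        return float(np.exp(rng.uniform(-spread, spread)))

    tissue = config.tissue_intensity * logu(0.065)
    body_axes = (rng.uniform(0.72, 0.92), rng.uniform(0.52, 0.72))
    ring_radius = 0.12 * logu(0.14)
    layer_contrast = logu(0.18)
    texture_amp = config.texture_amplitude * logu(0.30)
    fine_amp = config.fine_texture_amplitude * logu(0.25)
    noise_factor_std = logu(0.10)
    noise_factor_ai = logu(0.10)
    n_slices = int(rng.integers(config.slices_min, config.slices_max + 1))

    # Anatomy without texture, rendered once per exam; the smooth texture
    # field is also rendered once and circularly shifted per slice, which
    # is exact because its smoothing uses wrap boundaries.
    anatomy = generate_phantom_slice(
        ss.spawn(1)[0],
        size=size,
        tissue_intensity=tissue,
        body_axes=body_axes,
        ring_radius=ring_radius,
        layer_contrast=layer_contrast,
        texture_amplitude=0.0,
        fine_texture_amplitude=0.0,
    )

    def unit_field(sigma: float) -> np.ndarray:
        f = gaussian_filter(rng.standard_normal((size, size)), sigma, mode="wrap")
        return f / f.std()

    coarse = unit_field(size / 16.0)
    fine = unit_field(size / 213.0)
    ax = np.linspace(-1.0, 1.0, size)
    x, y = np.meshgrid(ax, ax)
    a, b = body_axes
    body = 1.0 / (
        1.0
        + np.exp(
            np.clip((np.sqrt((x / a) ** 2 + (y / b) ** 2) - 1.0) * size / 7.5, -60, 60)
        )
    )
    lumen, inner, _ = _ring_layers(x, y, ring_radius)
    tex_mask = body * (1.0 - 0.95 * (lumen + inner))

    def sharpen(im: np.ndarray) -> np.ndarray:
        return im + config.ai_sharpen_amount * (
            im - gaussian_filter(im, config.ai_sharpen_sigma, mode="nearest")
        )

    anatomy_ai = sharpen(anatomy)

    # unsharp masking is linear, and wrap-mode filtering commutes with roll
    def sharpen_wrap(f: np.ndarray) -> np.ndarray:
        return f + config.ai_sharpen_amount * (
            f - gaussian_filter(f, config.ai_sharpen_sigma, mode="wrap")
        )

    coarse_ai = sharpen_wrap(coarse)
    fine_ai = sharpen_wrap(fine)

    positions = (np.arange(n_slices) - (n_slices - 1) / 2.0) * config.slice_spacing_mm
    # per-exam noise level varies with coil loading and patient habitus
    sd_std = config.noise_sd_standard * tissue * noise_factor_std
    sd_ai = config.noise_sd_ai * tissue * noise_factor_ai
    shift = config.inter_arm_shift_px

    pairs: list[tuple[ImageSlice, ImageSlice]] = []
    for k, pos in enumerate(positions):
        dr, dc = (int(v) for v in rng.integers(0, size, size=2))
        roll = lambda f: np.roll(f, (dr, dc), axis=(0, 1))  # noqa: E731
        tex_k = texture_amp * roll(coarse) + fine_amp * roll(fine)
        tex_ai_k = texture_amp * roll(coarse_ai) + fine_amp * roll(fine_ai)
        intensity_mod = 1.0 + 0.02 * np.sin(np.pi * k / max(n_slices - 1, 1))
        base_std = np.clip(
            (anatomy + tissue * tex_k * tex_mask) * intensity_mod, 0.0, None
        )
        base_ai = np.clip(
            (anatomy_ai + tissue * tex_ai_k * tex_mask) * intensity_mod, 0.0, None
        )
        if shift:
            base_ai = np.roll(base_ai, int(round(shift)), axis=1)
        std_px = _rician(base_std, sd_std, rng)
        ai_px = _rician(base_ai, sd_ai, rng)
        common = dict(
            slice_position_mm=float(pos),
            exam_id=exam_id,
            scanner_id=scanner_id,
            acquired_at=acquired_at,
        )
        pairs.append(
            (
                ImageSlice(pixels=ai_px, arm=Arm.AI, **common),
                ImageSlice(pixels=std_px, arm=Arm.STANDARD, **common),
            )
        )
    return SeriesPair(
        exam_id=exam_id, scanner_id=scanner_id, pairs=pairs, acquired_at=acquired_at
    )


@dataclass
class Cohort:
    """Recipes for every exam of the study design, rendered on demand."""

    config: CohortConfig
    reference: list[ExamRecipe] = field(default_factory=list)
    constancy: list[ExamRecipe] = field(default_factory=list)
    perturbation: dict[str, list[ExamRecipe]] = field(default_factory=dict)

    def realise(
        self, recipe: ExamRecipe, perturbation_spec: PerturbationSpec | None = None
    ) -> SeriesPair:
        """Render a recipe to pixels.

        A perturbation recipe renders its held-out base exam, then applies
        the RR operator to every AI-arm slice; the standard arm is left
        untouched (re-reconstruction does not change the standard series).
        """
        seed = _exam_seed(self.config.master_seed, recipe.role, recipe.seed_index)
        acquired = datetime(2024, 1, 1) + timedelta(days=recipe.order)
        pair = generate_exam(
            seed,
            self.config,
            exam_id=recipe.exam_id,
            scanner_id=recipe.scanner_id,
            acquired_at=acquired,
        )
        if recipe.rr_kind is None:
            return pair
        spec = perturbation_spec or PerturbationSpec(kind=recipe.rr_kind)
        if spec.kind != recipe.rr_kind:
            spec = replace(spec, kind=recipe.rr_kind)
        perturbed = [
            (
                ImageSlice(
                    pixels=apply_perturbation(ai.pixels, spec),
                    slice_position_mm=ai.slice_position_mm,
                    exam_id=recipe.exam_id,
                    scanner_id=ai.scanner_id,
                    arm=Arm.AI,
                    acquired_at=ai.acquired_at,
                ),
                std,
            )
            for ai, std in pair.pairs
        ]
        return SeriesPair(
            exam_id=recipe.exam_id,
            scanner_id=recipe.scanner_id,
            pairs=perturbed,
            acquired_at=pair.acquired_at,
        )


def generate_cohort(config: CohortConfig = CohortConfig()) -> Cohort:
    """Lay out the full study design as exam recipes.

    Reference and constancy exams are assigned to scanners round-robin.
    Each scanner contributes ``n_perturbation_per_system`` held-out base
    exams; every base exam appears once per RR kind, so each perturbation
    batch re-reconstructs the same underlying exams.
    """
    scanners = config.scanner_ids
    cohort = Cohort(config=config)
    order = 0
    for i in range(config.n_reference):
        cohort.reference.append(
            ExamRecipe(
                exam_id=f"ref-{i:03d}",
                scanner_id=scanners[i % len(scanners)],
                role="reference",
                seed_index=i,
                order=order,
            )
        )
        order += 1
    for i in range(config.n_constancy):
        cohort.constancy.append(
            ExamRecipe(
                exam_id=f"con-{i:03d}",
                scanner_id=scanners[i % len(scanners)],
                role="constancy",
                seed_index=i,
                order=order,
            )
        )
        order += 1
    base_index = 0
    bases: list[tuple[int, str]] = []
    for s, scanner in enumerate(scanners):
        for _ in range(config.n_perturbation_per_system):
            bases.append((base_index, scanner))
            base_index += 1
    for kind in RR_KINDS:
        cohort.perturbation[kind] = []
        for idx, scanner in bases:
            cohort.perturbation[kind].append(
                ExamRecipe(
                    exam_id=f"per-{idx:03d}-{kind.lower()}",
                    scanner_id=scanner,
                    role="perturbation",
                    seed_index=idx,
                    order=order,
                    rr_kind=kind,
                )
            )
            order += 1
    return cohort
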