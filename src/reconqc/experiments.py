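"""Canned experiment configurations.

The sensitivity replay runs the full study design — 50 reference exams,
8 constancy exams, and 5 perturbation exams per system on 4 systems under
each RR kind — on the synthetic cohort.  To keep a replay tractable on a
single CPU it uses 256 x 256 slices with the ROI at its defined proportion
(the central third of the matrix) and restricts the metric set to the
chart-relevant representatives: MSE, pSNR and SSIM for the paired family
and entropy for the unpaired family.
"""

from __future__ import annotations

from .config import RunConfig
from .pipeline import CohortAnalysis, analyse_cohort
from .synthetic_cohort import CohortConfig
from .types import RoiSpec

REPLAY_PAIRED = ("mse", "psnr", "ssim")
REPLAY_UNPAIRED = ("entropy",)


def scaled_replay_config(master_seed: int, image_size: int = 256) -> RunConfig:
    """Configuration of the scaled sensitivity replay for one master seed."""
    return RunConfig(
        cohort=CohortConfig(image_size=image_size, master_seed=master_seed),
        roi=RoiSpec.third_of(image_size),
        paired_metrics=REPLAY_PAIRED,
        unpaired_metrics=REPLAY_UNPAIRED,
        seed=master_seed,
    )


def run_sensitivity_replay(master_seed: int, image_size: int = 256) -> CohortAnalysis:
    """Reference -> constancy -> RR1/RR2/RR3 replay for one master seed."""
    return analyse_cohort(scaled_replay_config(master_seed, image_size))


def replay_summary(analysis: CohortAnalysis) -> dict:
    """Reduce a replay to the quantities the protocol reports.

    Returns the constancy rule-2-4 violation count, the paired metrics the
    RR3 batch makes sensitive, and the RR kinds (if any) that make entropy
    sensitive.
    """
    constancy_234 = sum(
        1 for v in analysis.constancy_violations if v.rule_id in (2, 3, 4)
    )
    sens = analysis.sensitivity
    rr3_sensitive = set(
        sens.query("rr_kind == 'RR3' and arm == 'paired' and sensitive")["metric"]
    )
    entropy_sensitive_kinds = set(
        sens.query("metric == 'entropy' and sensitive")["rr_kind"]
    )
    return {
        "constancy_rule234_violations": constancy_234,
        "constancy_traffic_light": analysis.constancy_traffic_light,
        "rr3_sensitive_paired": rr3_sensitive,
        "entropy_sensitive_kinds": entropy_sensitive_kinds,
    }
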