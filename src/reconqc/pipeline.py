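"""End-to-end analysis: metrics -> exam statistics -> charts -> verdicts.

Glue between the metric modules and the control-chart module, operating on
the synthetic cohort (or any iterable of :class:`SeriesPair`).  Exams are
rendered and reduced one at a time so the pixel data of at most one exam
is alive at any moment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import control_charts as cc
from .config import RunConfig
from .paired_metrics import compute_paired
from .perturbation import RR_KINDS, PerturbationSpec
from .synthetic_cohort import Cohort, generate_cohort
from .types import Arm, Baseline, ExamStatistic, RuleViolation, SeriesPair, SliceMetricRecord
from .unpaired_metrics import BrisqueModel, compute_unpaired, default_brisque_model

REPORT_SCHEMA_VERSION = 1


def compute_exam_records(
    pair: SeriesPair,
    config: RunConfig,
    brisque_model: BrisqueModel | None = None,
) -> list[SliceMetricRecord]:
    """All per-slice records (paired + both unpaired arms) for one exam."""
    records = compute_paired(pair, config.roi, config.hist, config.paired_metrics)
    if config.unpaired_metrics:
        ai = [a for a, _ in pair.pairs]
        std = [s for _, s in pair.pairs]
        hist = config.entropy_hist or config.hist
        records += compute_unpaired(
            ai, config.roi, hist, config.unpaired_metrics, brisque_model
        )
        records += compute_unpaired(
            std, config.roi, hist, config.unpaired_metrics, brisque_model
        )
    return records


def exam_statistics(
    pair: SeriesPair,
    config: RunConfig,
    brisque_model: BrisqueModel | None = None,
) -> tuple[list[ExamStatistic], list[SliceMetricRecord]]:
    """Log-transformed per-exam statistics (and raw records) for one exam."""
    records = compute_exam_records(pair, config, brisque_model)
    logged = cc.log_transform(records, config.log_skip_metrics)
    stats = cc.summarise_exams(
        logged,
        statistic=config.exam_statistic,
        acquired_at_by_exam={pair.exam_id: pair.acquired_at},
    )
    return stats, records


def records_to_frame(records: list[SliceMetricRecord]) -> pd.DataFrame:
    """Tidy per-slice table: exam_id, scanner_id, slice_index, metric, arm, value, flag."""
    return pd.DataFrame(
        {
            "exam_id": [r.exam_id for r in records],
            "scanner_id": [r.scanner_id for r in records],
            "slice_index": [r.slice_index for r in records],
            "metric": [r.metric for r in records],
            "arm": [r.arm.value for r in records],
            "value": [r.value for r in records],
            "flag": [r.flag for r in records],
        }
    )


def stats_to_frame(stats: list[ExamStatistic]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "exam_id": [s.exam_id for s in stats],
            "scanner_id": [s.scanner_id for s in stats],
            "metric": [s.metric for s in stats],
            "arm": [s.arm.value for s in stats],
            "mean_log_value": [s.mean_log_value for s in stats],
            "n_slices_used": [s.n_slices_used for s in stats],
            "acquired_at": [
                s.acquired_at.isoformat() if s.acquired_at else "" for s in stats
            ],
        }
    )


def write_frame(df: pd.DataFrame, path) -> None:
    """CSV writer with a fixed float format so reruns are byte-identical."""
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def violations_to_dicts(violations: list[RuleViolation]) -> list[dict]:
    return [
        {
            "rule_id": v.rule_id,
            "metric": v.metric,
            "arm": v.arm.value,
            "exam_ids": list(v.exam_ids),
            "side": v.side,
            "limit_value": v.limit_value,
        }
        for v in violations
    ]


def baseline_to_dict(b: Baseline) -> dict:
    return {
        "metric": b.metric,
        "arm": b.arm.value,
        "group_key": b.group_key,
        "mu": b.mu,
        "sigma": b.sigma,
        "n_exams": b.n_exams,
        "exam_ids": list(b.exam_ids),
    }


def baseline_from_dict(d: dict) -> Baseline:
    return Baseline(
        metric=d["metric"],
        arm=Arm(d["arm"]),
        group_key=d["group_key"],
        mu=float(d["mu"]),
        sigma=float(d["sigma"]),
        n_exams=int(d["n_exams"]),
        exam_ids=list(d.get("exam_ids", [])),
    )


@dataclass
class CohortAnalysis:
    """Everything the reference -> constancy -> perturbation replay yields."""

    config: RunConfig
    reference_stats: list[ExamStatistic] = field(default_factory=list)
    reference_records: list[SliceMetricRecord] = field(default_factory=list)
    baselines: dict[tuple[str, str], Baseline] = field(default_factory=dict)
    constancy_stats: list[ExamStatistic] = field(default_factory=list)
    constancy_violations: list[RuleViolation] = field(default_factory=list)
    perturbation_stats: dict[str, list[ExamStatistic]] = field(default_factory=dict)
    sensitivity: pd.DataFrame | None = None

    def baseline_for(self, metric: str, arm: Arm | str) -> Baseline:
        return self.baselines[(metric, Arm(arm).value)]

    @property
    def constancy_traffic_light(self) -> str:
        return cc.traffic_light(self.constancy_violations)


def _group_stats(stats: list[ExamStatistic]) -> dict[tuple[str, str], list[ExamStatistic]]:
    groups: dict[tuple[str, str], list[ExamStatistic]] = {}
    for s in stats:
        groups.setdefault((s.metric, s.arm.value), []).append(s)
    return groups


def _batch_stats(
    cohort: Cohort,
    recipes,
    config: RunConfig,
    brisque_model: BrisqueModel | None,
    perturbation_spec: PerturbationSpec | None = None,
    keep_records: bool = False,
) -> tuple[list[ExamStatistic], list[SliceMetricRecord]]:
    stats: list[ExamStatistic] = []
    records: list[SliceMetricRecord] = []
    for recipe in recipes:
        pair = cohort.realise(recipe, perturbation_spec)
        s, r = exam_statistics(pair, config, brisque_model)
        stats.extend(s)
        if keep_records:
            records.extend(r)
    return stats, records


def analyse_cohort(
    config: RunConfig,
    rr_kinds: tuple[str, ...] = RR_KINDS,
    keep_records: bool = False,
) -> CohortAnalysis:
    """Run the full synthetic experiment for one configuration.

    1. Render the reference exams, chart their per-exam statistics, and
       build a pooled baseline per metric and arm.
    2. Chart the constancy exams against those baselines and collect rule
       violations.
    3. For each requested RR kind, chart the perturbed batch and tabulate
       which metrics the batch makes *sensitive* (any rule 2-4 firing).
    """
    brisque_model = (
        default_brisque_model() if "brisque" in config.unpaired_metrics else None
    )
    cohort = generate_cohort(config.cohort)
    out = CohortAnalysis(config=config)

    out.reference_stats, out.reference_records = _batch_stats(
        cohort, cohort.reference, config, brisque_model, keep_records=keep_records
    )
    baselines = cc.build_baseline(out.reference_stats, grouping=config.baseline_grouping)
    out.baselines = {(b.metric, b.arm.value): b for b in baselines}

    out.constancy_stats, _ = _batch_stats(
        cohort, cohort.constancy, config, brisque_model
    )
    for key, stats in _group_stats(out.constancy_stats).items():
        if key in out.baselines:
            out.constancy_violations.extend(
                cc.evaluate_rules(
                    out.baselines[key], stats, always_on=config.rules_always_on
                )
            )

    rows = []
    for kind in rr_kinds:
        spec = PerturbationSpec(kind=kind, **config.perturbation_params)
        stats, _ = _batch_stats(
            cohort, cohort.perturbation[kind], config, brisque_model, spec
        )
        out.perturbation_stats[kind] = stats
        for key, batch in _group_stats(stats).items():
            if key not in out.baselines:
                continue
            sensitive, violations = cc.assess_sensitivity(
                out.baselines[key], batch, always_on=config.rules_always_on
            )
            rows.append(
                {
                    "metric": key[0],
                    "arm": key[1],
                    "rr_kind": kind,
                    "sensitive": sensitive,
                    "rules_fired": ",".join(
                        sorted({str(v.rule_id) for v in violations if v.rule_id > 1})
                    ),
                    "n_rule1": sum(1 for v in violations if v.rule_id == 1),
                }
            )
    if rows:
        out.sensitivity = (
            pd.DataFrame(rows)
            .sort_values(["metric", "arm", "rr_kind"])
            .reset_index(drop=True)
        )
    return out
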