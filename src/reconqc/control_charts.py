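"""Shewhart control charting of per-exam metric statistics.

Per-slice metric values are natural-log transformed (to bring the skewed
metric distributions closer to normal), averaged within each exam, and the
per-exam means are charted against control limits derived from a reference
cohort: mu +/- k*sigma for k in {1, 2, 3}, with mu and sigma the mean and
sample SD of the reference exam means.

Four rules are evaluated on each monitored exam:

1. warning — the exam mean exceeds mu +/- 2 SD; triggers rules 2-4;
2. 3-SD rule — the exam mean exceeds mu +/- 3 SD;
3. twice 2-SD rule — two consecutive exams beyond the same 2-SD limit;
4. four 1-SD rule — four consecutive exams beyond the same 1-SD limit.

Rules 2-4 are reported only where rule 1 has fired (they are escalations of
the warning); ``always_on=True`` evaluates them unconditionally for
research use.  A metric is deemed *sensitive* to a perturbation when any of
rules 2-4 fires on the perturbed batch.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

from .errors import (
    DegenerateBaselineError,
    InsufficientBaselineError,
    ValidationError,
)
from .types import Arm, Baseline, ExamStatistic, RuleViolation, SliceMetricRecord

POOLED_GROUP = "pooled"


def log_transform(
    records: list[SliceMetricRecord],
    skip_metrics: tuple[str, ...] = (),
) -> list[SliceMetricRecord]:
    """Natural log of each record value.

    Nonpositive values and infinite sentinels cannot be charted on the log
    scale; they become flagged missing records rather than errors, so one
    pathological slice never aborts an exam.  Metrics listed in
    ``skip_metrics`` pass through untouched.
    """
    out: list[SliceMetricRecord] = []
    for r in records:
        if r.metric in skip_metrics:
            out.append(r)
            continue
        if r.flag or not math.isfinite(r.value) or r.value <= 0.0:
            flag = r.flag or ("nonpositive" if r.value <= 0.0 else "undefined")
            out.append(
                SliceMetricRecord(
                    r.exam_id, r.scanner_id, r.slice_index, r.metric, r.arm,
                    float("nan"), flag,
                )
            )
        else:
            out.append(
                SliceMetricRecord(
                    r.exam_id, r.scanner_id, r.slice_index, r.metric, r.arm,
                    math.log(r.value), "",
                )
            )
    return out


def summarise_exam(
    records: list[SliceMetricRecord],
    statistic: str = "mean",
    acquired_at=None,
) -> ExamStatistic:
    """Per-exam statistic of the finite per-slice values of one metric+arm.

    The default statistic is the arithmetic mean of the (log) values; a
    median mode is available.  Flagged missing slices are excluded and
    ``n_slices_used`` records how many slices contributed.
    """
    if not records:
        raise ValidationError("no records to summarise")
    keys = {(r.exam_id, r.scanner_id, r.metric, r.arm) for r in records}
    if len(keys) != 1:
        raise ValidationError(f"records mix exams/metrics/arms: {keys}")
    exam_id, scanner_id, metric, arm = next(iter(keys))
    vals = np.array(
        [r.value for r in records if not r.flag and math.isfinite(r.value)]
    )
    if vals.size == 0:
        raise ValidationError(
            f"no finite values for {metric}/{arm} in exam {exam_id}"
        )
    if statistic == "mean":
        stat = float(vals.mean())
    elif statistic == "median":
        stat = float(np.median(vals))
    else:
        raise ValidationError(f"unknown statistic {statistic!r}")
    return ExamStatistic(
        exam_id=exam_id,
        scanner_id=scanner_id,
        metric=metric,
        arm=arm,
        mean_log_value=stat,
        n_slices_used=int(vals.size),
        acquired_at=acquired_at,
    )


def summarise_exams(
    records: list[SliceMetricRecord],
    statistic: str = "mean",
    acquired_at_by_exam: dict[str, object] | None = None,
) -> list[ExamStatistic]:
    """Group mixed records by (exam, metric, arm) and summarise each group.

    Exam order follows first appearance in ``records``, which callers keep
    chronological.
    """
    groups: dict[tuple, list[SliceMetricRecord]] = defaultdict(list)
    order: list[tuple] = []
    for r in records:
        key = (r.exam_id, r.metric, r.arm)
        if key not in groups:
            order.append(key)
        groups[key].append(r)
    acquired_at_by_exam = acquired_at_by_exam or {}
    out = []
    for key in order:
        recs = groups[key]
        if all(r.flag or not math.isfinite(r.value) for r in recs):
            continue  # metric undefined for the whole exam: no chart point
        out.append(
            summarise_exam(recs, statistic, acquired_at_by_exam.get(key[0]))
        )
    return out


def build_baseline(
    exam_stats: list[ExamStatistic],
    grouping: str = POOLED_GROUP,
) -> list[Baseline]:
    """Reference baselines from the exam statistics of the reference cohort.

    One baseline per (metric, arm) — pooled across scanners by default,
    matching a single reference band per chart — or per (metric, arm,
    scanner) with ``grouping='scanner'``.  mu is the mean and sigma the
    sample SD (n-1 denominator) of the exam means, which matches charting
    the per-exam statistic rather than pooled slices.
    """
    if grouping not in (POOLED_GROUP, "scanner"):
        raise ValidationError(f"unknown grouping {grouping!r}")
    groups: dict[tuple, list[ExamStatistic]] = defaultdict(list)
    for s in exam_stats:
        gk = POOLED_GROUP if grouping == POOLED_GROUP else s.scanner_id
        groups[(s.metric, s.arm, gk)].append(s)
    baselines = []
    for (metric, arm, gk), stats in groups.items():
        if len(stats) < 2:
            raise InsufficientBaselineError(
                f"baseline for {metric}/{arm}/{gk} needs >= 2 exams, got {len(stats)}"
            )
        # membership order is the (chronological) input order
        vals = np.array([s.mean_log_value for s in stats])
        baselines.append(
            Baseline(
                metric=metric,
                arm=arm,
                group_key=gk,
                mu=float(vals.mean()),
                sigma=float(vals.std(ddof=1)),
                n_exams=len(stats),
                exam_ids=[s.exam_id for s in stats],
            )
        )
    return baselines


def evaluate_rules(
    baseline: Baseline,
    exam_stats: list[ExamStatistic],
    always_on: bool = False,
) -> list[RuleViolation]:
    """Apply the four chart rules to a chronological exam sequence.

    ``exam_stats`` must be in chronological order for one metric+arm (and
    one scanner group, if grouped).  Rule 1 is reported for every exam
    beyond the 2-SD limits.  Rules 2-4 are evaluated at exams where rule 1
    fired (or at every exam with ``always_on``): rule 2 beyond 3 SD; rule 3
    when this and the previous exam are beyond the same-side 2-SD limit;
    rule 4 when this and the three previous exams are beyond the same-side
    1-SD limit.
    """
    if baseline.sigma == 0.0:
        raise DegenerateBaselineError(
            f"baseline sigma is zero for {baseline.metric}/{baseline.arm.value}"
        )
    for s in exam_stats:
        if s.metric != baseline.metric or s.arm != baseline.arm:
            raise ValidationError(
                f"exam stat {s.metric}/{s.arm} does not match baseline "
                f"{baseline.metric}/{baseline.arm}"
            )
    mu, sd = baseline.mu, baseline.sigma
    z = [(s.mean_log_value - mu) / sd for s in exam_stats]
    ids = [s.exam_id for s in exam_stats]

    def side(i: int) -> str:
        return "high" if z[i] > 0 else "low"

    violations: list[RuleViolation] = []
    for i in range(len(z)):
        rule1 = abs(z[i]) > 2.0
        if rule1:
            violations.append(
                RuleViolation(
                    1, baseline.metric, baseline.arm, [ids[i]], side(i),
                    mu + (2.0 * sd if z[i] > 0 else -2.0 * sd),
                )
            )
        if not (rule1 or always_on):
            continue
        if abs(z[i]) > 3.0:
            violations.append(
                RuleViolation(
                    2, baseline.metric, baseline.arm, [ids[i]], side(i),
                    mu + (3.0 * sd if z[i] > 0 else -3.0 * sd),
                )
            )
        sgn = 1.0 if z[i] > 0 else -1.0
        if i >= 1 and all(sgn * z[j] > 2.0 for j in (i - 1, i)):
            violations.append(
                RuleViolation(
                    3, baseline.metric, baseline.arm, ids[i - 1 : i + 1], side(i),
                    mu + sgn * 2.0 * sd,
                )
            )
        if i >= 3 and all(sgn * z[j] > 1.0 for j in range(i - 3, i + 1)):
            violations.append(
                RuleViolation(
                    4, baseline.metric, baseline.arm, ids[i - 3 : i + 1], side(i),
                    mu + sgn * 1.0 * sd,
                )
            )
    return violations


def assess_sensitivity(
    baseline: Baseline,
    perturbed_stats: list[ExamStatistic],
    always_on: bool = False,
) -> tuple[bool, list[RuleViolation]]:
    """Is a metric sensitive to a perturbation batch?

    Sensitive iff at least one rule 2-4 violation fires within the batch.
    """
    violations = evaluate_rules(baseline, perturbed_stats, always_on=always_on)
    sensitive = any(v.rule_id in (2, 3, 4) for v in violations)
    return sensitive, violations


def traffic_light(violations: list[RuleViolation]) -> str:
    """Traffic-light status of a chart window.

    green = no rule fired (acceptable); yellow = only the 2-SD warning
    (continue with closer monitoring); red = any rule 2-4 (immediate
    investigation).
    """
    if any(v.rule_id in (2, 3, 4) for v in violations):
        return "red"
    if any(v.rule_id == 1 for v in violations):
        return "yellow"
    return "green"
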