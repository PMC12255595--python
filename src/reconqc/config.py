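"""Run configuration: one validated object driving every pipeline command.

The configuration is serialised (YAML) into every output directory so any
result can be reproduced from the artefacts alone.  All randomness flows
from the single ``seed`` via the cohort's master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .synthetic_cohort import CohortConfig
from .types import PAIRED_METRICS, UNPAIRED_METRICS, HistogramSpec, RoiSpec


@dataclass
class RunConfig:
    """Everything a pipeline command needs.

    ``perturbation_params`` holds strength overrides passed to
    :class:`~reconqc.perturbation.PerturbationSpec` for each RR kind.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    roi: RoiSpec = field(default_factory=RoiSpec)
    hist: HistogramSpec = field(default_factory=HistogramSpec)
    # Entropy is charted longitudinally, so its histogram uses a *fixed*
    # intensity range (8-bit-style quantisation over a stable ceiling)
    # rather than the per-image maximum, whose sampling noise would leak
    # into the chart.  None -> 256 bins over [0, 4 x tissue intensity].
    entropy_hist: HistogramSpec | None = None
    paired_metrics: tuple[str, ...] = PAIRED_METRICS
    unpaired_metrics: tuple[str, ...] = UNPAIRED_METRICS
    log_skip_metrics: tuple[str, ...] = ()
    exam_statistic: str = "mean"
    baseline_grouping: str = "pooled"
    rules_always_on: bool = False
    perturbation_params: dict = field(default_factory=dict)
    output_dir: str = "reconqc_out"
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.paired_metrics) - set(PAIRED_METRICS)
        unknown |= set(self.unpaired_metrics) - set(UNPAIRED_METRICS)
        if unknown:
            raise ConfigError(f"unknown metrics in config: {sorted(unknown)}")
        if self.exam_statistic not in ("mean", "median"):
            raise ConfigError(f"unknown exam statistic {self.exam_statistic!r}")
        if self.baseline_grouping not in ("pooled", "scanner"):
            raise ConfigError(f"unknown grouping {self.baseline_grouping!r}")
        # the run seed is the cohort master seed unless set explicitly
        if self.seed != self.cohort.master_seed:
            self.cohort = dataclasses.replace(self.cohort, master_seed=self.seed)
        if self.entropy_hist is None:
            self.entropy_hist = HistogramSpec(
                n_bins=256,
                range_policy="fixed",
                fixed_max=4.0 * self.cohort.tissue_intensity,
            )

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["paired_metrics"] = list(self.paired_metrics)
        d["unpaired_metrics"] = list(self.unpaired_metrics)
        d["log_skip_metrics"] = list(self.log_skip_metrics)
        d["cohort"]["scanner_ids"] = list(self.cohort.scanner_ids)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        try:
            if "cohort" in d:
                c = dict(d["cohort"])
                if "scanner_ids" in c:
                    c["scanner_ids"] = tuple(c["scanner_ids"])
                d["cohort"] = CohortConfig(**c)
            if "roi" in d:
                d["roi"] = RoiSpec(**d["roi"])
            if "hist" in d:
                d["hist"] = HistogramSpec(**d["hist"])
            if d.get("entropy_hist") is not None:
                d["entropy_hist"] = HistogramSpec(**d["entropy_hist"])
            for key in ("paired_metrics", "unpaired_metrics", "log_skip_metrics"):
                if key in d:
                    d[key] = tuple(d[key])
            return cls(**d)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid run configuration: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.is_file():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Short stable hash of the configuration, for log provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
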