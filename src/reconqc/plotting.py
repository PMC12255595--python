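"""Control-chart plots.

One chart per metric (and arm): per-exam statistics in chronological
order, a solid line at the reference mean, dashed lines at the +/-2 SD
control limits, dotted lines at +/-1 and +/-3 SD, and a vertical separator
between the reference set and the monitored exams.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .types import Baseline, ExamStatistic


def plot_control_chart(
    baseline: Baseline,
    reference_stats: list[ExamStatistic],
    monitored_stats: list[ExamStatistic] | None = None,
    path: str | Path | None = None,
    title: str | None = None,
):
    """Render one control chart; returns the figure (saved if ``path``)."""
    monitored_stats = monitored_stats or []
    fig, ax = plt.subplots(figsize=(8, 3.2))
    n_ref = len(reference_stats)
    xs_ref = range(1, n_ref + 1)
    xs_mon = range(n_ref + 1, n_ref + len(monitored_stats) + 1)
    ax.plot(
        list(xs_ref),
        [s.mean_log_value for s in reference_stats],
        "o",
        ms=3,
        color="tab:blue",
        label="reference",
    )
    if monitored_stats:
        ax.plot(
            list(xs_mon),
            [s.mean_log_value for s in monitored_stats],
            "s",
            ms=4,
            color="tab:orange",
            label="monitored",
        )
        ax.axvline(n_ref + 0.5, color="k", lw=0.8)
    ax.axhline(baseline.mu, color="tab:green", lw=1.2)
    for k, style in ((1, ":"), (2, "--"), (3, ":")):
        lo, hi = baseline.limit(k)
        ax.axhline(lo, color="tab:red" if k > 1 else "gray", ls=style, lw=0.8)
        ax.axhline(hi, color="tab:red" if k > 1 else "gray", ls=style, lw=0.8)
    ax.set_xlabel("exam (chronological)")
    ax.set_ylabel(f"mean ln {baseline.metric} [{baseline.arm.value}]")
    ax.set_title(title or f"{baseline.metric} ({baseline.arm.value})")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_relative_difference(diff_pct, path: str | Path | None = None, title: str = ""):
    """Percent difference map in the style of perturbation comparison panels."""
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(diff_pct, cmap="inferno", vmin=0)
    fig.colorbar(im, ax=ax, label="|original - perturbed| / max(original) [%]")
    ax.set_title(title)
    ax.axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
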