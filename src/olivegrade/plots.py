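"""Optional report plots: ROC curves and per-sample probability strips."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .cascade import EvaluationReport

__all__ = ["plot_roc", "plot_probability_strip", "save_report_plots"]


def plot_roc(report: EvaluationReport, ax=None):
    """External-validation ROC curves of both stages, with AUC in the
    legend."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    for stage in ("stage1", "stage2"):
        block = report.stages[stage]["external"]
        roc = block["roc"]
        ax.plot(roc["fpr"], roc["tpr"], label=f"{stage} (AUC {block['auc']:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"strategy {report.strategy.value}")
    ax.legend(loc="lower right", fontsize=8)
    return ax


def plot_probability_strip(report: EvaluationReport, ax=None):
    """P(correct class) per sample for cross-validation and external sets;
    samples below the 0.5 line are the misgrouped/uncertain ones."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    offset = 0
    for sset, marker in (("cross_validation", "o"), ("external", "s")):
        probs = list(report.probabilities[sset].values())
        x = range(offset, offset + len(probs))
        ax.scatter(x, probs, s=10, marker=marker, label=sset.replace("_", " "))
        offset += len(probs)
    ax.axhline(0.5, color="k", lw=0.8, ls="--")
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("sample")
    ax.set_ylabel("P(correct class)")
    ax.set_title(f"strategy {report.strategy.value}")
    ax.legend(fontsize=8)
    return ax


def save_report_plots(report: EvaluationReport, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, fn in (("roc", plot_roc), ("probabilities", plot_probability_strip)):
        ax = fn(report)
        path = directory / f"{report.strategy.value.lower()}_{name}.png"
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
        written.append(path)
    return written
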