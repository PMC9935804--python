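"""Diagnostic plots for evaluation reports (matplotlib, Agg backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .modeling import EvalReport  # noqa: E402

__all__ = ["plot_roc", "plot_precision_sensitivity"]


def plot_roc(report: EvalReport, path, title: str = "MC prediction ROC") -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(report.roc["fpr"], report.roc["tpr"], color="tab:blue",
            label=f"AUC = {report.auc:.2f}")
    if report.auc_sd is not None:
        ax.fill_between(report.roc["fpr"],
                        (report.roc["tpr"] - report.auc_sd).clip(0, 1),
                        (report.roc["tpr"] + report.auc_sd).clip(0, 1),
                        color="tab:blue", alpha=0.2, lw=0)
    ax.plot([0, 1], [0, 1], ls="--", color="gray", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(title)
    ax.legend(loc="lower right", frameon=False)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)


def plot_precision_sensitivity(report: EvalReport, path,
                               title: str = "Precision vs sensitivity") -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(report.pr["recall"], report.pr["precision"], color="tab:orange")
    for name, marker in (("precision_favoring", "^"), ("sensitivity_favoring", "v")):
        cm = report.confusion[name]
        ax.plot(cm["sensitivity"], cm["precision"], marker, color="black",
                label=name.replace("_", " "))
    ax.set_xlabel("sensitivity (recall)")
    ax.set_ylabel("precision (PPV)")
    ax.set_xlim(0, 1.02)
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend(loc="lower left", frameon=False)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)
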