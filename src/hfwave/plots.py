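"""Optional figures: ReliefF weight bars and per-model metric radar.

Matplotlib is imported lazily so the core pipeline has no plotting
dependency.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .classify import EvaluationReport
from .relieff import ReliefFWeights

__all__ = ["plot_feature_weights", "plot_metric_radar"]


def plot_feature_weights(w: ReliefFWeights, path: str | Path,
                         title: str = "ReliefF feature weights") -> None:
    """Horizontal bar chart of per-feature relevance weights, ranked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.argsort(w.weights)
    names = [w.feature_names[i] for i in order]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(names) + 1.2))
    ax.barh(names, w.weights[order], color="#33639c")
    ax.set_xlabel("weight")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_metric_radar(reports: list[EvaluationReport], path: str | Path,
                      title: str = "Classifier performance") -> None:
    """Radar plot of the six metrics, one polygon per classifier."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = ["accuracy", "sensitivity", "specificity", "precision", "auc", "f1"]
    angles = np.linspace(0, 2 * np.pi, len(metrics), endpoint=False)
    angles = np.concatenate([angles, angles[:1]])
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    for r in reports:
        row = r.as_row()
        vals = [row[m] for m in metrics]
        vals.append(vals[0])
        ax.plot(angles, vals, label=r.model_name, linewidth=1.2)
    ax.set_xticks(angles[:-1])
    ax.set_xticklabels(metrics)
    ax.set_ylim(0, 1)
    ax.set_title(title)
    ax.legend(loc="upper right", bbox_to_anchor=(1.35, 1.1), fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
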