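"""Optional figures: linkage metrics by threshold and a forest plot of hazard
ratios. Matplotlib is imported lazily so headless pipelines never touch it."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_metrics_by_threshold(metrics: pd.DataFrame, path=None):
    """Line plot of sensitivity, PPV and false-match rate across thresholds.

    ``metrics`` is the per-threshold table with columns threshold,
    sensitivity, ppv, false_match_rate.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(metrics))
    for col, label in (("sensitivity", "Sensitivity"), ("ppv", "PPV"),
                       ("false_match_rate", "False-match rate")):
        ax.plot(x, metrics[col], marker="o", label=label)
    ax.set_xticks(x, metrics["threshold"])
    ax.set_xlabel("Match score threshold")
    ax.set_ylabel("Proportion")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_hr_forest(report_frame: pd.DataFrame, path=None):
    """Forest-style plot of the modality hazard ratio (95% CI) per dataset.

    ``report_frame`` is ``ThresholdReport.to_frame()`` output.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report_frame.dropna(subset=["hr"])
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(df) + 1.5))
    y = np.arange(len(df))[::-1]
    ax.errorbar(
        df["hr"], y,
        xerr=[df["hr"] - df["ci_low"], df["ci_high"] - df["hr"]],
        fmt="s", color="black", capsize=3,
    )
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(y, df["threshold"])
    ax.set_xscale("log")
    ax.set_xlabel("Hazard ratio (clinic vs sero-survey), 95% CI")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
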