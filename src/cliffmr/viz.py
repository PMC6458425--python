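"""Data-first plotting helpers.

Every figure has a TSV behind it (the DataFrames these functions accept
are exactly what the analysis functions return and the pipeline writes);
plots are a thin presentation layer and never the primary output.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_quantile_summary(summary: pd.DataFrame, path: str | Path,
                          xlabel: str = "genetic score quantile",
                          ylabel: str = "mean outcome") -> None:
    """Mean outcome per score bin with 95% CI error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    yerr = summary["mean_outcome"] - summary["ci_low"]
    ax.errorbar(summary["bin"], summary["mean_outcome"], yerr=yerr,
                fmt="o", capsize=3)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_xticks(summary["bin"])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_removal_scan(scan: pd.DataFrame, path: str | Path,
                      ylabel: str = "score coefficient") -> None:
    """Scan coefficient (with CI band) against the removal fraction."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.fill_between(scan["removal_fraction"], scan["ci_low"], scan["ci_high"],
                    alpha=0.25)
    ax.plot(scan["removal_fraction"], scan["beta"], marker="o")
    ax.axhline(0, lw=0.8, color="grey")
    ax.set_xlabel("fraction of top scores removed")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
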