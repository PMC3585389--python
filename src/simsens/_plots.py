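"""Best-effort matplotlib figures for each analysis technique.

Plot generation never gates tabular output: callers wrap these in
try/except and log failures.  Aesthetics are utilitarian.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .atest import DEFAULT_THRESHOLDS

_THRESHOLD_STYLE = dict(color="0.4", linestyle="--", linewidth=0.8)


def _threshold_lines(ax) -> None:
    for label, level in (
        ("large", DEFAULT_THRESHOLDS.large),
        ("medium", DEFAULT_THRESHOLDS.medium),
        ("small", DEFAULT_THRESHOLDS.small),
    ):
        ax.axhline(level, **_THRESHOLD_STYLE)
        ax.annotate(label, (0.99, level), xycoords=("axes fraction", "data"),
                    fontsize=7, ha="right", va="bottom", color="0.4")


def plot_consistency_scores(scores: pd.DataFrame, size: int, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for response in scores.columns:
        ax.plot(scores.index, scores[response], marker="o", label=response)
    _threshold_lines(ax)
    ax.set_xlabel("result subset (vs subset 1)")
    ax.set_ylabel("A-Test score (folded)")
    ax.set_ylim(0.45, 1.02)
    ax.set_title(f"Aleatory variation at sample size {size}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_max_scores(max_scores: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for response in max_scores.columns:
        ax.plot(max_scores.index, max_scores[response], marker="o", label=response)
    _threshold_lines(ax)
    ax.set_xscale("log")
    ax.set_xlabel("sample size (runs per subset)")
    ax.set_ylabel("maximum A-Test score")
    ax.set_ylim(0.45, 1.02)
    ax.set_title("Maximum aleatory effect vs sample size")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_robustness_scores(scores: pd.DataFrame, parameter: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for response, group in scores.groupby("response"):
        group = group.sort_values("value")
        ax.plot(group["value"], group["a_normalised"], marker="o", label=response)
    _threshold_lines(ax)
    ax.set_xlabel(parameter)
    ax.set_ylabel("A-Test score vs baseline (folded)")
    ax.set_ylim(0.45, 1.02)
    ax.set_title(f"Robustness to perturbation of {parameter}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_lhs_scatter(
    values, medians, parameter: str, response: str, coefficient: float, path: Path
) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(values, medians, s=8, alpha=0.6)
    ax.set_xlabel(parameter)
    ax.set_ylabel(f"median {response}")
    ax.set_title(f"{response} vs {parameter}  (PRCC = {coefficient:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_efast_indices(summary: pd.DataFrame, response: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(summary))
    width = 0.38
    ax.bar(x - width / 2, summary["Si_mean"], width, yerr=summary["Si_se"],
           capsize=3, color="black", label="Si")
    ax.bar(x + width / 2, summary["STi_mean"], width, yerr=summary["STi_se"],
           capsize=3, color="0.6", label="STi")
    ax.set_xticks(x)
    ax.set_xticklabels(summary["parameter"], rotation=30, ha="right", fontsize=8)
    ax.set_ylabel("sensitivity index")
    ax.set_title(f"eFAST variance partition: {response}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
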