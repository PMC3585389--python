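"""Consistency (aleatory) analysis: how many replicate runs are enough?

Stochastic simulations produce different results on every run even at
fixed parameter values.  This technique quantifies that run-to-run
(aleatory) variation and determines the number of replicates needed for
it to fall below a chosen effect magnitude.  For each candidate sample
size *s*, ``subset_count`` independent subsets of *s* runs are gathered
under identical (calibrated) parameters; subsets 2..subset_count are each
contrasted with subset 1 using the Vargha-Delaney A-Test, per response.
As *s* grows the subsets become statistically indistinguishable and the
maximum folded score falls towards 0.5.  The recommended sample size is
the smallest analysed one whose maximum folded score over all responses
and subsets is strictly below the tolerance (default 0.56, the "small"
effect threshold, i.e. aleatory effects smaller than "small").

On-disk layout expected by :func:`analyse_consistency`::

    <root>/size<s>/subset<k>.csv     k = 1..subset_count

each file holding one row per run (per-run medians) and one column per
response measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atest import DEFAULT_THRESHOLDS, MagnitudeThresholds, a_test
from .params_io import read_responses

logger = logging.getLogger("simsens")

__all__ = [
    "ConsistencyResult",
    "summarise_runs",
    "analyse_sample_size",
    "recommend_sample_size",
    "analyse_consistency",
    "write_consistency_outputs",
]

#: Default tolerance: aleatory effects must stay below the "small" band.
DEFAULT_TOLERANCE = DEFAULT_THRESHOLDS.small


@dataclass
class ConsistencyResult:
    """Scores and recommendation from a consistency analysis.

    Attributes
    ----------
    scores : dict of int -> DataFrame
        Per sample size: folded A-Test scores, indexed by comparison
        subset (2..subset_count), one column per response.
    max_scores : DataFrame
        Per sample size (index): maximum folded score per response.
    tolerance : float
        Folded-score tolerance used for the recommendation.
    recommended_size : int or None
        Smallest analysed size meeting the tolerance; ``None`` means no
        analysed size was sufficient.
    rows_ingested : int
        Total number of simulation rows consumed (bookkeeping check:
        equals ``subset_count * sum(sample_sizes)`` when every run
        contributes one row).
    """

    scores: dict[int, pd.DataFrame]
    max_scores: pd.DataFrame
    tolerance: float
    recommended_size: int | None
    rows_ingested: int

    @property
    def recommendation_label(self) -> str:
        return "insufficient" if self.recommended_size is None else str(self.recommended_size)


def summarise_runs(
    records: pd.DataFrame,
    responses: Sequence[str],
    run_column: str = "run",
) -> pd.DataFrame:
    """Reduce raw per-record output (e.g. one row per cell) to per-run medians.

    When a run contributes several records per response its value is the
    median of those records; runs with zero records are simply absent
    from the grouped output (a warning notes the count if the run column
    declares runs that vanished entirely after ingestion).
    """
    if run_column not in records.columns:
        raise ValueError(f"records lack the run identifier column {run_column!r}")
    grouped = records.groupby(run_column)[list(responses)].median()
    return grouped.reset_index(drop=True)


def analyse_sample_size(
    subsets: Sequence[pd.DataFrame],
    responses: Sequence[str],
    thresholds: MagnitudeThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Contrast subsets 2..n with subset 1, returning folded scores.

    All subsets at one sample size must contain the same number of runs;
    unequal sizes indicate a protocol violation and raise.
    """
    if len(subsets) < 2:
        raise ValueError("need at least two subsets (reference plus one comparison)")
    sizes = {len(s) for s in subsets}
    if len(sizes) != 1:
        raise ValueError(f"subsets have unequal run counts: {sorted(sizes)}")
    reference = subsets[0]
    rows = {}
    for k, subset in enumerate(subsets[1:], start=2):
        rows[k] = {
            r: a_test(subset[r], reference[r], thresholds).a_normalised
            for r in responses
        }
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(responses))
    out.index.name = "subset"
    return out


def recommend_sample_size(
    max_by_size: Mapping[int, float], tolerance: float = DEFAULT_TOLERANCE
) -> int | None:
    """Smallest analysed sample size whose maximum folded score is below tolerance.

    Returns ``None`` ("insufficient") when no analysed size qualifies.
    """
    qualifying = [size for size, max_a in max_by_size.items() if max_a < tolerance]
    return min(qualifying) if qualifying else None


def analyse_consistency(
    root: str | Path,
    sample_sizes: Sequence[int],
    subset_count: int,
    responses: Sequence[str],
    tolerance: float = DEFAULT_TOLERANCE,
    thresholds: MagnitudeThresholds = DEFAULT_THRESHOLDS,
) -> ConsistencyResult:
    """Run the full consistency analysis over a ``size<s>/subset<k>.csv`` tree."""
    root = Path(root)
    scores: dict[int, pd.DataFrame] = {}
    rows = 0
    for size in sample_sizes:
        subsets = []
        for k in range(1, subset_count + 1):
            table = read_responses(root / f"size{size}" / f"subset{k}.csv", responses)
            rows += table.n_runs
            subsets.append(table.data)
        scores[size] = analyse_sample_size(subsets, responses, thresholds)
    max_scores = pd.DataFrame(
        {size: frame.max(axis=0) for size, frame in scores.items()}
    ).T
    max_scores.index.name = "sample_size"
    overall = max_scores.max(axis=1)
    recommended = recommend_sample_size(overall.to_dict(), tolerance)
    logger.info(
        "consistency analysis ingested %d simulation rows over %d sample sizes",
        rows,
        len(sample_sizes),
    )
    return ConsistencyResult(
        scores=scores,
        max_scores=max_scores,
        tolerance=tolerance,
        recommended_size=recommended,
        rows_ingested=rows,
    )


def write_consistency_outputs(result: ConsistencyResult, out_dir: str | Path) -> None:
    """Write score tables, the max-score summary, and best-effort plots."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for size, frame in result.scores.items():
        frame.to_csv(out_dir / f"atest_scores_size{size}.csv")
    summary = result.max_scores.copy()
    summary["overall_max"] = summary.max(axis=1)
    summary.to_csv(out_dir / "max_atest_scores.csv")
    with open(out_dir / "recommendation.txt", "w", encoding="utf-8") as fh:
        fh.write(
            f"recommended_sample_size: {result.recommendation_label}\n"
            f"tolerance: {result.tolerance}\n"
            f"rows_ingested: {result.rows_ingested}\n"
        )
    try:
        from ._plots import plot_consistency_scores, plot_max_scores

        for size, frame in result.scores.items():
            plot_consistency_scores(
                frame, size, out_dir / f"atest_scores_size{size}.png"
            )
        plot_max_scores(result.max_scores, out_dir / "max_atest_scores.png")
    except Exception:  # plotting is best-effort, never gates analysis output
        logger.warning("consistency plotting failed; tabular outputs written", exc_info=True)
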