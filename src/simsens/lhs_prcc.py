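"""Global sensitivity analysis: latin-hypercube sampling with PRCC.

All parameters are perturbed simultaneously.  A latin hypercube design
stratifies each parameter's range into N equal-width strata and draws one
uniform value inside each stratum, independently permuted across
parameters; among R candidate designs (differing only in the
permutations) the one minimising the maximum absolute pairwise rank
correlation between parameter columns is kept, so the columns are as
close to uncorrelated as a cheap search allows.

Each parameter set is run (with replicates for stochastic simulators) and
summarised to a median response.  Influence is then quantified with
partial rank correlation coefficients: every column is rank-transformed,
the ranks of parameter j and of the response are each residualised
against the ranks of the other K-1 parameters (least squares with
intercept), and the PRCC is the Pearson correlation of the two residual
vectors.  Rank transformation makes the coefficient invariant under any
strictly monotone transform of parameter or response; partialling removes
the linear rank effects of the co-varying parameters.  Significance uses
t = prcc * sqrt(df / (1 - prcc^2)) on df = N - 2 - (K - 1) degrees of
freedom, two-sided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .params_io import ParameterSpec, ReplicateTable, read_responses

logger = logging.getLogger("simsens")

__all__ = [
    "LHSDesign",
    "lhs_sample",
    "summarise_sets",
    "prcc",
    "PRCCResult",
    "prcc_analysis",
    "analyse_lhs_dir",
    "write_lhs_outputs",
]


@dataclass
class LHSDesign:
    """An N x K latin-hypercube design matrix plus its seed."""

    samples: pd.DataFrame
    seed: int

    @property
    def n_sets(self) -> int:
        return len(self.samples)

    def design_files(self) -> dict[str, pd.DataFrame]:
        return {"lhs_design.csv": self.samples}


def _max_abs_rank_correlation(matrix: np.ndarray) -> float:
    ranks = np.column_stack([rankdata(matrix[:, j]) for j in range(matrix.shape[1])])
    corr = np.corrcoef(ranks, rowvar=False)
    off = corr[~np.eye(corr.shape[0], dtype=bool)]
    return float(np.max(np.abs(off)))


def lhs_sample(
    parameters: Sequence[ParameterSpec],
    n: int,
    seed: int,
    candidates: int = 20,
) -> LHSDesign:
    """Draw a stratified latin-hypercube design, best of ``candidates``.

    Deterministic given ``seed``.  Each column places exactly one value,
    uniformly positioned, in each of the N equal-width strata of its
    parameter's range.
    """
    if n < 2:
        raise ValueError(f"latin hypercube needs at least 2 sets; got {n}")
    if candidates < 1:
        raise ValueError("candidates must be >= 1")
    rng = np.random.default_rng(seed)
    names = [p.name for p in parameters]
    best: np.ndarray | None = None
    best_score = np.inf
    for _ in range(candidates):
        columns = []
        for p in parameters:
            strata = (rng.permutation(n) + rng.uniform(size=n)) / n
            columns.append(p.lower + strata * p.span)
        candidate = np.column_stack(columns)
        if len(parameters) == 1:
            best = candidate
            break
        score = _max_abs_rank_correlation(candidate)
        if score < best_score:
            best_score = score
            best = candidate
    assert best is not None
    return LHSDesign(samples=pd.DataFrame(best, columns=names), seed=seed)


def summarise_sets(
    tables: Sequence[ReplicateTable],
) -> tuple[pd.DataFrame, int]:
    """Median response per parameter set; returns (medians, rows ingested).

    Empty sets are excluded with a warning (decrementing the effective N);
    the medians frame keeps the positional index of surviving sets.
    """
    rows = 0
    medians = {}
    skipped = 0
    for i, table in enumerate(tables):
        if table.n_runs == 0:
            logger.warning("set %s has no replicate rows; excluded", table.condition_id)
            skipped += 1
            continue
        rows += table.n_runs
        medians[i] = table.data.median()
    if skipped:
        logger.warning("%d empty set(s) excluded from the analysis", skipped)
    frame = pd.DataFrame.from_dict(medians, orient="index")
    logger.info(
        "summarised %d parameter sets from %d simulation rows", len(frame), rows
    )
    return frame, rows


def prcc(samples: pd.DataFrame, response) -> pd.DataFrame:
    """Partial rank correlation of every parameter column with a response.

    Returns a frame indexed by parameter with columns ``prcc`` and
    ``p_value``.  A constant parameter column has no defined coefficient
    and is reported as 0 with a logged warning.
    """
    X = samples.to_numpy(dtype=float)
    y = np.asarray(response, dtype=float).ravel()
    n, k = X.shape
    if len(y) != n:
        raise ValueError(f"response length {len(y)} does not match {n} parameter sets")
    if n < k + 3:
        raise ValueError(
            f"PRCC needs at least K + 3 = {k + 3} complete sets; got {n}"
        )
    ranks_x = np.column_stack([rankdata(X[:, j]) for j in range(k)])
    ranks_y = rankdata(y)
    dof = n - 2 - (k - 1)
    out = []
    for j in range(k):
        xj = ranks_x[:, j]
        name = samples.columns[j]
        if np.ptp(xj) == 0 or np.ptp(ranks_y) == 0:
            logger.warning(
                "PRCC undefined for %r (constant ranks); reported as 0", name
            )
            out.append({"prcc": 0.0, "p_value": np.nan})
            continue
        others = np.column_stack(
            [np.ones(n), ranks_x[:, [m for m in range(k) if m != j]]]
        )
        beta_x, *_ = np.linalg.lstsq(others, xj, rcond=None)
        beta_y, *_ = np.linalg.lstsq(others, ranks_y, rcond=None)
        res_x = xj - others @ beta_x
        res_y = ranks_y - others @ beta_y
        denom = np.linalg.norm(res_x) * np.linalg.norm(res_y)
        if denom == 0:
            logger.warning("PRCC undefined for %r (zero residuals); reported as 0", name)
            out.append({"prcc": 0.0, "p_value": np.nan})
            continue
        r = float(np.clip(res_x @ res_y / denom, -1.0, 1.0))
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt(dof / (1.0 - r * r))
            p = 2.0 * stats.t.sf(abs(t), dof)
        out.append({"prcc": r, "p_value": float(p)})
    return pd.DataFrame(out, index=list(samples.columns))


@dataclass
class PRCCResult:
    """PRCC and p-value per (parameter, response) pair."""

    table: pd.DataFrame  # columns: parameter, response, prcc, p_value
    n_effective: int
    rows_ingested: int

    def coefficient(self, parameter: str, response: str) -> float:
        mask = (self.table["parameter"] == parameter) & (
            self.table["response"] == response
        )
        return float(self.table.loc[mask, "prcc"].iloc[0])


def prcc_analysis(
    design: LHSDesign, medians: pd.DataFrame, rows_ingested: int = 0
) -> PRCCResult:
    """Compute PRCCs for every response column against the design matrix.

    ``medians`` rows must align 1:1 (positionally) with design rows; sets
    excluded by :func:`summarise_sets` are dropped from both sides via the
    medians frame's index.
    """
    samples = design.samples.iloc[medians.index.to_numpy()]
    records = []
    for response in medians.columns:
        coeffs = prcc(samples, medians[response])
        for name, row in coeffs.iterrows():
            records.append(
                {
                    "parameter": name,
                    "response": response,
                    "prcc": row["prcc"],
                    "p_value": row["p_value"],
                }
            )
    return PRCCResult(
        table=pd.DataFrame.from_records(records),
        n_effective=len(medians),
        rows_ingested=rows_ingested,
    )


def analyse_lhs_dir(
    root: str | Path,
    responses: Sequence[str],
    design: LHSDesign | None = None,
) -> tuple[PRCCResult, pd.DataFrame]:
    """Run the LHS/PRCC analysis over ``lhs_design.csv`` + ``set<i>.csv`` files.

    Returns the PRCC result and the per-set medians (for plotting).
    """
    root = Path(root)
    if design is None:
        design_path = root / "lhs_design.csv"
        if not design_path.exists():
            raise ValueError(f"missing design file: {design_path}")
        design = LHSDesign(samples=pd.read_csv(design_path), seed=-1)
    tables = []
    for i in range(1, design.n_sets + 1):
        path = root / f"set{i}.csv"
        if not path.exists():
            raise ValueError(f"missing response table for set {i}: {path}")
        tables.append(read_responses(path, responses))
    medians, rows = summarise_sets(tables)
    return prcc_analysis(design, medians, rows), medians


def write_lhs_outputs(
    result: PRCCResult,
    design: LHSDesign,
    medians: pd.DataFrame,
    out_dir: str | Path,
) -> None:
    """Write the PRCC summary table and best-effort scatter plots."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(out_dir / "prcc_summary.csv", index=False)
    try:
        from ._plots import plot_lhs_scatter

        samples = design.samples.iloc[medians.index.to_numpy()]
        for _, row in result.table.iterrows():
            name, response = row["parameter"], row["response"]
            plot_lhs_scatter(
                samples[name],
                medians[response],
                name,
                response,
                row["prcc"],
                out_dir / f"scatter_{name}_{response}.png",
            )
    except Exception:  # plotting is best-effort
        logger.warning("LHS plotting failed; tabular outputs written", exc_info=True)
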