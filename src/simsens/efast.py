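"""eFAST: variance decomposition via sinusoidal search-curve sampling.

The extended Fourier Amplitude Sensitivity Test explores parameter space
along space-filling curves.  For each parameter of interest i, all
parameters k are driven through their ranges by

    x_k(s_j) = lower_k + span_k * (1/2 + (1/pi) * arcsin(sin(w_k s_j + phi_k)))

over the symmetric grid s_j = pi (2j - NS - 1) / NS, j = 1..NS (NS odd),
with the parameter of interest assigned the high frequency
w_i = omega_max = floor((NS - 1) / (2 M)) and the complementary set
assigned low *odd* integer frequencies cycling through
{1, 3, 5, ...} within [1, floor(omega_max / 2)] in parameter order.
Restricting the complement to odd frequencies avoids low-order 1:2
frequency ratios, whose degenerate Lissajous coverage couples
complementary parameters along the curve and badly distorts the
per-curve total variance whenever the model has interactions (easily
seen on the Ishigami benchmark).  The arcsin-of-sin transform is a
triangle wave, so each parameter sweeps its range uniformly.  Repeating
the sampling NR times with freshly drawn phase offsets phi ("resample
curves") decorrelates the curves and provides error bars.

Fourier analysis of the response y(s_j) along one curve gives

    A_k = (1/NS) sum_j y_j cos(k s_j),   B_k = (1/NS) sum_j y_j sin(k s_j)
    D_total = 2 sum_{k=1}^{(NS-1)/2} (A_k^2 + B_k^2)

The first-order index Si is the fraction of D_total found at the
harmonics p * omega_max (p = 1..M) — variance attributable to the
parameter of interest alone; the total-order index STi is one minus the
fraction found below omega_max / 2 (the complementary set's first-order
band), so it additionally counts all interactions involving the
parameter.  A "dummy" parameter with no simulator effect is sampled
alongside the real ones; its indices estimate the aliasing/interference
noise floor, and each real parameter's per-curve indices are compared to
the dummy's with a one-sided Welch t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .params_io import ParameterSpec, read_responses

logger = logging.getLogger("simsens")

__all__ = [
    "EFASTDesign",
    "efast_sample",
    "search_curve",
    "fourier_variances",
    "curve_indices",
    "EFASTResult",
    "efast_indices",
    "dummy_comparison",
    "analyse_efast_dir",
    "write_efast_outputs",
]


def sample_grid(ns: int) -> np.ndarray:
    """The symmetric curve-parameter grid s_j in (-pi, pi], j = 1..NS."""
    j = np.arange(1, ns + 1)
    return np.pi * (2.0 * j - ns - 1) / ns


def search_curve(
    lower: float, upper: float, omega: int, phase: float, ns: int
) -> np.ndarray:
    """Sampled values of one parameter along one search curve."""
    s = sample_grid(ns)
    return lower + (upper - lower) * (
        0.5 + np.arcsin(np.sin(omega * s + phase)) / np.pi
    )


@dataclass
class EFASTDesign:
    """Curve samples plus the frequency/phase metadata needed for analysis."""

    parameters: list[ParameterSpec]  # includes the dummy
    ns: int
    nr: int
    m: int
    seed: int
    omega_max: int
    dummy_name: str | None
    frequencies: dict[str, dict[str, int]]  # per parameter-of-interest
    phases: dict[tuple[str, int], dict[str, float]]  # per (poi, curve)
    samples: dict[tuple[str, int], pd.DataFrame]  # per (poi, curve): NS x (K+1)

    @property
    def parameter_names(self) -> list[str]:
        return [p.name for p in self.parameters]

    @property
    def total_sets(self) -> int:
        return len(self.parameters) * self.nr * self.ns

    @property
    def sets_per_parameter(self) -> int:
        return self.nr * self.ns

    def design_files(self) -> dict[str, pd.DataFrame]:
        return {
            f"curve{curve}_param{poi}.csv": frame
            for (poi, curve), frame in self.samples.items()
        }


def efast_sample(
    parameters: Sequence[ParameterSpec],
    ns: int,
    nr: int,
    m: int = 4,
    seed: int = 0,
    dummy_name: str | None = "dummy",
) -> EFASTDesign:
    """Generate the full eFAST design for ``parameters`` (dummy included).

    ``parameters`` must already contain the dummy spec when
    ``dummy_name`` is not None; the dummy takes part in sampling like any
    other parameter but is known to have no simulator effect.
    """
    if ns % 2 == 0:
        raise ValueError(f"NS must be odd; got {ns}")
    omega_max = (ns - 1) // (2 * m)
    if omega_max < 2:
        raise ValueError(
            f"NS = {ns} is too small for M = {m}: the smallest admissible "
            f"(odd) NS is {4 * m + 1}"
        )
    names = [p.name for p in parameters]
    if len(set(names)) != len(names):
        raise ValueError("parameter names must be unique")
    if dummy_name is not None and dummy_name not in names:
        raise ValueError(f"dummy parameter {dummy_name!r} not present in parameters")
    comp_max = max(1, omega_max // 2)
    # Odd frequencies only: 1, 3, 5, ... up to comp_max, cycled.
    comp_cycle = list(range(1, comp_max + 1, 2))
    rng = np.random.default_rng(seed)
    frequencies: dict[str, dict[str, int]] = {}
    phases: dict[tuple[str, int], dict[str, float]] = {}
    samples: dict[tuple[str, int], pd.DataFrame] = {}
    for poi in parameters:
        omegas = {poi.name: omega_max}
        slot = 0
        for p in parameters:
            if p.name == poi.name:
                continue
            omegas[p.name] = comp_cycle[slot % len(comp_cycle)]
            slot += 1
        frequencies[poi.name] = omegas
        for curve in range(1, nr + 1):
            phi = {p.name: float(rng.uniform(0.0, 2.0 * np.pi)) for p in parameters}
            frame = pd.DataFrame(
                {
                    p.name: search_curve(p.lower, p.upper, omegas[p.name], phi[p.name], ns)
                    for p in parameters
                }
            )
            phases[(poi.name, curve)] = phi
            samples[(poi.name, curve)] = frame
    return EFASTDesign(
        parameters=list(parameters),
        ns=ns,
        nr=nr,
        m=m,
        seed=seed,
        omega_max=omega_max,
        dummy_name=dummy_name,
        frequencies=frequencies,
        phases=phases,
        samples=samples,
    )


def _spectrum(y: np.ndarray) -> np.ndarray:
    """Power A_k^2 + B_k^2 at k = 1..(NS-1)/2 for one curve's responses."""
    y = np.asarray(y, dtype=float).ravel()
    ns = y.size
    if ns % 2 == 0:
        raise ValueError(f"curve length must be odd; got {ns}")
    s = sample_grid(ns)
    k = np.arange(1, (ns - 1) // 2 + 1)
    arg = np.outer(k, s)
    a = (np.cos(arg) @ y) / ns
    b = (np.sin(arg) @ y) / ns
    return a * a + b * b


def fourier_variances(y, omega: int, m: int) -> tuple[float, float]:
    """Total spectral variance and the share at harmonics of ``omega``.

    Returns ``(D_total, D_omega)`` with
    ``D_omega = 2 * sum_{p=1}^{M} (A_{p w}^2 + B_{p w}^2)``.  A constant
    response yields ``D_total = 0`` (no error; handled downstream).
    """
    power = _spectrum(y)
    d_total = 2.0 * float(power.sum())
    harmonics = omega * np.arange(1, m + 1)
    harmonics = harmonics[harmonics <= power.size]
    d_omega = 2.0 * float(power[harmonics - 1].sum())
    return d_total, d_omega


def curve_indices(y, omega_max: int, m: int) -> tuple[float, float]:
    """(Si, STi) for one parameter-of-interest curve.

    ``Si = D_omega_max / D_total``;
    ``STi = 1 - D_complement / D_total`` with the complement band
    ``k = 1..floor(omega_max/2)``.  A dead (constant) response gives
    ``(0, 0)`` with a logged warning.
    """
    power = _spectrum(y)
    d_total = 2.0 * float(power.sum())
    if d_total <= 0.0:
        logger.warning("constant response along curve: Si and STi reported as 0")
        return 0.0, 0.0
    harmonics = omega_max * np.arange(1, m + 1)
    harmonics = harmonics[harmonics <= power.size]
    d_omega = 2.0 * float(power[harmonics - 1].sum())
    d_comp = 2.0 * float(power[: omega_max // 2].sum())
    return d_omega / d_total, 1.0 - d_comp / d_total


def dummy_comparison(indices, dummy_indices) -> float:
    """One-sided Welch t-test p-value for index > dummy index, over curves.

    Fewer than two curves on either side makes the test non-computable;
    NaN is returned with a logged warning.
    """
    indices = np.asarray(indices, dtype=float)
    dummy_indices = np.asarray(dummy_indices, dtype=float)
    if indices.size < 2 or dummy_indices.size < 2:
        logger.warning(
            "dummy comparison needs at least 2 resample curves per side; "
            "p-value not computable"
        )
        return float("nan")
    result = stats.ttest_ind(
        indices, dummy_indices, equal_var=False, alternative="greater"
    )
    return float(result.pvalue)


@dataclass
class EFASTResult:
    """Per-curve and aggregated Si/STi indices with dummy-test p-values."""

    per_curve: pd.DataFrame  # columns: parameter, response, curve, Si, STi
    summary: pd.DataFrame  # parameter, response, Si_mean, Si_se, STi_mean, STi_se, p_si, p_sti
    dummy_name: str | None

    def mean_index(self, parameter: str, response: str, which: str = "Si") -> float:
        mask = (self.summary["parameter"] == parameter) & (
            self.summary["response"] == response
        )
        return float(self.summary.loc[mask, f"{which}_mean"].iloc[0])


def efast_indices(
    responses: Mapping[tuple[str, int], pd.DataFrame],
    design: EFASTDesign,
) -> EFASTResult:
    """Compute Si/STi per curve and aggregate over resample curves.

    ``responses`` maps (parameter-of-interest, curve) to a frame of NS
    median-response rows aligned with the design's sample order.
    """
    records = []
    for poi in design.parameter_names:
        for curve in range(1, design.nr + 1):
            key = (poi, curve)
            if key not in responses:
                raise ValueError(f"missing responses for parameter {poi!r} curve {curve}")
            frame = responses[key]
            if len(frame) != design.ns:
                raise ValueError(
                    f"responses for parameter {poi!r} curve {curve} have "
                    f"{len(frame)} rows; expected NS = {design.ns}"
                )
            for response in frame.columns:
                si, sti = curve_indices(
                    frame[response].to_numpy(), design.omega_max, design.m
                )
                records.append(
                    {
                        "parameter": poi,
                        "response": response,
                        "curve": curve,
                        "Si": si,
                        "STi": sti,
                    }
                )
    per_curve = pd.DataFrame.from_records(records)

    summary_rows = []
    for (poi, response), group in per_curve.groupby(["parameter", "response"], sort=False):
        si = group["Si"].to_numpy()
        sti = group["STi"].to_numpy()
        nr = len(group)
        row = {
            "parameter": poi,
            "response": response,
            "Si_mean": float(si.mean()),
            "Si_se": float(si.std(ddof=1) / np.sqrt(nr)) if nr > 1 else float("nan"),
            "STi_mean": float(sti.mean()),
            "STi_se": float(sti.std(ddof=1) / np.sqrt(nr)) if nr > 1 else float("nan"),
            "p_si": float("nan"),
            "p_sti": float("nan"),
        }
        summary_rows.append(row)
    summary = pd.DataFrame.from_records(summary_rows)

    if design.dummy_name is not None:
        for response in summary["response"].unique():
            dummy_mask = (per_curve["parameter"] == design.dummy_name) & (
                per_curve["response"] == response
            )
            dummy_si = per_curve.loc[dummy_mask, "Si"].to_numpy()
            dummy_sti = per_curve.loc[dummy_mask, "STi"].to_numpy()
            for poi in design.parameter_names:
                if poi == design.dummy_name:
                    continue
                mask = (per_curve["parameter"] == poi) & (
                    per_curve["response"] == response
                )
                si = per_curve.loc[mask, "Si"].to_numpy()
                sti = per_curve.loc[mask, "STi"].to_numpy()
                target = (summary["parameter"] == poi) & (
                    summary["response"] == response
                )
                summary.loc[target, "p_si"] = dummy_comparison(si, dummy_si)
                summary.loc[target, "p_sti"] = dummy_comparison(sti, dummy_sti)
    return EFASTResult(per_curve=per_curve, summary=summary, dummy_name=design.dummy_name)


def analyse_efast_dir(
    root: str | Path,
    design: EFASTDesign,
    responses: Sequence[str],
) -> EFASTResult:
    """Run the eFAST analysis over ``curve<c>_param<name>_results.csv`` files."""
    root = Path(root)
    tables: dict[tuple[str, int], pd.DataFrame] = {}
    rows = 0
    for poi in design.parameter_names:
        for curve in range(1, design.nr + 1):
            path = root / f"curve{curve}_param{poi}_results.csv"
            if not path.exists():
                raise ValueError(
                    f"missing response table for parameter {poi!r} curve {curve}: {path}"
                )
            table = read_responses(path, responses)
            rows += table.n_runs
            tables[(poi, curve)] = table.data
    logger.info("eFAST analysis ingested %d median-response rows", rows)
    return efast_indices(tables, design)


def write_efast_outputs(result: EFASTResult, out_dir: str | Path) -> None:
    """Write per-response summary files and best-effort grouped bar charts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.per_curve.to_csv(out_dir / "efast_per_curve.csv", index=False)
    for response, group in result.summary.groupby("response", sort=False):
        group.drop(columns="response").to_csv(
            out_dir / f"efast_summary_{response}.csv", index=False
        )
    try:
        from ._plots import plot_efast_indices

        for response, group in result.summary.groupby("response", sort=False):
            plot_efast_indices(group, response, out_dir / f"efast_indices_{response}.png")
    except Exception:  # plotting is best-effort
        logger.warning("eFAST plotting failed; tabular outputs written", exc_info=True)
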