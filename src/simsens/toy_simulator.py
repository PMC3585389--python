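"""A synthetic stochastic cell-behaviour simulator with known sensitivities.

The toy model emulates the structure of an agent-based tissue-development
simulation — six named parameters, two responses (cell ``Velocity`` and
``Displacement``), many cells per run, lognormal run-to-run noise — while
keeping the ground-truth sensitivity structure fully controlled, so that
every analysis technique in the package can be checked end to end:

* ``maxVCAMeffectProbabilityCutoff`` is, by construction, the dominant
  influence on Velocity, followed by ``thresholdBindProbability`` and
  then ``vcamSlope`` (adhesion slows cells down);
* ``chemoThreshold`` and ``chemoLowerLinearAdjust`` additionally drive
  Displacement through a chemotaxis gain;
* ``chemoUpperLinearAdjust`` is deliberately inert — a true negative
  every technique must clear.

Per cell c, with V0 the base speed:

    w        = (1 - exp(-vcamSlope)) / (1 - exp(-2))
    adhesion = maxVCAM * (0.35 + 0.65 * thresholdBind * w)
    velocity_c = V0 * (1 - 0.7 * adhesion) * exp(eps_c),   eps_c ~ N(0, sigma_v^2)
    gain     = clamp(0.5 - chemoThreshold, 0, 1) * chemoLower / 0.08
    displacement_c = velocity_c * n_steps * (0.2 + 0.8 * gain) * exp(eta_c),
                                                           eta_c ~ N(0, sigma_d^2)

Multiplicative lognormal noise keeps responses positive and non-normal,
matching the motivation for non-parametric scoring.  Runs are seeded as
``master_seed + run_counter`` (numpy PCG64), so datasets are reproducible
bit for bit.  There is no spatial mechanics or chemokine diffusion here:
the model is a test harness with designed sensitivities, not a tissue
model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .efast import EFASTDesign
from .lhs_prcc import LHSDesign
from .params_io import ConsistencySettings, ParameterSpec, format_value
from .robustness import OATDesign

logger = logging.getLogger("simsens")

__all__ = [
    "RESPONSES",
    "PARAMETER_NAMES",
    "case_study_parameters",
    "ToySimConfig",
    "simulate_run",
    "run_medians",
    "generate_consistency_dataset",
    "generate_robustness_dataset",
    "generate_lhs_dataset",
    "generate_efast_dataset",
    "generate_dataset",
]

RESPONSES = ("Velocity", "Displacement")

PARAMETER_NAMES = (
    "chemoThreshold",
    "chemoLowerLinearAdjust",
    "chemoUpperLinearAdjust",
    "thresholdBindProbability",
    "vcamSlope",
    "maxVCAMeffectProbabilityCutoff",
)


def case_study_parameters() -> list[ParameterSpec]:
    """The six parameters with their ranges, OAT increments and calibrated values.

    Ranges and increments follow the published lymphoid-tissue case study;
    the calibrated values are this package's choice (mid-range, on the
    increment grid).
    """
    return [
        ParameterSpec("chemoThreshold", 0.0, 1.0, 0.3, 0.1),
        ParameterSpec("chemoLowerLinearAdjust", 0.015, 0.08, 0.045, 0.005),
        ParameterSpec("chemoUpperLinearAdjust", 0.1, 0.5, 0.3, 0.05),
        ParameterSpec("thresholdBindProbability", 0.0, 1.0, 0.5, 0.1),
        ParameterSpec("vcamSlope", 0.25, 2.0, 1.0, 0.25),
        ParameterSpec("maxVCAMeffectProbabilityCutoff", 0.0, 1.0, 0.5, 0.1),
    ]


@dataclass(frozen=True)
class ToySimConfig:
    """Simulator settings: cells per run, steps, base speed, noise scales."""

    n_cells: int = 50
    n_steps: int = 100
    base_speed: float = 10.0  # arbitrary speed units per time unit
    sigma_v: float = 0.2
    sigma_d: float = 0.3

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.sigma_v <= 0 or self.sigma_d <= 0:
            raise ValueError("noise scales must be positive")


DEFAULT_CONFIG = ToySimConfig()


def simulate_run(
    assignment: Mapping[str, float],
    config: ToySimConfig = DEFAULT_CONFIG,
    seed: int = 0,
) -> pd.DataFrame:
    """One simulation run: per-cell (Velocity, Displacement) records.

    ``assignment`` must cover all six parameters; extra entries (such as
    an eFAST dummy) are ignored by construction.  Deterministic given
    ``seed``.
    """
    missing = [name for name in PARAMETER_NAMES if name not in assignment]
    if missing:
        raise ValueError(f"assignment missing parameter(s): {missing}")
    ct = float(assignment["chemoThreshold"])
    cl = float(assignment["chemoLowerLinearAdjust"])
    tbp = float(assignment["thresholdBindProbability"])
    slope = float(assignment["vcamSlope"])
    mvc = float(assignment["maxVCAMeffectProbabilityCutoff"])
    # chemoUpperLinearAdjust is read but deliberately has no effect.
    float(assignment["chemoUpperLinearAdjust"])

    rng = np.random.default_rng(seed)
    w = (1.0 - np.exp(-slope)) / (1.0 - np.exp(-2.0))
    adhesion = mvc * (0.35 + 0.65 * tbp * w)
    eps = rng.normal(0.0, config.sigma_v, config.n_cells)
    velocity = config.base_speed * (1.0 - 0.7 * adhesion) * np.exp(eps)
    gain = np.clip(0.5 - ct, 0.0, 1.0) * (cl / 0.08)
    eta = rng.normal(0.0, config.sigma_d, config.n_cells)
    displacement = velocity * config.n_steps * (0.2 + 0.8 * gain) * np.exp(eta)
    return pd.DataFrame({"Velocity": velocity, "Displacement": displacement})


def run_medians(
    assignment: Mapping[str, float],
    config: ToySimConfig = DEFAULT_CONFIG,
    seed: int = 0,
) -> dict[str, float]:
    """Median per-cell response of a single run — the run's summary value."""
    cells = simulate_run(assignment, config, seed)
    return {r: float(cells[r].median()) for r in RESPONSES}


class _RunCounter:
    """Derives per-run seeds as master seed + running index."""

    def __init__(self, master_seed: int) -> None:
        self.master_seed = int(master_seed)
        self.count = 0

    def next_seed(self) -> int:
        seed = self.master_seed + self.count
        self.count += 1
        return seed


def _replicate_frame(
    assignment: Mapping[str, float],
    replicates: int,
    config: ToySimConfig,
    counter: _RunCounter,
) -> pd.DataFrame:
    rows = [
        run_medians(assignment, config, counter.next_seed()) for _ in range(replicates)
    ]
    return pd.DataFrame(rows, columns=list(RESPONSES))


def generate_consistency_dataset(
    out_dir: str | Path,
    sample_sizes: Sequence[int],
    subset_count: int = 20,
    assignment: Mapping[str, float] | None = None,
    config: ToySimConfig = DEFAULT_CONFIG,
    seed: int = 0,
) -> int:
    """Write ``size<s>/subset<k>.csv`` tables of per-run medians.

    All runs use one fixed parameter assignment (default: calibrated
    values).  Returns the total number of runs executed, which equals
    ``subset_count * sum(sample_sizes)``.
    """
    out_dir = Path(out_dir)
    if assignment is None:
        assignment = {p.name: p.calibrated for p in case_study_parameters()}
    counter = _RunCounter(seed)
    for size in sample_sizes:
        size_dir = out_dir / f"size{size}"
        size_dir.mkdir(parents=True, exist_ok=True)
        for k in range(1, subset_count + 1):
            frame = _replicate_frame(assignment, size, config, counter)
            frame.to_csv(size_dir / f"subset{k}.csv", index=False)
    logger.info("toy simulator executed %d consistency runs", counter.count)
    return counter.count


def generate_robustness_dataset(
    out_dir: str | Path,
    design: OATDesign,
    replicates: int,
    config: ToySimConfig = DEFAULT_CONFIG,
    seed: int = 0,
) -> int:
    """Write ``baseline.csv`` and ``param<name>/value<v>.csv`` replicate tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counter = _RunCounter(seed)
    baseline = _replicate_frame(design.baseline, replicates, config, counter)
    baseline.to_csv(out_dir / "baseline.csv", index=False)
    for name, value in design.conditions():
        param_dir = out_dir / f"param{name}"
        param_dir.mkdir(parents=True, exist_ok=True)
        frame = _replicate_frame(design.assignment(name, value), replicates, config, counter)
        frame.to_csv(param_dir / f"value{format_value(value)}.csv", index=False)
    logger.info("toy simulator executed %d robustness runs", counter.count)
    return counter.count


def generate_lhs_dataset(
    out_dir: str | Path,
    design: LHSDesign,
    replicates: int,
    config: ToySimConfig = DEFAULT_CONFIG,
    seed: int = 0,
) -> int:
    """Write one ``set<i>.csv`` replicate table per latin-hypercube set."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counter = _RunCounter(seed)
    for i in range(design.n_sets):
        assignment = design.samples.iloc[i].to_dict()
        frame = _replicate_frame(assignment, replicates, config, counter)
        frame.to_csv(out_dir / f"set{i + 1}.csv", index=False)
    logger.info("toy simulator executed %d latin-hypercube runs", counter.count)
    return counter.count


def generate_efast_dataset(
    out_dir: str | Path,
    design: EFASTDesign,
    replicates: int,
    config: ToySimConfig = DEFAULT_CONFIG,
    seed: int = 0,
) -> int:
    """Write ``curve<c>_param<name>_results.csv``: one median row per sample.

    Each of the NS samples on each curve is run ``replicates`` times; the
    stored row is the median over replicates of the per-run medians.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counter = _RunCounter(seed)
    for (poi, curve), frame in design.samples.items():
        rows = []
        for j in range(len(frame)):
            assignment = frame.iloc[j].to_dict()
            reps = _replicate_frame(assignment, replicates, config, counter)
            rows.append(reps.median().to_dict())
        pd.DataFrame(rows, columns=list(RESPONSES)).to_csv(
            out_dir / f"curve{curve}_param{poi}_results.csv", index=False
        )
    logger.info("toy simulator executed %d eFAST runs", counter.count)
    return counter.count


def generate_dataset(
    technique: str,
    design,
    replicates: int,
    config: ToySimConfig = DEFAULT_CONFIG,
    seed: int = 0,
    out_dir: str | Path = ".",
) -> int:
    """Dispatch to the generator matching each technique's expected layout.

    For ``"consistency"`` the design is a :class:`ConsistencySettings`
    (``replicates`` is ignored there: each run is one replicate).
    Returns the number of simulation runs executed.
    """
    if technique == "consistency":
        if not isinstance(design, ConsistencySettings):
            raise ValueError("consistency generation expects ConsistencySettings")
        return generate_consistency_dataset(
            out_dir, design.sample_sizes, design.subset_count, config=config, seed=seed
        )
    if technique == "robustness":
        return generate_robustness_dataset(out_dir, design, replicates, config, seed)
    if technique == "lhs":
        return generate_lhs_dataset(out_dir, design, replicates, config, seed)
    if technique == "efast":
        return generate_efast_dataset(out_dir, design, replicates, config, seed)
    raise ValueError(
        f"unknown technique {technique!r}; expected consistency, robustness, lhs or efast"
    )
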