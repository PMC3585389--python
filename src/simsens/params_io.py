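"""Parameter specifications, experiment configuration and delimited-text I/O.

Every technique in :mod:`simsens` consumes the same three kinds of input:

* a list of :class:`ParameterSpec` objects describing the simulation
  parameters under study (bounds, calibrated baseline value and — for
  one-at-a-time robustness analysis — the perturbation increment);
* tables of simulation responses, one row per run (or per parameter set),
  one column per response measure, exchanged as plain CSV; and
* an :class:`ExperimentConfig` gathering the above with the
  technique-specific settings (consistency sample sizes, LHS set count,
  eFAST NS/NR/M), normally loaded from a YAML file.

Design matrices produced by the samplers are written back to disk with
:func:`write_design` so that an external simulator can execute them; the
round trip through CSV is exact to full floating-point precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("simsens")

__all__ = [
    "ConfigurationError",
    "ParameterSpec",
    "ConsistencySettings",
    "LHSSettings",
    "EFASTSettings",
    "ExperimentConfig",
    "ReplicateTable",
    "load_config",
    "read_responses",
    "write_design",
    "format_value",
]


class ConfigurationError(ValueError):
    """An experiment configuration is missing, malformed or inconsistent."""


@dataclass(frozen=True)
class ParameterSpec:
    """One simulation parameter: bounds, calibrated value, OAT increment.

    Parameters
    ----------
    name : str
        Short identifier, used in file headers and design matrices.
    lower, upper : float
        Range of biologically plausible values explored by the analyses.
    calibrated : float
        Baseline value used whenever the parameter is *not* being
        perturbed; must lie inside ``[lower, upper]``.
    increment : float, optional
        One-at-a-time perturbation step.  Only required for robustness
        analysis; must satisfy ``0 < increment <= upper - lower``.
    """

    name: str
    lower: float
    upper: float
    calibrated: float
    increment: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigurationError("parameter name must be a non-empty string")
        if not self.lower < self.upper:
            raise ConfigurationError(
                f"parameter {self.name!r}: lower bound ({self.lower}) must be "
                f"strictly below upper bound ({self.upper})"
            )
        if not (self.lower <= self.calibrated <= self.upper):
            raise ConfigurationError(
                f"parameter {self.name!r}: calibrated value ({self.calibrated}) "
                f"lies outside [{self.lower}, {self.upper}]"
            )
        if self.increment is not None and not (
            0.0 < self.increment <= self.upper - self.lower
        ):
            raise ConfigurationError(
                f"parameter {self.name!r}: increment ({self.increment}) must be "
                f"positive and no larger than the range ({self.upper - self.lower})"
            )

    @property
    def span(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class ConsistencySettings:
    """Settings for the aleatory (consistency) analysis."""

    sample_sizes: tuple[int, ...] = (1, 5, 50, 100, 300, 500)
    subset_count: int = 20

    def __post_init__(self) -> None:
        if self.subset_count < 2:
            raise ConfigurationError(
                "consistency subset_count must be >= 2 (subset 1 is the "
                "reference; at least one comparison is needed)"
            )
        if not self.sample_sizes or any(s < 1 for s in self.sample_sizes):
            raise ConfigurationError("consistency sample_sizes must be positive")
        if list(self.sample_sizes) != sorted(set(self.sample_sizes)):
            raise ConfigurationError(
                "consistency sample_sizes must be strictly increasing"
            )


@dataclass(frozen=True)
class LHSSettings:
    """Settings for latin-hypercube sampling."""

    n_sets: int = 500
    candidates: int = 20  # best-of-R correlation minimisation

    def __post_init__(self) -> None:
        if self.n_sets < 2:
            raise ConfigurationError("lhs n_sets must be >= 2")
        if self.candidates < 1:
            raise ConfigurationError("lhs candidates must be >= 1")


@dataclass(frozen=True)
class EFASTSettings:
    """Settings for eFAST sampling and analysis."""

    ns: int = 65  # samples per curve, odd
    nr: int = 3  # resample curves
    m: int = 4  # interference factor (harmonics per frequency)
    dummy_name: str = "dummy"

    def __post_init__(self) -> None:
        if self.ns < 3 or self.ns % 2 == 0:
            raise ConfigurationError("efast ns must be an odd integer >= 3")
        if self.nr < 1:
            raise ConfigurationError("efast nr must be >= 1")
        if self.m < 1:
            raise ConfigurationError("efast m must be >= 1")


@dataclass(frozen=True)
class ExperimentConfig:
    """A full experiment description: parameters, responses and settings."""

    parameters: tuple[ParameterSpec, ...]
    responses: tuple[str, ...]
    seed: int = 0
    consistency: ConsistencySettings = field(default_factory=ConsistencySettings)
    lhs: LHSSettings = field(default_factory=LHSSettings)
    efast: EFASTSettings = field(default_factory=EFASTSettings)

    def __post_init__(self) -> None:
        if not self.parameters:
            raise ConfigurationError("at least one parameter is required")
        if not self.responses:
            raise ConfigurationError("at least one response measure is required")
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigurationError(f"duplicate parameter names: {dupes}")
        if len(set(self.responses)) != len(self.responses):
            raise ConfigurationError("duplicate response names")

    def parameter(self, name: str) -> ParameterSpec:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(name)


@dataclass
class ReplicateTable:
    """Responses of repeated runs under one parameter assignment.

    ``data`` holds one row per simulation run and one column per response
    measure; after ingestion through :func:`read_responses` there are no
    missing cells.
    """

    condition_id: str
    data: pd.DataFrame

    @property
    def n_runs(self) -> int:
        return len(self.data)

    @property
    def responses(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate an experiment configuration from a YAML file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"configuration file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"{path}: configuration must be a mapping")

    specs: list[ParameterSpec] = []
    for entry in raw.get("parameters") or []:
        if not isinstance(entry, Mapping):
            raise ConfigurationError(f"{path}: each parameter entry must be a mapping")
        try:
            increment = entry.get("increment")
            specs.append(
                ParameterSpec(
                    name=str(entry["name"]),
                    lower=float(entry["lower"]),
                    upper=float(entry["upper"]),
                    calibrated=float(entry["calibrated"]),
                    increment=None if increment is None else float(increment),
                )
            )
        except KeyError as exc:
            raise ConfigurationError(
                f"{path}: parameter entry missing required field {exc}"
            ) from exc

    responses = tuple(str(r) for r in (raw.get("responses") or []))

    def _block(key: str) -> Mapping:
        block = raw.get(key) or {}
        if not isinstance(block, Mapping):
            raise ConfigurationError(f"{path}: section {key!r} must be a mapping")
        return block

    cons = _block("consistency")
    lhs = _block("lhs")
    efast = _block("efast")
    return ExperimentConfig(
        parameters=tuple(specs),
        responses=responses,
        seed=int(raw.get("seed", 0)),
        consistency=ConsistencySettings(
            sample_sizes=tuple(int(s) for s in cons.get("sample_sizes", (1, 5, 50, 100, 300, 500))),
            subset_count=int(cons.get("subset_count", 20)),
        ),
        lhs=LHSSettings(
            n_sets=int(lhs.get("n_sets", 500)),
            candidates=int(lhs.get("candidates", 20)),
        ),
        efast=EFASTSettings(
            ns=int(efast.get("ns", 65)),
            nr=int(efast.get("nr", 3)),
            m=int(efast.get("m", 4)),
            dummy_name=str(efast.get("dummy_name", "dummy")),
        ),
    )


def read_responses(path: str | Path, responses: Sequence[str]) -> ReplicateTable:
    """Read a delimited response table, keeping only complete numeric rows.

    Rows with missing or non-numeric cells in any requested response column
    are dropped with a logged warning and count; a missing response column
    is a hard error listing the columns that are available.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in responses if c not in frame.columns]
    if missing:
        raise ValueError(
            f"{path}: missing response column(s) {missing}; "
            f"available columns: {list(frame.columns)}"
        )
    data = frame[list(responses)].apply(pd.to_numeric, errors="coerce")
    bad = data.isna().any(axis=1)
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning(
            "%s: excluded %d of %d rows with missing or non-numeric cells",
            path,
            n_bad,
            len(data),
        )
        data = data.loc[~bad]
    return ReplicateTable(condition_id=path.stem, data=data.reset_index(drop=True))


def write_design(design, directory: str | Path) -> list[Path]:
    """Write a sampling design to ``directory``, one CSV per design file.

    eFAST designs emit one file per (parameter-of-interest, curve) pair,
    named ``curve<c>_param<name>.csv``; LHS and one-at-a-time designs emit
    a single file of all parameter sets.  Returns the paths written.
    """
    frames = design.design_files()
    if not frames:
        raise ValueError("cannot write an empty design")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for filename, frame in frames.items():
        if len(frame) == 0:
            raise ValueError(f"cannot write empty design file {filename!r}")
        target = directory / filename
        frame.to_csv(target, index=False)
        written.append(target)
    logger.info("wrote %d design file(s) to %s", len(written), directory)
    return written


def format_value(value: float) -> str:
    """Canonical short rendering of a parameter value for file names.

    Six significant digits, trailing noise from float grid arithmetic
    removed, so the sampler and the analyser agree on condition names.
    """
    return format(float(value), ".6g")


def ensure_directory(path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    return path
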