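"""Data model and CSV I/O for probabilistic-sensitivity-analysis samples.

A PSA run of a health-economic decision model produces ``S`` draws from the
joint distribution of the model parameters together with, for each draw and
each treatment ``t``, either the monetary net benefit directly or an
(effectiveness, cost) pair that yields it as ``NB_t = k*e_t - c_t`` at a
willingness-to-pay ``k``.  Everything downstream (EVPI/EVPPI estimators,
regressions) consumes the :class:`PsaDataset` container defined here.

CSV layout: one header row; parameter columns carry their own names;
net-benefit columns are ``nb_<label>``; alternatively effectiveness/cost
pairs ``e_<label>``/``c_<label>`` may be given and combined with ``k`` at
read time.  Comma separator, ``.`` decimal, UTF-8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParameterDraws",
    "NetBenefitTable",
    "PsaDataset",
    "PsaDataError",
    "PsaInputError",
    "compute_net_benefits",
    "read_psa",
    "write_psa",
    "select_parameters",
]


class PsaInputError(ValueError):
    """Malformed request: bad shapes, unknown names, invalid options."""


class PsaDataError(ValueError):
    """Malformed data: NaN/inf cells, missing columns, duplicates."""


def _as_2d_float(values, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise PsaInputError(f"{what} must be a 2-D table, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise PsaDataError(f"{what} contains non-finite entries")
    return arr


@dataclass
class ParameterDraws:
    """``S x P`` table of simulated parameter values with unique column names."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.names = [str(n) for n in self.names]
        self.values = _as_2d_float(self.values, "parameter draws")
        if len(set(self.names)) != len(self.names):
            raise PsaDataError("duplicate parameter names")
        if self.values.shape[1] != len(self.names):
            raise PsaInputError(
                f"{len(self.names)} names but {self.values.shape[1]} columns"
            )
        if self.values.shape[0] < 2:
            raise PsaInputError("need at least S=2 draws")

    @property
    def S(self) -> int:
        return self.values.shape[0]

    @property
    def P(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)


@dataclass
class NetBenefitTable:
    """``S x T`` monetary net benefits at willingness-to-pay ``k``."""

    values: np.ndarray
    k: float
    treatment_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = _as_2d_float(self.values, "net benefits")
        if self.values.shape[1] < 2:
            raise PsaInputError("need at least T=2 treatments")
        if self.k < 0:
            raise PsaInputError("willingness-to-pay k must be >= 0")
        if not self.treatment_labels:
            self.treatment_labels = [f"t{j}" for j in range(self.values.shape[1])]
        self.treatment_labels = [str(t) for t in self.treatment_labels]
        if len(self.treatment_labels) != self.values.shape[1]:
            raise PsaInputError("treatment_labels length mismatch")

    @property
    def S(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]


@dataclass
class PsaDataset:
    """Row-aligned parameter draws and net benefits (draw s produced row s)."""

    draws: ParameterDraws
    nb: NetBenefitTable
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.draws.S != self.nb.S:
            raise PsaInputError(
                f"draws have S={self.draws.S} rows but net benefits S={self.nb.S}"
            )

    @property
    def S(self) -> int:
        return self.draws.S


def compute_net_benefits(effects, costs, k: float,
                         treatment_labels: list[str] | None = None) -> NetBenefitTable:
    """Monetary net benefit ``NB_t = k * e_t - c_t`` per draw and treatment."""
    e = _as_2d_float(effects, "effects")
    c = _as_2d_float(costs, "costs")
    if e.shape != c.shape:
        raise PsaInputError(f"effects shape {e.shape} != costs shape {c.shape}")
    if k < 0:
        raise PsaInputError("willingness-to-pay k must be >= 0")
    return NetBenefitTable(k * e - c, k=k, treatment_labels=treatment_labels or [])


def _split_columns(columns: list[str]):
    nb_cols = [c for c in columns if c.startswith("nb_")]
    e_cols = [c for c in columns if c.startswith("e_")]
    c_cols = [c for c in columns if c.startswith("c_")]
    par_cols = [c for c in columns if c not in nb_cols + e_cols + c_cols]
    return par_cols, nb_cols, e_cols, c_cols


def read_psa(path, k: float | None = None, provenance: str = "") -> PsaDataset:
    """Read a PSA CSV into a :class:`PsaDataset`.

    The file must contain either ``nb_*`` columns (then ``k`` is optional
    metadata, default 0 … the net benefits are taken as-is) or matching
    ``e_*``/``c_*`` pairs, in which case ``k`` is required and net benefits
    are computed on the fly.
    """
    try:
        frame = pd.read_csv(path)
    except ValueError as exc:
        raise PsaDataError(f"cannot parse {path}: {exc}") from exc
    cols = list(frame.columns)
    if len(set(cols)) != len(cols):
        raise PsaDataError("duplicate column names in CSV")
    par_cols, nb_cols, e_cols, c_cols = _split_columns(cols)
    for col in cols:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            raise PsaDataError(f"non-numeric cells in column {col!r}")
    if frame.isna().any().any():
        bad = [c for c in cols if frame[c].isna().any()]
        raise PsaDataError(f"NaN cells in columns {bad}")
    if not par_cols:
        raise PsaDataError("no parameter columns found")

    draws = ParameterDraws(par_cols, frame[par_cols].to_numpy(float))
    if nb_cols:
        labels = [c[len("nb_"):] for c in nb_cols]
        nb = NetBenefitTable(frame[nb_cols].to_numpy(float),
                             k=0.0 if k is None else k,
                             treatment_labels=labels)
    else:
        labels_e = sorted(c[len("e_"):] for c in e_cols)
        labels_c = sorted(c[len("c_"):] for c in c_cols)
        if not labels_e or labels_e != labels_c:
            raise PsaDataError(
                "need nb_* columns or matching e_*/c_* pairs; "
                f"found e:{labels_e} c:{labels_c}"
            )
        if k is None:
            raise PsaInputError("k is required when reading e_*/c_* columns")
        e = frame[[f"e_{t}" for t in labels_e]].to_numpy(float)
        c = frame[[f"c_{t}" for t in labels_e]].to_numpy(float)
        nb = compute_net_benefits(e, c, k, treatment_labels=labels_e)
    return PsaDataset(draws, nb, provenance=provenance or str(path))


def write_psa(dataset: PsaDataset, path) -> None:
    """Write a dataset as CSV; ``read_psa`` round-trips the values."""
    frame = dataset.draws.to_frame()
    for j, label in enumerate(dataset.nb.treatment_labels):
        frame[f"nb_{label}"] = dataset.nb.values[:, j]
    frame.to_csv(path, index=False)


def select_parameters(dataset: PsaDataset, focal_names: list[str],
                      standardize: bool = False) -> ParameterDraws:
    """Extract the focal-parameter columns, optionally standardized.

    Standardization centres each column and scales it to unit sample
    standard deviation (divisor S-1); the regressions and the mesh both
    assume inputs on comparable scales, so rescaling is applied before any
    projection.  Constant columns map to zeros with a warning.
    """
    if not focal_names:
        raise PsaInputError("empty focal-parameter selection")
    unknown = [n for n in focal_names if n not in dataset.draws.names]
    if unknown:
        raise PsaInputError(f"unknown parameter names: {unknown}")
    idx = [dataset.draws.names.index(n) for n in focal_names]
    values = dataset.draws.values[:, idx].copy()
    if standardize:
        mean = values.mean(axis=0)
        sd = values.std(axis=0, ddof=1)
        constant = sd == 0.0
        if constant.any():
            names = [n for n, c in zip(focal_names, constant) if c]
            warnings.warn(f"constant focal columns standardized to zero: {names}")
        sd = np.where(constant, 1.0, sd)
        values = (values - mean) / sd
        values[:, constant] = 0.0
    return ParameterDraws(list(focal_names), values)
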