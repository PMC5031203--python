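"""Monte-Carlo reference estimators of EVPI and EVPPI.

The expected value of perfect information is the expected opportunity loss
of deciding under current uncertainty,

    EVPI = E_theta[max_t NB_t(theta)] - max_t E_theta[NB_t(theta)],

estimated from PSA samples as mean-of-row-maxima minus max-of-column-means.
The partial-information analogue for a focal subset phi replaces NB_t by
the conditional expectation g_t(phi) = E_{psi|phi}[NB_t]; the same
"combiner" applied to fitted or analytic g_t values gives the EVPPI.  Both
a nested two-loop scheme (general) and a single-loop scheme (when the
conditional expectation is available in closed form) are provided.

All regression estimators in this package reduce to ``evppi_from_fitted``
once they have produced fitted conditional expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .psa import NetBenefitTable, PsaInputError

__all__ = [
    "VoiEstimate",
    "NestedMcPlan",
    "evpi_mc",
    "evppi_from_fitted",
    "evppi_nested_mc",
    "evppi_single_loop",
    "voi_combiner",
]

# EVPI/EVPPI are non-negative in theory; estimates below -NEG_TOL * scale
# indicate estimator failure and are flagged (never silently clipped).
_NEG_TOL = 1e-8


@dataclass
class VoiEstimate:
    """An EVPI or EVPPI value with enough metadata to reproduce it."""

    value: float
    kind: str  # "EVPI" or "EVPPI"
    method: str
    focal_names: list[str] = field(default_factory=list)
    k: float = 0.0
    S: int = 0
    seed: int | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("EVPI", "EVPPI"):
            raise PsaInputError(f"kind must be EVPI or EVPPI, got {self.kind!r}")

    def __float__(self) -> float:
        return float(self.value)


@dataclass
class NestedMcPlan:
    """Outer/inner sample sizes for the two-loop EVPPI estimator."""

    S_phi: int
    S_psi: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.S_phi < 2 or self.S_psi < 2:
            raise PsaInputError("nested-MC plan needs S_phi >= 2 and S_psi >= 2")


def voi_combiner(table: np.ndarray) -> tuple[float, dict]:
    """mean of row maxima minus max of column means, with a negativity flag."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2:
        raise PsaInputError("expected an S x T table with S >= 2")
    if not np.all(np.isfinite(table)):
        raise PsaInputError("non-finite entries in value table")
    value = float(table.max(axis=1).mean() - table.mean(axis=0).max())
    diagnostics: dict = {}
    scale = max(1.0, float(np.abs(table).max()))
    if value < -_NEG_TOL * scale:
        diagnostics["negative_estimate"] = value
    return value, diagnostics


def evpi_mc(nb: NetBenefitTable, method: str = "mc") -> VoiEstimate:
    """Plug-in EVPI estimate from the PSA net-benefit sample."""
    value, diag = voi_combiner(nb.values)
    return VoiEstimate(value=value, kind="EVPI", method=method, k=nb.k,
                       S=nb.S, diagnostics=diag)


def evppi_from_fitted(ghat: np.ndarray, *, method: str,
                      focal_names: list[str] | None = None,
                      k: float = 0.0, seed: int | None = None,
                      diagnostics: dict | None = None) -> VoiEstimate:
    """EVPPI from an ``S x T`` table of (fitted) conditional expectations."""
    ghat = np.asarray(ghat, dtype=float)
    value, diag = voi_combiner(ghat)
    if diagnostics:
        diag = {**diagnostics, **diag}
    return VoiEstimate(value=value, kind="EVPPI", method=method,
                       focal_names=list(focal_names or []), k=k,
                       S=ghat.shape[0], seed=seed, diagnostics=diag)


def evppi_nested_mc(model, focal_names: list[str], plan: NestedMcPlan,
                    k: float) -> VoiEstimate:
    """Two-loop EVPPI: outer draws of phi, inner conditional draws of psi.

    ``model`` must expose ``parameter_names``, ``sample_focal(names, n,
    rng)`` returning an ``n x |phi|`` array, ``sample_nuisance(names,
    phi_row, n, rng)`` returning ``n x |psi|`` conditional draws, and
    ``net_benefits(draws_by_name, k)``.  Deterministic given ``plan.seed``;
    inner streams are spawned from a seed sequence so the outer loop is
    order-independent.
    """
    for attr in ("sample_focal", "sample_nuisance", "net_benefits"):
        if not hasattr(model, attr):
            raise PsaInputError(
                f"model lacks {attr}; cannot run the nested-MC estimator")
    names = list(model.parameter_names)
    focal = list(focal_names)
    unknown = [n for n in focal if n not in names]
    if unknown:
        raise PsaInputError(f"unknown focal parameters: {unknown}")
    nuisance = [n for n in names if n not in focal]

    root = np.random.SeedSequence(plan.seed)
    outer_ss, inner_ss = root.spawn(2)
    rng = np.random.default_rng(outer_ss)
    phi = np.asarray(model.sample_focal(focal, plan.S_phi, rng), dtype=float)
    inner_streams = inner_ss.spawn(plan.S_phi)

    T = None
    ghat = None
    for s in range(plan.S_phi):
        inner_rng = np.random.default_rng(inner_streams[s])
        if nuisance:
            psi = np.asarray(
                model.sample_nuisance(nuisance, phi[s], plan.S_psi, inner_rng),
                dtype=float)
            draws = {n: np.full(plan.S_psi, phi[s, j]) for j, n in enumerate(focal)}
            draws.update({n: psi[:, j] for j, n in enumerate(nuisance)})
        else:
            draws = {n: np.full(1, phi[s, j]) for j, n in enumerate(focal)}
        nb = np.asarray(model.net_benefits(draws, k), dtype=float)
        if ghat is None:
            T = nb.shape[1]
            ghat = np.empty((plan.S_phi, T))
        ghat[s] = nb.mean(axis=0)

    return evppi_from_fitted(
        ghat, method="mc-nested", focal_names=focal, k=k, seed=plan.seed,
        diagnostics={"S_phi": plan.S_phi, "S_psi": plan.S_psi})


def evppi_single_loop(model, focal_names: list[str], S_phi: int,
                      seed: int | None, k: float,
                      chunk: int = 1_000_000) -> VoiEstimate:
    """Single-loop EVPPI using the model's analytic conditional expectation.

    Requires ``model.conditional_expectation(phi_draws, focal_names, k)``
    returning the exact ``n x T`` table E[NB_t | phi].  Draws phi from its
    marginal, evaluates the closed form, and applies the combiner.  Work is
    chunked so very large ``S_phi`` stays within memory; the estimate is
    identical to the unchunked one because the combiner only needs running
    sums of per-row maxima and of columns.
    """
    if not hasattr(model, "conditional_expectation"):
        raise PsaInputError(
            "model lacks conditional_expectation; use evppi_nested_mc")
    focal = list(focal_names)
    rng = np.random.default_rng(seed)
    if not focal:
        # No information gained: conditional expectation is the prior mean.
        return VoiEstimate(value=0.0, kind="EVPPI", method="single-loop",
                           focal_names=[], k=k, S=S_phi, seed=seed,
                           diagnostics={"note": "empty focal set"})
    sum_rowmax = 0.0
    sum_cols = None
    sum_rowmax_sq = 0.0
    done = 0
    while done < S_phi:
        n = min(chunk, S_phi - done)
        phi = np.asarray(model.sample_focal(focal, n, rng), dtype=float)
        g = np.asarray(model.conditional_expectation(phi, focal, k), dtype=float)
        rowmax = g.max(axis=1)
        sum_rowmax += float(rowmax.sum())
        sum_rowmax_sq += float((rowmax ** 2).sum())
        sum_cols = g.sum(axis=0) if sum_cols is None else sum_cols + g.sum(axis=0)
        done += n
    mean_rowmax = sum_rowmax / S_phi
    value = mean_rowmax - float(np.max(sum_cols / S_phi))
    se_rowmax = float(
        np.sqrt(max(sum_rowmax_sq / S_phi - mean_rowmax ** 2, 0.0) / S_phi))
    diag = {"mc_se_rowmax": se_rowmax}
    scale = max(1.0, abs(mean_rowmax))
    if value < -_NEG_TOL * scale:
        diag["negative_estimate"] = value
    return VoiEstimate(value=value, kind="EVPPI", method="single-loop",
                       focal_names=focal, k=k, S=S_phi, seed=seed,
                       diagnostics=diag)
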