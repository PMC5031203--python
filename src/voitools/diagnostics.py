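"""Model checking for EVPPI regressions.

Two audits are provided: residual-structure checks (structured residuals
mean the regression curve missed part of the relationship between net
benefit and the focal parameters) and a monotonicity audit (EVPPI is
non-decreasing in the focal set, so estimates along a nested chain of
subsets must not decrease beyond estimator noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.sandbox.stats.runs import runstest_1samp

from .mc import VoiEstimate
from .psa import PsaDataset, PsaInputError

__all__ = ["ResidualReport", "MonotonicityReport", "residual_check",
           "monotonicity_check"]

# declared defaults: the literature prescribes residual checking but no
# cutoffs, so these are package choices
AUTOCORR_THRESHOLD = 0.2
RUNS_ALPHA = 0.01


@dataclass
class ResidualReport:
    residuals: np.ndarray
    lag1_autocorr: np.ndarray      # one value per ordering coordinate
    runs_z: float
    runs_p: float
    passed: bool
    notes: dict = field(default_factory=dict)


def _lag1(x: np.ndarray) -> float:
    if x.size < 3 or x.std() == 0:
        return 0.0
    a, b = x[:-1], x[1:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def residual_check(residuals: np.ndarray, coordinates: np.ndarray,
                   autocorr_threshold: float = AUTOCORR_THRESHOLD,
                   runs_alpha: float = RUNS_ALPHA) -> ResidualReport:
    """Structure statistics for one contrast's residuals.

    Residuals are sorted along each projected coordinate and their lag-1
    autocorrelation computed; a Wald-Wolfowitz runs test (about zero) is
    run on the residual signs in the first coordinate's order.  The check
    passes iff every |autocorrelation| < ``autocorr_threshold`` and the
    runs-test p-value exceeds ``runs_alpha``.
    """
    r = np.asarray(residuals, dtype=float)
    coords = np.atleast_2d(np.asarray(coordinates, dtype=float))
    if coords.shape[0] != r.shape[0]:
        coords = coords.T
    if coords.shape[0] != r.shape[0]:
        raise PsaInputError("coordinates and residuals length mismatch")
    if np.allclose(r, 0.0):
        return ResidualReport(residuals=r,
                              lag1_autocorr=np.zeros(coords.shape[1]),
                              runs_z=0.0, runs_p=1.0, passed=True,
                              notes={"zero_residuals": True})
    acs = np.array([_lag1(r[np.argsort(coords[:, j], kind="stable")])
                    for j in range(coords.shape[1])])
    order = np.argsort(coords[:, 0], kind="stable")
    z, p = runstest_1samp(r[order], cutoff=0.0, correction=True)
    passed = bool(np.all(np.abs(acs) < autocorr_threshold) and p > runs_alpha)
    return ResidualReport(residuals=r, lag1_autocorr=acs, runs_z=float(z),
                          runs_p=float(p), passed=passed)


@dataclass
class MonotonicityReport:
    focal_sets: list[list[str]]
    estimates: list[float]
    violations: list[dict]
    tolerance: float
    passed: bool


def monotonicity_check(psa: PsaDataset | None, nested_focal_sets,
                       estimator, tolerance_frac: float = 0.02
                       ) -> MonotonicityReport:
    """Audit EVPPI monotonicity along a chain of strictly nested focal sets.

    ``estimator`` is either a callable ``(psa, focal_names) ->
    VoiEstimate`` / number, or a string naming a built-in regression method
    ("gp" or "spde") applied to ``psa``.  A decrease larger than
    ``tolerance_frac`` times the final (largest-set) estimate is flagged.
    """
    sets = [list(s) for s in nested_focal_sets]
    if not sets:
        raise PsaInputError("need at least one focal set")
    for a, b in zip(sets, sets[1:]):
        if not set(a) < set(b):
            raise PsaInputError(f"focal sets not strictly nested: {a} vs {b}")

    if isinstance(estimator, str):
        if estimator == "gp":
            from .gp import gp_evppi
            fn = lambda p, s: gp_evppi(p, s)[0]
        elif estimator == "spde":
            from .spde import spde_evppi
            fn = lambda p, s: spde_evppi(p, s)[0]
        else:
            raise PsaInputError(f"unknown estimator {estimator!r}")
    else:
        fn = estimator

    estimates = []
    for s in sets:
        est = fn(psa, s)
        estimates.append(float(est.value if isinstance(est, VoiEstimate)
                               else est))
    tol = tolerance_frac * abs(estimates[-1])
    violations = [
        {"from_set": sets[i], "to_set": sets[i + 1],
         "decrease": estimates[i] - estimates[i + 1], "tolerance": tol}
        for i in range(len(estimates) - 1)
        if estimates[i + 1] < estimates[i] - tol
    ]
    return MonotonicityReport(focal_sets=sets, estimates=estimates,
                              violations=violations, tolerance=tol,
                              passed=not violations)
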