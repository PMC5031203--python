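"""Dense Gaussian-process regression of net benefits on focal parameters.

The net benefit for treatment ``t`` at PSA draw ``s`` is treated as a noisy
observation of the conditional expectation ``g_t(phi_s)``:

    NB_t(theta_s) = g_t(phi_s) + eps_s,   eps_s ~ N(0, sigma_eps^2),

with a GP prior on ``g_t``: mean ``H beta`` (intercept plus linear terms)
and squared-exponential covariance

    C(r, s) = sigma^2 exp(-sum_p ((phi_rp - phi_sp) / delta_p)^2).

The model has 2P + 3 hyperparameters: beta (P + 1), the per-dimension
smoothness delta (P), the marginal variance sigma^2 and the nugget
sigma_eps^2.  beta (flat prior) and sigma^2 (prior 1/sigma^2) are
integrated analytically; the profile objective in (log delta, log eta)
with eta = sigma_eps^2 / sigma^2 is minimized numerically with an analytic
gradient and multiple starts.  Hyperparameters are estimated on a seeded
subsample (default 500 draws) and the fitted values are then computed on
the full sample, whose row maxima/column means give the EVPPI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .mc import VoiEstimate, evppi_from_fitted
from .psa import PsaDataset, PsaInputError, select_parameters

__all__ = [
    "GpHyperparams",
    "GpContrastFit",
    "GpFit",
    "design_matrix",
    "sqexp_cov",
    "gp_neg_log_marginal",
    "gp_fit",
    "gp_evppi",
]

_JITTER0 = 1e-10
_JITTER_MAX = 1e-6


@dataclass
class GpHyperparams:
    delta: np.ndarray      # length-P positive smoothness parameters
    sigma2: float          # GP marginal variance
    nugget: float          # residual variance sigma_eps^2
    beta: np.ndarray       # length-(P+1) regression coefficients

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        if np.any(self.delta <= 0) or self.sigma2 <= 0 or self.nugget < 0:
            raise PsaInputError("invalid GP hyperparameters")


@dataclass
class GpContrastFit:
    """One incremental-net-benefit regression."""

    hyper: GpHyperparams | None
    fitted: np.ndarray
    subsample_index: np.ndarray
    converged: bool
    trace: dict = field(default_factory=dict)


@dataclass
class GpFit:
    """Per-contrast fits and the assembled S x T fitted-value table
    (reference arm fixed at zero)."""

    contrasts: list[GpContrastFit]
    fitted: np.ndarray
    subsample_index: np.ndarray

    @property
    def converged(self) -> bool:
        return all(c.converged for c in self.contrasts)


def design_matrix(phi: np.ndarray) -> np.ndarray:
    """Intercept column followed by the focal-parameter columns."""
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 1:
        phi = phi[:, None]
    if phi.size and not np.all(np.isfinite(phi)):
        raise PsaInputError("non-finite design inputs")
    return np.hstack([np.ones((phi.shape[0], 1)), phi])


def sqexp_cov(phi_r, phi_s, delta, sigma2: float = 1.0) -> np.ndarray:
    """Squared-exponential covariance between two point sets (R x S block)."""
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    if np.any(delta <= 0):
        raise PsaInputError("delta must be positive")
    a = np.atleast_2d(np.asarray(phi_r, dtype=float))
    b = np.atleast_2d(np.asarray(phi_s, dtype=float))
    diff = (a[:, None, :] - b[None, :, :]) / delta
    return sigma2 * np.exp(-(diff ** 2).sum(axis=-1))


class _MarginalObjective:
    """Negative log marginal posterior of (log delta, log eta) with
    beta and sigma^2 integrated analytically; value and gradient."""

    def __init__(self, y: np.ndarray, phi: np.ndarray):
        self.y = np.asarray(y, dtype=float)
        phi = np.asarray(phi, dtype=float)
        if phi.ndim == 1:
            phi = phi[:, None]
        self.phi = phi
        self.n, self.P = phi.shape
        if self.n <= self.P + 2:
            raise PsaInputError("need n > P + 2 draws to estimate the GP")
        self.H = design_matrix(phi)
        # squared pairwise differences per focal dimension
        self.D = (phi[:, None, :] - phi[None, :, :]) ** 2
        self.m = self.n - self.P - 1

    def _corr(self, delta: np.ndarray) -> np.ndarray:
        return np.exp(-(self.D / (delta ** 2)).sum(axis=-1))

    def __call__(self, params: np.ndarray):
        delta = np.exp(params[:-1])
        eta = np.exp(params[-1])
        R = self._corr(delta)
        Sigma = R + eta * np.eye(self.n)
        jitter = _JITTER0
        while True:
            try:
                L = linalg.cho_factor(
                    Sigma + jitter * np.eye(self.n), lower=True)
                break
            except linalg.LinAlgError:
                jitter *= 10.0
                if jitter > _JITTER_MAX:
                    raise
        logdet_S = 2.0 * np.log(np.diag(L[0])).sum()
        W = linalg.cho_solve(L, self.H)            # Sigma^-1 H
        M = self.H.T @ W
        sign, logdet_M = np.linalg.slogdet(M)
        if sign <= 0:
            return np.inf, np.zeros_like(params)
        alpha = linalg.cho_solve(L, self.y)
        hta = self.H.T @ alpha
        beta = np.linalg.solve(M, hta)
        Q = float(self.y @ alpha - hta @ beta)
        if Q <= 0:
            return np.inf, np.zeros_like(params)
        value = 0.5 * logdet_S + 0.5 * logdet_M + 0.5 * self.m * np.log(Q)

        # gradient: A = 0.5 (Sigma^-1 - V) - (m / 2Q) (Py)(Py)^T, with
        # V = W M^-1 W^T and Py = alpha - W beta; df = sum(A * dSigma).
        Sinv = linalg.cho_solve(L, np.eye(self.n))
        V = W @ np.linalg.solve(M, W.T)
        Py = alpha - W @ beta
        A = 0.5 * (Sinv - V) - (0.5 * self.m / Q) * np.outer(Py, Py)
        grad = np.empty_like(params)
        for p in range(self.P):
            dSigma = R * (2.0 * self.D[:, :, p] / delta[p] ** 2)
            grad[p] = float((A * dSigma).sum())
        grad[-1] = eta * float(np.trace(A))
        return value, grad


def gp_neg_log_marginal(log_delta, log_eta, y, phi) -> float:
    """Profile negative log marginal posterior at (log delta, log eta)."""
    obj = _MarginalObjective(y, phi)
    params = np.concatenate([np.atleast_1d(log_delta), [float(log_eta)]])
    return float(obj(params)[0])


def _optimize(obj: _MarginalObjective, seed, starts: int, maxiter: int):
    rng = np.random.default_rng(seed)
    span = obj.phi.max(axis=0) - obj.phi.min(axis=0)
    span = np.where(span > 0, span, 1.0)
    inits = [np.concatenate([np.log(span), [np.log(0.1)]])]
    for _ in range(starts):
        ld = np.log(span) + rng.uniform(-2.0, 2.0, size=obj.P)
        le = rng.uniform(np.log(1e-3), np.log(10.0))
        inits.append(np.concatenate([ld, [le]]))
    bounds = ([(np.log(1e-3 * s), np.log(1e3 * s)) for s in span]
              + [(np.log(1e-8), np.log(1e4))])
    best, trace = None, []
    for x0 in inits:
        try:
            res = optimize.minimize(obj, x0, jac=True, method="L-BFGS-B",
                                    bounds=bounds,
                                    options={"maxiter": maxiter})
        except linalg.LinAlgError:
            trace.append({"status": "factorization failed"})
            continue
        trace.append({"fun": float(res.fun), "success": bool(res.success),
                      "nit": int(res.nit)})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"all GP optimizer starts failed: {trace}")
    return best, trace


def gp_fit(y: np.ndarray, phi: np.ndarray, subsample_size: int = 500,
           seed: int | None = None, starts: int = 3,
           maxiter: int = 200) -> GpContrastFit:
    """Fit one GP regression: hyperparameters on a seeded subsample, fitted
    values on all draws via the posterior mean g = H beta + C (C +
    nugget I)^-1 (y - H beta) with generalized-least-squares beta."""
    y = np.asarray(y, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 1:
        phi = phi[:, None]
    S = y.shape[0]
    if phi.shape[0] != S:
        raise PsaInputError("y and phi row counts differ")

    # constant focal columns carry no signal for the covariance
    keep = phi.std(axis=0) > 0
    if not keep.all():
        warnings.warn("dropping constant focal columns from the GP covariance")
    phi_cov = phi[:, keep]

    sd_y = y.std()
    if sd_y == 0 or phi_cov.shape[1] == 0:
        fitted = np.full(S, y.mean())
        return GpContrastFit(hyper=None, fitted=fitted,
                             subsample_index=np.arange(0),
                             converged=True, trace={"degenerate": True})

    rng = np.random.default_rng(seed)
    n_sub = min(subsample_size, S)
    idx = np.sort(rng.choice(S, size=n_sub, replace=False))
    obj = _MarginalObjective(y[idx], phi_cov[idx])
    best, trace = _optimize(obj, rng, starts, maxiter)
    delta = np.exp(best.x[:-1])
    eta = float(np.exp(best.x[-1]))

    # full-sample fitted values; sigma^2 cancels from C (C + nugget I)^-1
    R = sqexp_cov(phi_cov, phi_cov, delta)
    Sigma = R + (eta + _JITTER0) * np.eye(S)
    L = linalg.cho_factor(Sigma, lower=True)
    H = design_matrix(phi)
    W = linalg.cho_solve(L, H)
    M = H.T @ W
    beta = np.linalg.solve(M, W.T @ y)
    resid = y - H @ beta
    fitted = y - eta * linalg.cho_solve(L, resid)

    alpha_s = obj(best.x)  # recompute Q for the variance estimate
    # quadratic form at the optimum (subsample scale)
    sub_obj_val = float(alpha_s[0])
    # sigma^2 posterior mode given (delta, eta) on the subsample
    Rs = sqexp_cov(phi_cov[idx], phi_cov[idx], delta)
    Ls = linalg.cho_factor(Rs + (eta + _JITTER0) * np.eye(n_sub), lower=True)
    Hs = design_matrix(phi[idx])
    Ws = linalg.cho_solve(Ls, Hs)
    Ms = Hs.T @ Ws
    ys = y[idx]
    betas = np.linalg.solve(Ms, Ws.T @ ys)
    Qs = float(ys @ linalg.cho_solve(Ls, ys) - (Hs.T @ linalg.cho_solve(Ls, ys)) @ betas)
    # Qs can underflow to ~0 when the response is exactly linear in phi
    sigma2 = max(Qs / max(obj.m, 1), 1e-12 * float(ys.var() + 1e-300))
    hyper_delta = np.full(phi.shape[1], np.inf)
    hyper_delta[keep] = delta
    hyper = GpHyperparams(delta=np.where(np.isfinite(hyper_delta),
                                         hyper_delta, 1e6),
                          sigma2=sigma2, nugget=eta * sigma2, beta=beta)
    return GpContrastFit(hyper=hyper, fitted=fitted, subsample_index=idx,
                         converged=bool(best.success),
                         trace={"objective": sub_obj_val, "starts": trace})


def gp_evppi(psa: PsaDataset, focal_names: list[str],
             subsample_size: int = 500, seed: int | None = None,
             starts: int = 3, maxiter: int = 200
             ) -> tuple[VoiEstimate, GpFit]:
    """EVPPI by dense GP regression of incremental net benefits.

    The focal columns are standardized; each incremental contrast
    ``NB_t - NB_0`` is regressed separately with the reference arm fixed at
    zero (the EVPPI combiner is invariant to subtracting any common
    function of phi from all arms).
    """
    phi = select_parameters(psa, focal_names, standardize=True).values
    nb = psa.nb.values
    S, T = nb.shape
    fitted = np.zeros((S, T))
    contrasts = []
    for t in range(1, T):
        fit = gp_fit(nb[:, t] - nb[:, 0], phi, subsample_size=subsample_size,
                     seed=None if seed is None else seed + t,
                     starts=starts, maxiter=maxiter)
        if not fit.converged:
            warnings.warn(f"GP optimizer did not converge for contrast {t}")
        fitted[:, t] = fit.fitted
        contrasts.append(fit)
    gfit = GpFit(contrasts=contrasts, fitted=fitted,
                 subsample_index=contrasts[0].subsample_index)
    est = evppi_from_fitted(
        fitted, method="gp", focal_names=list(focal_names), k=psa.nb.k,
        seed=seed,
        diagnostics={"converged": gfit.converged,
                     "subsample_size": int(len(gfit.subsample_index))})
    return est, gfit
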