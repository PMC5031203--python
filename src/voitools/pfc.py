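"""Principal Fitted Components: sufficient dimension reduction of the
focal parameters against the net-benefit response.

PFC is a model-based *inverse* regression: the P focal parameters are
modelled as a linear function of basis functions of the response,

    phi = mu + Upsilon f(y) + eps,    eps ~ N(0, Delta),

where ``f(y)`` stacks centred polynomial terms ``y, y^2, ..., y^h`` and
``Upsilon`` is a P x d matrix whose columns, through the reduction
``R(phi) = Upsilon' Delta^{-1} phi``, estimate the sufficient subspace:
NB is independent of phi given R(phi).  Three error structures are
supported — isotropic (Delta = sigma^2 I), diagonal (independent
heteroskedastic) and unstructured (full Delta).  The unstructured variant
matters when the focal parameters are correlated: with Delta restricted to
a diagonal the estimated directions are biased towards the predictor
covariance, whereas the Delta^{-1}-weighted reduction recovers the
forward-regression directions.

Dimension ``d`` and degree ``h`` are chosen by AIC across a small grid;
the projection used downstream is always 2-D (the mesh-based regression
lives in the plane), with a ``sufficiency_ok`` flag recording whether the
AIC-optimal ``d`` exceeded two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .psa import PsaDataError, PsaInputError

__all__ = ["ResponseBasis", "PfcModel", "response_basis", "fit_pfc",
           "select_pfc", "project"]

_STRUCTURES = ("isotropic", "diagonal", "unstructured")


@dataclass
class ResponseBasis:
    degree: int
    basis: np.ndarray    # n x h, centred, orthogonalized across degrees


@dataclass
class PfcModel:
    mu: np.ndarray
    Upsilon: np.ndarray            # P x d direction matrix
    error_structure: str
    Delta_hat: np.ndarray          # scalar, length-P or P x P
    d: int
    h: int
    aic: float
    loglik: float
    sufficiency_ok: bool = True
    # eigenbasis in the whitened metric plus the whitening map, so a second
    # projection coordinate exists even when d = 1
    eigvecs: np.ndarray = field(default=None, repr=False)
    eigvals: np.ndarray = field(default=None, repr=False)
    whiten: np.ndarray = field(default=None, repr=False)   # P x P


def response_basis(y: np.ndarray, h: int) -> ResponseBasis:
    """Centred powers of the response, orthogonalized degree by degree.

    Orthogonalization (Gram-Schmidt against lower degrees) leaves the
    column span identical to span{y - mean, ..., y^h - mean} but keeps the
    inverse-regression design well conditioned for larger h.
    """
    y = np.asarray(y, dtype=float)
    if h < 1:
        raise PsaInputError("basis degree h must be >= 1")
    if h >= y.shape[0]:
        raise PsaInputError(f"h={h} must be smaller than n={y.shape[0]}")
    if not np.all(np.isfinite(y)):
        raise PsaDataError("non-finite response values")
    if y.std() == 0:
        raise PsaDataError("constant response: inverse regression undefined")
    # scale to unit sd so powers do not overflow for money-scale responses
    z = (y - y.mean()) / y.std()
    cols = []
    for j in range(1, h + 1):
        col = z ** j
        col = col - col.mean()
        for prev in cols:
            col = col - (col @ prev) / (prev @ prev) * prev
        norm = np.linalg.norm(col)
        if norm < 1e-12 * np.sqrt(len(z)):
            raise PsaDataError(f"response basis degenerate at degree {j}")
        cols.append(col)
    return ResponseBasis(degree=h, basis=np.column_stack(cols))


def _n_params(P: int, d: int, h: int, structure: str) -> int:
    # mu, Upsilon on its Grassmann manifold, basis coefficients, error scale
    error = {"isotropic": 1, "diagonal": P,
             "unstructured": P * (P + 1) // 2}[structure]
    return P + d * (P - d) + d * h + error


def _inv_sqrt(Delta: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(Delta)
    vals = np.maximum(vals, 1e-12 * vals.max())
    return vecs @ np.diag(vals ** -0.5) @ vecs.T


def fit_pfc(phi: np.ndarray, y: np.ndarray, d: int, h: int,
            error_structure: str = "isotropic",
            n_iter: int = 20) -> PfcModel:
    """Maximum-likelihood PFC fit for fixed (d, h, error structure).

    The diagonal and unstructured error covariances have no closed-form
    maximum-likelihood estimate; they are obtained by a short fixed-point
    iteration (whiten, rank-d eigenfit, update the residual covariance).
    """
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 1:
        phi = phi[:, None]
    n, P = phi.shape
    if n <= P:
        raise PsaInputError("need more draws than focal parameters (n > P)")
    if d < 1 or d > min(P, h):
        raise PsaInputError(f"need 1 <= d <= min(P, h); got d={d}, h={h}, P={P}")
    if error_structure not in _STRUCTURES:
        raise PsaInputError(f"unknown error structure {error_structure!r}")

    F = response_basis(y, h).basis
    mu = phi.mean(axis=0)
    X = phi - mu
    coef, *_ = np.linalg.lstsq(F, X, rcond=None)
    Fhat = F @ coef                        # n x P fitted inverse regression

    def rank_d_residual_cov(W):
        Z, Fz = X @ W, Fhat @ W
        Sfit = (Fz.T @ Fz) / n
        vals, vecs = np.linalg.eigh(Sfit)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        R = Z - (Fz @ vecs[:, :d]) @ vecs[:, :d].T
        return vals, vecs, (R.T @ R) / n

    if error_structure == "isotropic":
        W = np.eye(P)
        vals, vecs, Sres_z = rank_d_residual_cov(W)
        sigma2 = max(np.trace(Sres_z) / P, 1e-300)
        loglik = -0.5 * n * P * (np.log(2 * np.pi * sigma2) + 1.0)
        Delta_hat = np.asarray(sigma2)
    else:
        resid0 = X - Fhat
        if error_structure == "diagonal":
            delta = np.maximum((resid0 ** 2).mean(axis=0), 1e-12)
            W = np.diag(delta ** -0.5)
        else:
            Delta = (resid0.T @ resid0) / n
            W = _inv_sqrt(Delta)
        for _ in range(n_iter):
            vals, vecs, Sres_z = rank_d_residual_cov(W)
            Winv = np.linalg.inv(W)
            Delta = Winv @ Sres_z @ Winv.T
            if error_structure == "diagonal":
                delta_new = np.maximum(np.diag(Delta), 1e-12)
                W_new = np.diag(delta_new ** -0.5)
            else:
                W_new = _inv_sqrt(Delta)
            if np.allclose(W_new, W, rtol=1e-8, atol=0):
                W = W_new
                break
            W = W_new
        vals, vecs, Sres_z = rank_d_residual_cov(W)
        Winv = np.linalg.inv(W)
        Delta_full = Winv @ Sres_z @ Winv.T
        if error_structure == "diagonal":
            delta = np.maximum(np.diag(Delta_full), 1e-12)
            logdet = float(np.log(delta).sum())
            tr_term = float(np.trace(np.diag(1.0 / delta) @ Delta_full))
            Delta_hat = delta
        else:
            sign, logdet = np.linalg.slogdet(Delta_full)
            if sign <= 0:
                raise PsaDataError("singular residual covariance in PFC")
            tr_term = float(P)
            Delta_hat = Delta_full
        loglik = -0.5 * n * (P * np.log(2 * np.pi) + logdet + tr_term)

    Upsilon = np.linalg.inv(W) @ vecs[:, :d]   # back-transformed directions
    npar = _n_params(P, d, h, error_structure)
    return PfcModel(mu=mu, Upsilon=Upsilon, error_structure=error_structure,
                    Delta_hat=Delta_hat, d=d, h=h,
                    aic=float(-2.0 * loglik + 2.0 * npar),
                    loglik=float(loglik), eigvecs=vecs, eigvals=vals,
                    whiten=W)


def select_pfc(phi: np.ndarray, y: np.ndarray,
               d_grid=(1, 2, 3, 4), h_grid=(1, 2, 3, 4),
               structure_grid=("isotropic", "unstructured")) -> PfcModel:
    """AIC selection of (d, h, error structure) across the grids.

    Returns the AIC-minimizing model with ``sufficiency_ok`` set to whether
    the optimal structural dimension is at most two (the projection used
    downstream keeps two coordinates regardless; when d* = 1 the second
    coordinate only adds information, when d* > 2 information may be lost).
    """
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 1:
        phi = phi[:, None]
    n, P = phi.shape
    if not d_grid or not h_grid or not structure_grid:
        raise PsaInputError("empty selection grid")
    best, failures = None, []
    for structure in structure_grid:
        if structure == "unstructured" and n < 10 * P:
            continue   # full Delta too fragile at this n/P ratio
        for h in h_grid:
            for d in [dd for dd in d_grid if dd <= min(P, h)]:
                try:
                    model = fit_pfc(phi, y, d=d, h=h,
                                    error_structure=structure)
                except (PsaInputError, PsaDataError,
                        np.linalg.LinAlgError) as exc:
                    failures.append((structure, d, h, str(exc)))
                    continue
                if best is None or model.aic < best.aic:
                    best = model
    if best is None:
        raise RuntimeError(f"all PFC fits failed: {failures}")
    best.sufficiency_ok = best.d <= 2
    return best


def project(model: PfcModel, phi: np.ndarray) -> np.ndarray:
    """First two reduction coordinates, each standardized to mean zero and
    unit variance (constant coordinates are left at zero).

    When the structural dimension is one, the second coordinate is the next
    eigenvector in the whitened metric: it can only add information, so the
    reduction stays sufficient.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 1:
        phi = phi[:, None]
    P = phi.shape[1]
    ncoord = min(2, P)
    V = model.eigvecs[:, :ncoord]
    Z = (phi - model.mu) @ model.whiten
    coords = Z @ V
    if ncoord < 2:
        coords = np.column_stack([coords, np.zeros(phi.shape[0])])
    sd = coords.std(axis=0, ddof=1)
    out = (coords - coords.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    out[:, sd == 0] = 0.0
    return out
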