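"""REML variance components under the animal model y ~ N(Xb, G sa2 + I se2).

The restricted likelihood is profiled over the single ratio
lambda = sigma_a2/sigma_e2 after a one-off eigendecomposition of G: with
G = U D U', rotating y and X by U' makes V diagonal, so each profile
evaluation is O(n p^2).  The profile is maximized by bounded scalar search
in log(lambda); sigma_e2 then has a closed form.  Standard errors come from
the average-information matrix at the optimum via the delta method.

This is exact for a single genomic variance component and needs no
derivatives; an average-information Newton scheme would add nothing at
n ~ 10^3 but is the natural extension for multi-component models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .data import PhenotypeTable
from .kinship import GRM

log = logging.getLogger(__name__)

__all__ = ["VarianceComponents", "build_fixed_design", "fit_reml",
           "estimate_fixed_effects"]

LAMBDA_BOUNDS = (1e-6, 1e6)


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    h2: float
    se_h2: float
    loglik: float
    n_iter: int
    converged: bool
    at_boundary: bool = False

    def __post_init__(self) -> None:
        if self.sigma_a2 < 0 or self.sigma_e2 <= 0:
            raise ValueError("variance components out of range")
        if not (0 <= self.h2 <= 1):
            raise ValueError("h2 outside [0, 1]")


def build_fixed_design(pheno: PhenotypeTable, trait: str, use_age: bool = True):
    """Intercept + treatment-coded gender/farm/year (+ centered age).

    Rows are restricted to samples with an observed trait value; constant
    factors contribute no columns; aliased columns are dropped with a
    warning.  Returns (X, column names, row index into the table).
    """
    y = pheno.trait(trait)
    rows = np.flatnonzero(np.isfinite(y))
    if rows.size == 0:
        raise ValueError(f"trait {trait!r} has no observed values")
    sub = pheno.df.iloc[rows]

    cols = [np.ones(len(sub))]
    names = ["intercept"]
    for factor in ("gender", "farm", "year"):
        levels = pd.unique(sub[factor].astype(str))
        d = pd.get_dummies(sub[factor].astype(str), prefix=factor,
                           drop_first=True, dtype=float)
        if len(levels) > 1:
            for c in d.columns:
                cols.append(d[c].to_numpy())
                names.append(c)
    if use_age:
        age = sub["age"].to_numpy(dtype=float)
        cols.append(age - age.mean())
        names.append("age")
    X = np.column_stack(cols)

    # drop aliased columns (rank-revealing QR via pivoted numpy lstsq trick)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        keep = [0]
        for j in range(1, X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
            else:
                warnings.warn(f"dropping aliased design column {names[j]!r}")
        X = X[:, keep]
        names = [names[j] for j in keep]
    return X, names, rows


def _profile_reml(lam: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray):
    """Restricted log-likelihood profiled over sigma_e2 at ratio lam."""
    n, p = Xt.shape
    w = lam * d + 1.0
    Xw = Xt / w[:, None]
    XtWX = Xt.T @ Xw
    XtWy = Xw.T @ yt
    cho = np.linalg.cholesky(XtWX)
    b = np.linalg.solve(XtWX, XtWy)
    r = yt - Xt @ b
    rss = float(np.sum(r * r / w))
    sigma_e2 = rss / (n - p)
    logdet_XtWX = 2.0 * float(np.sum(np.log(np.diag(cho))))
    ll = -0.5 * ((n - p) * (np.log(sigma_e2) + 1.0 + np.log(2.0 * np.pi))
                 + float(np.sum(np.log(w))) + logdet_XtWX)
    return ll, sigma_e2, b


def _ai_se_h2(lam, sigma_e2, d, yt, Xt):
    """SE of h2 from the average-information matrix in (sigma_a2, sigma_e2).

    All products use the rotated (diagonal-V) representation:
    AI_ij = 0.5 * y'P V_i P V_j P y with V_a = G, V_e = I.
    """
    sigma_a2 = lam * sigma_e2
    w = sigma_a2 * d + sigma_e2          # diagonal of V in rotated space

    def P(v):  # projection P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1
        vi = v / w
        XtWX = Xt.T @ (Xt / w[:, None])
        return vi - (Xt / w[:, None]) @ np.linalg.solve(XtWX, Xt.T @ vi)

    Py = P(yt)
    t_a = d * Py        # G P y
    t_e = Py            # I P y
    Pta, Pte = P(t_a), P(t_e)
    AI = 0.5 * np.array([
        [float(t_a @ Pta), float(t_a @ Pte)],
        [float(t_e @ Pta), float(t_e @ Pte)],
    ])
    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        return float("nan")
    tot = sigma_a2 + sigma_e2
    grad = np.array([sigma_e2, -sigma_a2]) / tot ** 2
    var = float(grad @ cov @ grad)
    return float(np.sqrt(var)) if var > 0 else float("nan")


def fit_reml(y: np.ndarray, X: np.ndarray, grm: GRM,
             eig: tuple | None = None) -> VarianceComponents:
    """Maximize the restricted likelihood over lambda = sa2/se2.

    ``eig`` may carry a precomputed ``(eigenvalues, eigenvectors)`` of the
    GRM so repeated fits on the same kinship are O(n^2).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    n, p = X.shape
    if len(y) != n or grm.n_samples != n:
        raise ValueError("y, X and GRM are not aligned")
    if n <= p:
        raise ValueError("more fixed-effect columns than observations")

    if eig is None:
        d, U = np.linalg.eigh(grm.values)
    else:
        d, U = eig
    d = np.clip(d, 0.0, None)
    if np.ptp(d) < 1e-10 * max(1.0, d.max()):
        raise ValueError(
            "GRM is (numerically) a multiple of I: only the total variance "
            "is identifiable, the heritability is not")
    yt = U.T @ y
    Xt = U.T @ X

    neg = lambda loglam: -_profile_reml(np.exp(loglam), d, yt, Xt)[0]
    lo, hi = np.log(LAMBDA_BOUNDS[0]), np.log(LAMBDA_BOUNDS[1])
    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    loglam = float(res.x)
    lam = float(np.exp(loglam))
    ll, sigma_e2, _ = _profile_reml(lam, d, yt, Xt)
    sigma_a2 = lam * sigma_e2
    h2 = sigma_a2 / (sigma_a2 + sigma_e2)
    at_boundary = (loglam - lo < 1e-3) or (hi - loglam < 1e-3)
    if at_boundary:
        log.warning("REML ratio at search boundary (lambda=%.3g)", lam)
    se = _ai_se_h2(lam, sigma_e2, d, yt, Xt)
    return VarianceComponents(
        sigma_a2=sigma_a2, sigma_e2=sigma_e2, h2=h2, se_h2=se,
        loglik=float(ll), n_iter=int(res.nfev), converged=bool(res.success),
        at_boundary=at_boundary)


def estimate_fixed_effects(y: np.ndarray, X: np.ndarray, grm: GRM,
                           vc: VarianceComponents) -> np.ndarray:
    """GLS fixed effects at the REML optimum."""
    if not vc.converged:
        raise ValueError("variance components did not converge")
    n = len(y)
    V = vc.sigma_a2 * grm.values + vc.sigma_e2 * np.eye(n)
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    A = X.T @ Vi_X
    try:
        return np.linalg.solve(A, X.T @ Vi_y)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular X'V^-1X in GLS") from exc
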