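"""GBLUP prediction and its SNP-BLUP (ridge) dual.

Training animals get BLUP breeding values from the mixed-model equations;
validation animals — whose phenotypes are masked — are predicted through
the conditional-mean identity g_val = G_vr G_rr^-1 g_ref, which is
algebraically identical to solving the MME with empty records but keeps
the masking explicit and costs one extra solve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .kinship import GRM
from .reml import VarianceComponents

__all__ = ["GEBVResult", "fit_gblup", "snp_blup"]


@dataclass
class GEBVResult:
    sample_ids: np.ndarray
    gebv: np.ndarray
    method: str = "gblup"
    trait: str = ""
    fold: int | None = None
    repeat: int | None = None

    def __post_init__(self) -> None:
        self.gebv = np.asarray(self.gebv, dtype=float)
        if len(self.gebv) != len(self.sample_ids):
            raise ValueError("one GEBV per sample required")
        if not np.all(np.isfinite(self.gebv)):
            raise ValueError("non-finite GEBV")


def fit_gblup(y_ref: np.ndarray, X_ref: np.ndarray, grm: GRM,
              vc: VarianceComponents, ref_index: np.ndarray,
              trait: str = "") -> GEBVResult:
    """BLUP breeding values for all animals in ``grm``.

    ``ref_index`` marks the rows of the GRM with observed phenotypes;
    remaining animals are predicted from their genomic relationships with
    the reference.  Solves use a symmetric factorization of
    V = sa2*G_rr + se2*I after the GRM ridge policy.
    """
    if not vc.converged:
        raise ValueError("variance components did not converge")
    y_ref = np.asarray(y_ref, dtype=float)
    X_ref = np.asarray(X_ref, dtype=float)
    ref_index = np.asarray(ref_index, dtype=int)
    n_all = grm.n_samples
    if len(y_ref) != len(ref_index):
        raise ValueError("y_ref and ref_index disagree")

    G = grm.values
    G_rr = G[np.ix_(ref_index, ref_index)]
    V = vc.sigma_a2 * G_rr + vc.sigma_e2 * np.eye(len(ref_index))
    try:
        cho = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("singular mixed-model system") from exc

    b = np.linalg.solve(X_ref.T @ linalg.cho_solve(cho, X_ref),
                        X_ref.T @ linalg.cho_solve(cho, y_ref))
    resid = y_ref - X_ref @ b
    Vi_r = linalg.cho_solve(cho, resid)
    # g_hat for every animal: sa2 * G[:, ref] V^-1 (y - Xb); restricted to
    # the reference block this is the MME solution, elsewhere the
    # conditional mean G_vr G_rr^-1 g_ref.
    gebv = vc.sigma_a2 * (G[:, ref_index] @ Vi_r)
    return GEBVResult(sample_ids=grm.sample_ids, gebv=gebv, method="gblup",
                      trait=trait)


def snp_blup(y_ref: np.ndarray, X_ref: np.ndarray, W_ref: np.ndarray,
             lam: float, denominator: float) -> np.ndarray:
    """Ridge marker effects in the dual form.

    alpha = W'(WW' + lam*denominator*I)^-1 (y - Xb), with b estimated by
    GLS under the same dual covariance; GEBV = W alpha reproduces GBLUP
    with G = WW'/denominator and lam = se2/sa2.
    """
    if not (np.isfinite(lam) and lam > 0):
        raise ValueError("lam must be positive")
    y_ref = np.asarray(y_ref, dtype=float)
    W_ref = np.asarray(W_ref, dtype=float)
    n = len(y_ref)
    if W_ref.shape[0] != n or X_ref.shape[0] != n:
        raise ValueError("row mismatch between y, X and W")
    M = W_ref @ W_ref.T + lam * denominator * np.eye(n)
    cho = linalg.cho_factor(M, lower=True)
    b = np.linalg.solve(X_ref.T @ linalg.cho_solve(cho, X_ref),
                        X_ref.T @ linalg.cho_solve(cho, y_ref))
    resid = y_ref - X_ref @ b
    return W_ref.T @ linalg.cho_solve(cho, resid)
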