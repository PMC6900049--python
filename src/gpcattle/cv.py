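"""Five-fold cross-validation and the comparison criteria.

A predictor is trained on the reference folds, validation phenotypes are
masked, and predictions are scored against corrected phenotypes
y_hat = y - X b_hat with b_hat from the full-data animal-model fit:

* predictive ability   — Pearson r(GEBV, y_hat);
* predictive accuracy  — ability / sqrt(h2), the usual approximation to the
  correlation with the true breeding value;
* inflation slope      — OLS slope of y_hat on GEBV (1 = unbiased scale,
  < 1 = inflated predictions);
* MSE                  — mean squared difference between GEBV and y_hat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import McmcConfig, gebv_from_effects, run_sampler
from .gblup import fit_gblup
from .kinship import GRM, vanraden_grm
from .reml import build_fixed_design, estimate_fixed_effects, fit_reml

log = logging.getLogger(__name__)

__all__ = [
    "FoldPlan", "make_fold_plan", "correct_phenotypes", "predictive_ability",
    "predictive_accuracy", "inflation_slope", "mean_squared_error",
    "run_cross_validation", "aggregate_metrics",
]


@dataclass
class FoldPlan:
    n: int
    k: int
    repeats: int
    assignments: np.ndarray  # (repeats, n) fold label per sample
    seed: int

    def fold_members(self, repeat: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments[repeat] == fold)


def make_fold_plan(n: int, k: int = 5, repeats: int = 10, seed: int = 0) -> FoldPlan:
    """Balanced random partition per repeat; fold sizes differ by <= 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("need at least k samples")
    rng = np.random.default_rng(seed)
    assignments = np.empty((repeats, n), dtype=np.int64)
    base = np.concatenate([np.full(sz, f) for f, sz in
                           enumerate(_fold_sizes(n, k))])
    for rep in range(repeats):
        assignments[rep] = base[rng.permutation(n)]
    return FoldPlan(n=n, k=k, repeats=repeats, assignments=assignments,
                    seed=seed)


def _fold_sizes(n: int, k: int):
    q, r = divmod(n, k)
    return [q + 1] * r + [q] * (k - r)


def correct_phenotypes(y: np.ndarray, X: np.ndarray, b_hat: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    b_hat = np.asarray(b_hat, dtype=float)
    if X.shape != (len(y), len(b_hat)):
        raise ValueError("y, X and b_hat dimensions disagree")
    return y - X @ b_hat


def predictive_ability(gebv: np.ndarray, y_corr: np.ndarray) -> float:
    gebv = np.asarray(gebv, dtype=float)
    y_corr = np.asarray(y_corr, dtype=float)
    if len(gebv) != len(y_corr):
        raise ValueError("length mismatch")
    if len(gebv) < 3:
        raise ValueError("need at least 3 validation animals")
    if gebv.std() == 0 or y_corr.std() == 0:
        return float("nan")  # undefined, flagged as NaN rather than 0
    return float(np.corrcoef(gebv, y_corr)[0, 1])


def predictive_accuracy(r: float, h2: float) -> float:
    if not (0 < h2 <= 1):
        raise ValueError("h2 must lie in (0, 1]")
    return float(r / np.sqrt(h2))


def inflation_slope(y_corr: np.ndarray, gebv: np.ndarray) -> float:
    """OLS slope of corrected phenotype on GEBV."""
    gebv = np.asarray(gebv, dtype=float)
    y_corr = np.asarray(y_corr, dtype=float)
    v = gebv.var()
    if v == 0:
        return float("nan")
    return float(np.cov(y_corr, gebv, bias=True)[0, 1] / v)


def mean_squared_error(gebv: np.ndarray, y_corr: np.ndarray) -> float:
    gebv = np.asarray(gebv, dtype=float)
    y_corr = np.asarray(y_corr, dtype=float)
    if len(gebv) == 0:
        raise ValueError("empty vectors")
    if len(gebv) != len(y_corr):
        raise ValueError("length mismatch")
    return float(np.mean((gebv - y_corr) ** 2))


def _stage_seed(seed: int, *parts) -> int:
    """Deterministic per-stage seed below 2^31."""
    h = np.uint64(1469598103934665603)
    for token in (seed,) + parts:
        for byte in str(token).encode():
            h = np.uint64((int(h) ^ byte) * 1099511628211 % (2 ** 64))
    return int(h % (2 ** 31))


def run_cross_validation(geno, pheno, trait: str, methods, plan: FoldPlan,
                         mcmc: McmcConfig | None = None, use_age: bool = True,
                         grm: GRM | None = None,
                         vc_per_fold: bool = True) -> pd.DataFrame:
    """Evaluate each method over every repeat x fold of ``plan``.

    Requires QC'd, complete genotypes aligned with the phenotype table.
    The corrected phenotypes and the accuracy denominator h2 come from the
    full-data REML fit; GBLUP variance components are re-estimated on each
    training fold unless ``vc_per_fold`` is False.  Failures in a cell are
    logged and skipped; an all-empty result is an error.
    """
    if mcmc is None:
        mcmc = McmcConfig()
    Z = geno.values()
    if grm is None:
        grm = vanraden_grm(geno)
    X, _, rows = build_fixed_design(pheno, trait, use_age=use_age)
    if len(rows) != geno.n_samples:
        raise ValueError("run CV on samples with observed trait values only")
    y = pheno.trait(trait)[rows]

    eig = np.linalg.eigh(grm.values)
    eig = (eig[0], eig[1])
    vc_full = fit_reml(y, X, grm, eig=eig)
    b_full = estimate_fixed_effects(y, X, grm, vc_full)
    y_corr = correct_phenotypes(y, X, b_full)
    h2 = max(vc_full.h2, 1e-8)

    records = []
    for rep in range(plan.repeats):
        for fold in range(plan.k):
            val = plan.fold_members(rep, fold)
            ref = np.flatnonzero(plan.assignments[rep] != fold)
            for method in methods:
                try:
                    gebv_val = _predict_fold(
                        method, y, X, Z, grm, ref, val, vc_full, eig, mcmc,
                        vc_per_fold, rep, fold)
                except Exception:
                    log.exception("CV cell failed: %s rep %d fold %d",
                                  method, rep, fold)
                    continue
                r = predictive_ability(gebv_val, y_corr[val])
                records.append({
                    "trait": trait, "method": method, "repeat": rep,
                    "fold": fold, "ability": r,
                    "accuracy": predictive_accuracy(r, h2),
                    "slope": inflation_slope(y_corr[val], gebv_val),
                    "mse": mean_squared_error(gebv_val, y_corr[val]),
                })
    if not records:
        raise RuntimeError("cross-validation produced no results")
    return pd.DataFrame.from_records(records)


def _predict_fold(method, y, X, Z, grm, ref, val, vc_full, eig, mcmc,
                  vc_per_fold, rep, fold):
    if method == "gblup":
        sub = GRM(grm.values[np.ix_(ref, ref)], grm.sample_ids[ref],
                  grm.denominator)
        vc = fit_reml(y[ref], X[ref], sub) if vc_per_fold else vc_full
        res = fit_gblup(y[ref], X[ref], grm, vc,
                        ref_index=ref, trait="")
        return res.gebv[val]
    cfg = McmcConfig(
        n_iter=mcmc.n_iter, burn_in=mcmc.burn_in, thin=mcmc.thin,
        seed=_stage_seed(mcmc.seed, method, rep, fold),
        pi_fixed=mcmc.pi_fixed, v_df=mcmc.v_df,
        vc_prior=max(vc_full.sigma_a2, 1e-8),
        update_genetic_variance=mcmc.update_genetic_variance)
    post = run_sampler(method, y[ref], X[ref], Z[ref], cfg)
    return gebv_from_effects(Z[val], post.alpha_mean).gebv


def aggregate_metrics(table: pd.DataFrame):
    """Per trait x method means over fold-repeats, plus the trait-averaged
    per-method summary (unweighted mean of per-trait means; rounding only
    at presentation)."""
    if table.empty:
        raise ValueError("empty metrics table")
    cols = ["ability", "accuracy", "slope", "mse"]
    n_missing = int(table[cols].isna().sum().sum())
    if n_missing:
        log.warning("aggregating over %d missing metric cells", n_missing)
    per_trait = (table.groupby(["trait", "method"])[cols]
                 .mean().reset_index())
    per_method = per_trait.groupby("method")[cols].mean().reset_index()
    return per_trait, per_method
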