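"""Bayesian whole-genome regression: BayesA, BayesB, BayesC-pi and BayesR.

All four models share the linear model y = Xb + Z alpha + e and differ only
in the prior on the marker effects alpha_j:

* BayesA — every marker has an effect, alpha_j ~ N(0, sigma_j2) with
  per-marker scaled-inverse-chi2(v, Sa2) variances;
* BayesB — a spike at zero with probability pi, otherwise the BayesA slab;
  pi is fixed (the model treats it as known);
* BayesC-pi — spike at zero, common slab variance, and pi sampled under a
  uniform(0,1) prior;
* BayesR — four normal components with variances fixed at (0, 0.01%, 0.1%,
  1%) of the genetic variance and Dirichlet(1,1,1,1) mixture proportions.

The slab scale follows Sa2 = (v - 2) * E(sigma_j2) / v with v = 4.2 by
default, where E(sigma_j2) is the prior genetic variance spread over the
expected number of non-null markers: E = vc_prior / ((1 - pi) * sum 2pq).

Spike models sample the inclusion indicator with the effect analytically
integrated out, then redraw the marker variance from its conditional —
included markers from the posterior update, excluded ones from the prior
(their exact conditional when the effect is pinned at zero).  This replaces
the historical Metropolis-Hastings step and leaves the stationary
distribution unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _gibbs
from .gblup import GEBVResult

__all__ = ["McmcConfig", "PosteriorSummary", "derive_scale",
           "expected_marker_variance", "run_sampler", "gebv_from_effects"]

MODELS = ("bayesA", "bayesB", "bayesCpi", "bayesR")
_MODEL_CODE = {"bayesA": _gibbs.MODEL_A, "bayesB": _gibbs.MODEL_B,
               "bayesCpi": _gibbs.MODEL_CPI}

#: relative component variances of the four-component mixture
BAYESR_VARIANCE_FRACTIONS = np.array([0.0, 1e-4, 1e-3, 1e-2])


@dataclass
class McmcConfig:
    n_iter: int = 50_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    pi_fixed: float | None = None       # BayesB pi (default 0.95); forces pi for bayesCpi too
    v_df: float = 4.2
    vc_prior: float = 1.0               # expected genetic variance (e.g. REML sigma_a2)
    update_genetic_variance: bool = False  # BayesR: update sigma_g2 from current effects
    fix_sigma_e2: float | None = None      # testing hook: pin the residual variance
    fix_marker_variance: float | None = None  # testing hook: pin slab variances

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.v_df <= 2:
            raise ValueError("v_df must exceed 2 (prior scale formula)")
        if self.pi_fixed is not None and not (0 <= self.pi_fixed <= 1):
            raise ValueError("pi_fixed must lie in [0, 1]")
        if self.vc_prior <= 0:
            raise ValueError("vc_prior must be positive")


@dataclass
class PosteriorSummary:
    model: str
    alpha_mean: np.ndarray
    b_mean: np.ndarray
    pi_mean: float
    sigma_e2_mean: float
    genetic_variance_mean: float
    inclusion_prob: np.ndarray | None = None
    component_probs: np.ndarray | None = None   # per-marker K-vector (BayesR)
    mixture_props: np.ndarray | None = None     # posterior mean p_i (BayesR)
    traces: dict = field(default_factory=dict)
    n_kept: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.pi_mean <= 1):
            raise ValueError("pi_mean outside [0, 1]")
        if self.mixture_props is not None:
            if abs(float(np.sum(self.mixture_props)) - 1.0) > 1e-12:
                raise ValueError("mixture proportions do not sum to 1")


def derive_scale(v_df: float, expected_marker_variance: float) -> float:
    """Slab scale Sa2 = (v - 2) * E(sigma_j2) / v."""
    if v_df <= 2:
        raise ValueError("v_df must exceed 2")
    if not (np.isfinite(expected_marker_variance) and expected_marker_variance > 0):
        raise ValueError("expected marker variance must be positive")
    return (v_df - 2.0) * expected_marker_variance / v_df


def expected_marker_variance(genetic_variance: float, pi: float,
                             sum_2pq: float) -> float:
    """Prior per-marker effect variance: the genetic variance spread over
    the expected non-null heterozygosity (1 - pi) * sum 2p(1-p)."""
    if not (0 <= pi < 1):
        raise ValueError("pi must lie in [0, 1)")
    if sum_2pq <= 0:
        raise ValueError("sum of 2pq must be positive")
    return genetic_variance / ((1.0 - pi) * sum_2pq)


def _scale_for(model: str, cfg: McmcConfig, sum_2pq: float) -> tuple:
    """(pi_init, pi_is_fixed, Sa2) for the spike/slab models."""
    if model == "bayesA":
        pi, fixed = 0.0, True
    elif model == "bayesB":
        pi = 0.95 if cfg.pi_fixed is None else cfg.pi_fixed
        fixed = True
    else:  # bayesCpi
        if cfg.pi_fixed is not None:
            pi, fixed = cfg.pi_fixed, True
        else:
            pi, fixed = 0.5, False
    e_var = expected_marker_variance(cfg.vc_prior, min(pi, 1.0 - 1e-6), sum_2pq)
    return pi, fixed, derive_scale(cfg.v_df, e_var)


def run_sampler(model: str, y: np.ndarray, X: np.ndarray, Z: np.ndarray,
                cfg: McmcConfig) -> PosteriorSummary:
    """Run one Gibbs chain and return posterior means.

    ``Z`` is the raw 0/1/2 dosage matrix (complete); columns are centered
    internally for mixing, which shifts only the intercept, not alpha.
    Posterior means of alpha use every post-burn-in draw; the ``thin``
    setting applies to the stored scalar traces only.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    y = np.ascontiguousarray(y, dtype=np.float64)
    X = np.ascontiguousarray(X, dtype=np.float64)
    Z = np.asarray(Z, dtype=np.float64)
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    if not np.all(np.isfinite(Z)):
        raise ValueError("Z must be complete (mean-impute first)")
    n = len(y)
    if X.shape[0] != n or Z.shape[0] != n:
        raise ValueError("row mismatch between y, X and Z")

    p_freq = Z.mean(axis=0) / 2.0
    sum_2pq = float(np.sum(2.0 * p_freq * (1.0 - p_freq)))
    # kernels take row-contiguous transposes so per-marker passes stream
    XT = np.ascontiguousarray(X.T)
    ZT = np.ascontiguousarray((Z - Z.mean(axis=0)).T)

    fix_e = -1.0 if cfg.fix_sigma_e2 is None else float(cfg.fix_sigma_e2)
    fix_m = -1.0 if cfg.fix_marker_variance is None else float(cfg.fix_marker_variance)
    seed = int(cfg.seed) % (2 ** 31)

    if model == "bayesR":
        (alpha, b, comp, props, se2, gv, tr_se2, tr_gv, tr_sg2) = \
            _gibbs.bayes_r_kernel(
                y, XT, ZT, cfg.n_iter, cfg.burn_in, cfg.thin, seed,
                BAYESR_VARIANCE_FRACTIONS, float(cfg.vc_prior),
                cfg.update_genetic_variance, fix_e)
        props = props / props.sum()
        return PosteriorSummary(
            model=model, alpha_mean=alpha, b_mean=b,
            pi_mean=float(props[0]), sigma_e2_mean=float(se2),
            genetic_variance_mean=float(gv), component_probs=comp,
            mixture_props=props,
            traces={"sigma_e2": tr_se2, "genetic_variance": tr_gv,
                    "sigma_g2": tr_sg2},
            n_kept=cfg.n_iter - cfg.burn_in)

    pi0, pi_fixed, sa2 = _scale_for(model, cfg, sum_2pq)
    (alpha, b, incl, pi, se2, gv, tr_se2, tr_pi, tr_gv) = \
        _gibbs.bayes_abc_kernel(
            y, XT, ZT, cfg.n_iter, cfg.burn_in, cfg.thin, seed,
            _MODEL_CODE[model], pi0, pi_fixed, float(cfg.v_df), float(sa2),
            fix_e, fix_m)
    return PosteriorSummary(
        model=model, alpha_mean=alpha, b_mean=b, pi_mean=float(pi),
        sigma_e2_mean=float(se2), genetic_variance_mean=float(gv),
        inclusion_prob=incl,
        traces={"sigma_e2": tr_se2, "pi": tr_pi, "genetic_variance": tr_gv},
        n_kept=cfg.n_iter - cfg.burn_in)


def gebv_from_effects(Z: np.ndarray, alpha_mean: np.ndarray,
                      sample_ids=None, method: str = "", trait: str = "") -> GEBVResult:
    """GEBV_i = sum_j Z_ij alpha_j on the stored dosage coding."""
    Z = np.asarray(Z, dtype=float)
    alpha_mean = np.asarray(alpha_mean, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != len(alpha_mean):
        raise ValueError("Z and alpha dimensions disagree")
    gebv = Z @ alpha_mean
    if sample_ids is None:
        sample_ids = np.arange(Z.shape[0])
    return GEBVResult(sample_ids=np.asarray(sample_ids, dtype=object),
                      gebv=gebv, method=method or "bayes", trait=trait)
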