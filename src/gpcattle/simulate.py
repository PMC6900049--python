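"""Synthetic genotype/phenotype generator for genomic-prediction studies.

The generator mirrors the data-generating assumptions of the downstream
models so that each stage has a ground truth to recover:

* genotypes: two haplotypes per animal, each a first-order haplotype-copying
  chain along the chromosome — the allele at marker j+1 copies marker j's
  allele with probability ``ld_decay``, otherwise it is drawn fresh at that
  marker's allele frequency.  One parameter gives monotone adjacent-marker
  LD at negligible cost;
* marker effects from one of three architectures: a single normal
  (infinitesimal), a point-normal spike-and-slab with zero-proportion
  ``pi_true``, or a four-component normal mixture with relative variances
  (0, 1e-4, 1e-3, 1e-2) of the genetic variance;
* phenotypes y = Xb + g + e with gender/farm/year factors, a slaughter-age
  covariate, and a residual variance set so the *realized* heritability
  var(g)/(var(g)+sigma_e2) equals the target exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, PhenotypeTable

__all__ = [
    "SimulationConfig",
    "TrueValues",
    "simulate_genotypes",
    "simulate_marker_effects",
    "simulate_phenotypes",
    "simulate_dataset",
    "expected_marker_frequencies",
]

ARCHITECTURES = ("normal", "point_normal", "four_component")

#: relative variances of the four mixture components (fractions of the
#: genetic variance), fixed by the four-component model definition
FOUR_COMPONENT_VARIANCE_FRACTIONS = (0.0, 1e-4, 1e-3, 1e-2)


@dataclass
class SimulationConfig:
    n_individuals: int = 1217
    n_markers: int = 5000
    maf_range: tuple = (0.05, 0.5)
    ld_decay: float = 0.9
    architecture: str = "point_normal"
    pi_true: float = 0.95
    component_props: tuple = (0.95, 0.03, 0.015, 0.005)
    heritability_true: float = 0.4
    n_genders: int = 2
    n_farms: int = 5
    n_years: int = 6
    age_range: tuple = (540.0, 720.0)
    missing_rate: float = 0.0
    trait_name: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        def bad(fieldname, msg):
            raise ValueError(f"SimulationConfig.{fieldname}: {msg}")

        if not (isinstance(self.n_individuals, (int, np.integer)) and self.n_individuals >= 1):
            bad("n_individuals", "must be a positive integer")
        if not (isinstance(self.n_markers, (int, np.integer)) and self.n_markers >= 1):
            bad("n_markers", "must be >= 1")
        lo, hi = self.maf_range
        if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo <= hi <= 0.5):
            bad("maf_range", "must satisfy 0 < low <= high <= 0.5")
        if not (np.isfinite(self.ld_decay) and 0 <= self.ld_decay < 1):
            bad("ld_decay", "must lie in [0, 1)")
        if self.architecture not in ARCHITECTURES:
            bad("architecture", f"must be one of {ARCHITECTURES}")
        if not (np.isfinite(self.pi_true) and 0 <= self.pi_true <= 1):
            bad("pi_true", "must lie in [0, 1]")
        props = np.asarray(self.component_props, dtype=float)
        if len(props) != 4 or (props < 0).any() or not np.isclose(props.sum(), 1.0):
            bad("component_props", "must be 4 nonnegative proportions summing to 1")
        if not (np.isfinite(self.heritability_true) and 0 < self.heritability_true < 1):
            bad("heritability_true", "must lie strictly inside (0, 1)")
        for name, v in [("n_genders", self.n_genders), ("n_farms", self.n_farms),
                        ("n_years", self.n_years)]:
            if v < 1:
                bad(name, "must be >= 1")
        a0, a1 = self.age_range
        if not (np.isfinite(a0) and np.isfinite(a1) and a0 < a1):
            bad("age_range", "must be an increasing finite pair")
        if not (np.isfinite(self.missing_rate) and 0 <= self.missing_rate < 1):
            bad("missing_rate", "must lie in [0, 1)")


@dataclass
class TrueValues:
    """Ground truth carried alongside a simulated dataset."""

    marker_effects: np.ndarray
    breeding_values: np.ndarray = field(default=None)
    fixed_effects: np.ndarray = field(default=None)
    variance_components: tuple = field(default=None)  # (sigma_a2, sigma_e2)
    component_labels: np.ndarray = field(default=None)


def _target_frequencies(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.maf_range
    return rng.uniform(lo, hi, size=cfg.n_markers)


def expected_marker_frequencies(p_draw: np.ndarray, ld_decay: float) -> np.ndarray:
    """Marginal counted-allele frequency induced by the copying chain.

    f_1 = p_1 and f_{j+1} = ld*f_j + (1-ld)*p_{j+1}: copying propagates the
    previous marker's marginal, so the chain's marginals are a geometric
    smoothing of the drawn per-marker frequencies.
    """
    f = np.empty_like(p_draw)
    f[0] = p_draw[0]
    for j in range(1, len(p_draw)):
        f[j] = ld_decay * f[j - 1] + (1 - ld_decay) * p_draw[j]
    return f


def simulate_genotypes(cfg: SimulationConfig) -> GenotypeMatrix:
    """Simulate an N x M dosage matrix on one chromosome.

    Two haplotype chains per individual are summed to a dosage; missing
    calls are placed completely at random at rate ``missing_rate``.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_individuals, cfg.n_markers
    p = _target_frequencies(cfg, rng)

    hap = np.empty((2 * n, m), dtype=np.int8)
    hap[:, 0] = rng.random(2 * n) < p[0]
    for j in range(1, m):
        fresh = rng.random(2 * n) < p[j]
        copy = rng.random(2 * n) < cfg.ld_decay
        hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
    dos = (hap[0::2] + hap[1::2]).astype(np.float64)

    mask = np.zeros_like(dos, dtype=bool)
    if cfg.missing_rate > 0:
        mask = rng.random(dos.shape) < cfg.missing_rate
        # keep every marker observable at least once
        all_missing = mask.all(axis=0)
        mask[0, all_missing] = False
    dosages = np.ma.masked_array(dos, mask=mask)

    width = len(str(m))
    return GenotypeMatrix(
        dosages=dosages,
        sample_ids=np.array([f"ind{i + 1}" for i in range(n)], dtype=object),
        marker_ids=np.array([f"snp{j + 1:0{width}d}" for j in range(m)], dtype=object),
        chromosome=np.array(["1"] * m, dtype=object),
        position=np.arange(1, m + 1, dtype=np.int64),
        counted_allele=np.array(["A"] * m, dtype=object),
        other_allele=np.array(["G"] * m, dtype=object),
    )


def _raw_effects(cfg: SimulationConfig, genetic_variance: float,
                 rng: np.random.Generator):
    m = cfg.n_markers
    per_marker = genetic_variance / m
    labels = None
    if cfg.architecture == "normal":
        eff = rng.normal(0.0, np.sqrt(per_marker), size=m)
    elif cfg.architecture == "point_normal":
        nz = rng.random(m) >= cfg.pi_true
        eff = np.zeros(m)
        n_nz = int(nz.sum())
        if n_nz:
            eff[nz] = rng.normal(0.0, np.sqrt(genetic_variance / n_nz), size=n_nz)
        labels = nz.astype(int)
    else:  # four_component
        labels = rng.choice(4, size=m, p=np.asarray(cfg.component_props, dtype=float))
        sd = np.sqrt(np.array(FOUR_COMPONENT_VARIANCE_FRACTIONS) * genetic_variance)
        eff = rng.normal(0.0, 1.0, size=m) * sd[labels]
    return eff, labels


def simulate_marker_effects(cfg: SimulationConfig, genetic_variance: float,
                            geno: GenotypeMatrix | None = None,
                            rng: np.random.Generator | None = None) -> TrueValues:
    """Draw marker effects from the configured architecture.

    When ``geno`` is given, effects are rescaled so that the variance of
    Z·alpha over the simulated individuals equals ``genetic_variance``
    exactly (the matrix must be complete; degenerate all-zero draws are
    returned unscaled).
    """
    if not (np.isfinite(genetic_variance) and genetic_variance > 0):
        raise ValueError("genetic_variance must be positive")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    eff, labels = _raw_effects(cfg, genetic_variance, rng)

    bv = None
    if geno is not None:
        Z = geno.values()
        bv = Z @ eff
        realized = bv.var()
        if realized > 0:
            c = np.sqrt(genetic_variance / realized)
            eff = eff * c
            bv = bv * c
    return TrueValues(marker_effects=eff, breeding_values=bv,
                      component_labels=labels)


def simulate_phenotypes(geno: GenotypeMatrix, truth: TrueValues,
                        cfg: SimulationConfig,
                        rng: np.random.Generator | None = None):
    """Build y = Xb + g + e and return the phenotype table plus completed
    ground truth with the realized (sigma_a2, sigma_e2)."""
    if not geno.is_complete:
        raise ValueError("genotypes have missing calls; mean-impute before "
                         "simulating phenotypes")
    if len(truth.marker_effects) != geno.n_markers:
        raise ValueError(
            f"{len(truth.marker_effects)} effects for {geno.n_markers} markers")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))

    n = geno.n_samples
    g = truth.breeding_values
    if g is None:
        g = geno.values() @ truth.marker_effects
    var_g = g.var()
    h2 = cfg.heritability_true
    sigma_e2 = var_g * (1 - h2) / h2 if var_g > 0 else 1.0
    var_p = var_g + sigma_e2
    sd_p = np.sqrt(var_p)

    gender = rng.integers(cfg.n_genders, size=n)
    farm = rng.integers(cfg.n_farms, size=n)
    year = rng.integers(cfg.n_years, size=n)
    age = rng.uniform(*cfg.age_range, size=n)

    # one value per level, spread equal to the phenotypic SD; slope a small
    # fixed fraction of the phenotypic SD per age-SD
    eff_gender = rng.normal(0.0, sd_p, size=cfg.n_genders)
    eff_farm = rng.normal(0.0, sd_p, size=cfg.n_farms)
    eff_year = rng.normal(0.0, sd_p, size=cfg.n_years)
    age_sd = (cfg.age_range[1] - cfg.age_range[0]) / np.sqrt(12.0)
    age_slope = 0.1 * sd_p / age_sd
    intercept = 10.0 * sd_p

    xb = (intercept + eff_gender[gender] + eff_farm[farm] + eff_year[year]
          + age_slope * (age - age.mean()))
    e = rng.normal(0.0, np.sqrt(sigma_e2), size=n)
    y = xb + g + e

    df = pd.DataFrame({
        "id": geno.sample_ids,
        "gender": [f"g{k + 1}" for k in gender],
        "farm": [f"f{k + 1}" for k in farm],
        "year": [str(2008 + k) for k in year],
        "age": np.round(age, 1),
        cfg.trait_name: y,
    })
    out = TrueValues(
        marker_effects=truth.marker_effects,
        breeding_values=g,
        fixed_effects=np.concatenate(
            [[intercept], eff_gender, eff_farm, eff_year, [age_slope]]),
        variance_components=(var_g, sigma_e2),
        component_labels=truth.component_labels,
    )
    return PhenotypeTable(df, (cfg.trait_name,)), out


def simulate_dataset(cfg: SimulationConfig, genetic_variance: float | None = None):
    """Convenience: genotypes + effects + phenotypes in one call.

    The genetic variance defaults to the target heritability so the
    phenotypic variance is ~1.
    """
    if genetic_variance is None:
        genetic_variance = cfg.heritability_true
    geno = simulate_genotypes(cfg)
    complete = geno
    if not geno.is_complete:
        from .qc import mean_impute
        complete = mean_impute(geno)
    truth = simulate_marker_effects(cfg, genetic_variance, geno=complete)
    pheno, truth = simulate_phenotypes(complete, truth, cfg)
    return geno, pheno, truth
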