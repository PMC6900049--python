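"""Generator sanity: dosage coding, LD control, architectures, heritability
enforcement and seed determinism."""

import numpy as np
import pytest

from gpcattle.qc import ld_r2, mean_impute
from gpcattle.simulate import (SimulationConfig, expected_marker_frequencies,
                               simulate_dataset, simulate_genotypes,
                               simulate_marker_effects, simulate_phenotypes,
                               _target_frequencies)


def _adjacent_r2(geno):
    Z = geno.values()
    r2 = []
    for j in range(Z.shape[1] - 1):
        r2.append(ld_r2(Z[:, j], Z[:, j + 1]))
    return float(np.mean(r2))


class TestGenotypes:
    def test_dosages_in_range_without_missing(self):
        cfg = SimulationConfig(n_individuals=4, n_markers=3, missing_rate=0.0,
                               seed=1)
        geno = simulate_genotypes(cfg)
        assert geno.is_complete
        assert set(np.unique(geno.values())) <= {0.0, 1.0, 2.0}

    def test_seed_determinism(self):
        cfg = SimulationConfig(n_individuals=30, n_markers=40,
                               missing_rate=0.1, seed=9)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.dosages.filled(-1), b.dosages.filled(-1))

    def test_ld_decay_zero_gives_independent_markers(self):
        cfg = SimulationConfig(n_individuals=2000, n_markers=2000,
                               ld_decay=0.0, seed=2)
        assert _adjacent_r2(simulate_genotypes(cfg)) < 0.01

    def test_ld_decay_increases_adjacent_r2(self):
        base = dict(n_individuals=2000, n_markers=2000, seed=2)
        lo = _adjacent_r2(simulate_genotypes(SimulationConfig(ld_decay=0.0, **base)))
        hi = _adjacent_r2(simulate_genotypes(SimulationConfig(ld_decay=0.95, **base)))
        assert hi > lo
        assert hi > 0.5  # dense-LD regime really is dense

    def test_allele_frequencies_match_chain_marginals(self):
        cfg = SimulationConfig(n_individuals=800, n_markers=400, ld_decay=0.6,
                               seed=3)
        geno = simulate_genotypes(cfg)
        rng = np.random.default_rng(cfg.seed)
        p_draw = _target_frequencies(cfg, rng)
        target = expected_marker_frequencies(p_draw, cfg.ld_decay)
        obs = geno.values().mean(axis=0) / 2.0
        sigma = np.sqrt(target * (1 - target) / (2 * cfg.n_individuals))
        assert (np.abs(obs - target) <= 3 * sigma).mean() > 0.985

    def test_missing_rate(self):
        cfg = SimulationConfig(n_individuals=500, n_markers=200,
                               missing_rate=0.1, seed=4)
        geno = simulate_genotypes(cfg)
        frac = np.ma.getmaskarray(geno.dosages).mean()
        assert abs(frac - 0.1) < 0.01

    @pytest.mark.parametrize("field,value", [
        ("n_markers", 0),
        ("ld_decay", 1.0),
        ("maf_range", (0.0, 0.4)),
        ("heritability_true", 1.0),
        ("heritability_true", 0.0),
        ("missing_rate", 1.5),
        ("architecture", "bayesQ"),
    ])
    def test_invalid_config_rejected_with_field_name(self, field, value):
        with pytest.raises(ValueError, match=field.split("_")[0]):
            SimulationConfig(**{field: value})


class TestMarkerEffects:
    def test_point_normal_pi_one_all_zero(self):
        cfg = SimulationConfig(n_markers=200, architecture="point_normal",
                               pi_true=1.0, seed=5)
        tv = simulate_marker_effects(cfg, 1.0)
        assert np.all(tv.marker_effects == 0.0)

    def test_four_component_all_mass_on_null_component(self):
        cfg = SimulationConfig(n_markers=200, architecture="four_component",
                               component_props=(1.0, 0.0, 0.0, 0.0), seed=5)
        tv = simulate_marker_effects(cfg, 1.0)
        assert np.all(tv.marker_effects == 0.0)

    def test_point_normal_zero_count_binomial_band(self):
        cfg = SimulationConfig(n_markers=10_000, architecture="point_normal",
                               pi_true=0.9, seed=6)
        tv = simulate_marker_effects(cfg, 1.0)
        zeros = int((tv.marker_effects == 0.0).sum())
        sigma = np.sqrt(10_000 * 0.9 * 0.1)
        assert abs(zeros - 9000) <= 3 * sigma

    def test_normal_architecture_kurtosis_near_three(self):
        cfg = SimulationConfig(n_markers=20_000, architecture="normal", seed=7)
        e = simulate_marker_effects(cfg, 1.0).marker_effects
        kurt = np.mean((e - e.mean()) ** 4) / e.var() ** 2
        assert abs(kurt - 3.0) < 0.25

    def test_rescaling_enforces_genetic_variance(self):
        cfg = SimulationConfig(n_individuals=150, n_markers=120, seed=8)
        geno = simulate_genotypes(cfg)
        tv = simulate_marker_effects(cfg, 2.5, geno=geno)
        assert np.isclose(tv.breeding_values.var(), 2.5, rtol=1e-12)
        np.testing.assert_allclose(geno.values() @ tv.marker_effects,
                                   tv.breeding_values, rtol=1e-12)

    def test_nonpositive_variance_rejected(self):
        cfg = SimulationConfig(seed=1)
        with pytest.raises(ValueError):
            simulate_marker_effects(cfg, 0.0)


class TestPhenotypes:
    def test_realized_heritability_exact(self):
        cfg = SimulationConfig(n_individuals=300, n_markers=200,
                               heritability_true=0.47, seed=9)
        geno, pheno, truth = simulate_dataset(cfg)
        sa2, se2 = truth.variance_components
        assert abs(sa2 / (sa2 + se2) - 0.47) < 1e-12

    def test_dimension_mismatch_rejected(self):
        cfg = SimulationConfig(n_individuals=50, n_markers=60, seed=10)
        geno = simulate_genotypes(cfg)
        from gpcattle.simulate import TrueValues
        with pytest.raises(ValueError):
            simulate_phenotypes(geno, TrueValues(np.zeros(10)), cfg)

    def test_missing_genotypes_rejected(self):
        cfg = SimulationConfig(n_individuals=50, n_markers=60,
                               missing_rate=0.2, seed=11)
        geno = simulate_genotypes(cfg)
        tv = simulate_marker_effects(cfg, 1.0)
        with pytest.raises(ValueError, match="impute"):
            simulate_phenotypes(geno, tv, cfg)
        # after imputation it works
        simulate_phenotypes(mean_impute(geno), tv, cfg)

    def test_dataset_determinism(self):
        cfg = SimulationConfig(n_individuals=40, n_markers=50, seed=12)
        _, p1, t1 = simulate_dataset(cfg)
        _, p2, t2 = simulate_dataset(cfg)
        assert p1.df.equals(p2.df)
        np.testing.assert_array_equal(t1.marker_effects, t2.marker_effects)
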