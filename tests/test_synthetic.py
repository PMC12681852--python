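import numpy as np
import pytest

from evrank import (
    ConfigurationError,
    Direction,
    MarginalSpec,
    SyntheticSpec,
    ValidationError,
    generate_dataset,
    normalize_matrix,
    preset_spec,
)


def gaussian(name, mean, sd, **kw):
    return MarginalSpec(name, "gaussian", mean=mean, sd=sd, **kw)


class TestMarginalSpec:
    def test_gaussian_requires_positive_sd(self):
        with pytest.raises(ConfigurationError):
            gaussian("x", 10, 0)

    def test_poisson_requires_positive_rate(self):
        with pytest.raises(ConfigurationError):
            MarginalSpec("x", "poisson", rate=0)

    def test_minimize_gaussian_needs_headroom_or_floor(self):
        with pytest.raises(ConfigurationError, match="6\\*sd"):
            gaussian("tpc", 10, 5, direction=Direction.MINIMIZE)
        # explicit floor lifts the requirement
        gaussian("tpc", 10, 5, direction=Direction.MINIMIZE, floor=0.1)

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigurationError):
            MarginalSpec("x", "weibull")


class TestSyntheticSpecValidation:
    def test_non_psd_correlation_rejected(self):
        marg = [gaussian("a", 10, 1), gaussian("b", 10, 1), gaussian("c", 10, 1)]
        bad = np.array([[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValidationError, match="positive semi-definite"):
            SyntheticSpec(n_alternatives=5, marginals=marg, correlation=bad)

    def test_non_unit_diagonal_rejected(self):
        marg = [gaussian("a", 10, 1), gaussian("b", 10, 1)]
        with pytest.raises(ValidationError, match="unit diagonal"):
            SyntheticSpec(n_alternatives=5, marginals=marg,
                          correlation=np.array([[2.0, 0], [0, 1.0]]))


class TestGenerateDataset:
    def test_seed_determinism_bit_for_bit(self):
        spec = preset_spec("ev8x13", seed=42)
        a, ra = generate_dataset(spec)
        b, rb = generate_dataset(preset_spec("ev8x13", seed=42))
        assert np.array_equal(a.values.to_numpy(), b.values.to_numpy())
        assert ra.equals(rb)

    def test_different_seeds_differ(self):
        a, _ = generate_dataset(preset_spec("ev8x13", seed=1))
        b, _ = generate_dataset(preset_spec("ev8x13", seed=2))
        assert not np.array_equal(a.values.to_numpy(), b.values.to_numpy())

    def test_gaussian_mean_recovery(self):
        spec = SyntheticSpec(
            n_alternatives=1000,
            marginals=[gaussian("size", 150, 20, direction=Direction.MINIMIZE)],
            noise_cv=0.0, replicates=1, seed=3,
        )
        dm, _ = generate_dataset(spec)
        assert abs(dm.values["size"].mean() - 150) < 1.90  # 3*sd/sqrt(n)

    def test_poisson_rate_recovery(self):
        spec = SyntheticSpec(
            n_alternatives=1000,
            marginals=[MarginalSpec("count", "poisson", rate=100)],
            noise_cv=0.0, replicates=1, seed=4,
        )
        dm, _ = generate_dataset(spec)
        assert abs(dm.values["count"].mean() - 100) < 0.95  # 3*sqrt(lam/n)

    def test_target_correlation_recovery(self):
        marg = [gaussian("a", 100, 10), gaussian("b", 50, 5)]
        spec = SyntheticSpec(
            n_alternatives=2000, marginals=marg,
            correlation=np.array([[1.0, -0.7], [-0.7, 1.0]]),
            noise_cv=0.0, replicates=1, seed=5,
        )
        dm, _ = generate_dataset(spec)
        r = np.corrcoef(dm.values["a"], dm.values["b"])[0, 1]
        assert abs(r - (-0.7)) < 0.05  # Fisher-z se ~ 1/sqrt(n-3)

    def test_identity_correlation_stays_null(self):
        marg = [gaussian("a", 100, 10), gaussian("b", 50, 5),
                MarginalSpec("c", "poisson", rate=80)]
        spec = SyntheticSpec(n_alternatives=2000, marginals=marg,
                             noise_cv=0.0, replicates=1, seed=6)
        dm, _ = generate_dataset(spec)
        r = np.corrcoef(dm.values.to_numpy().T)
        off = r[np.triu_indices(3, k=1)]
        assert np.all(np.abs(off) < 0.08)

    def test_replicate_table_shape_and_mean_consistency(self):
        spec = preset_spec("ev8x13", seed=8)
        dm, rep = generate_dataset(spec)
        assert len(rep) == 8 * 13 * 3
        means = rep.groupby(["alternative", "factor"], sort=False)["value"].mean()
        for (alt, fac), v in means.items():
            assert dm.values.loc[alt, fac] == pytest.approx(v, rel=1e-12)

    def test_generated_matrix_passes_validation_and_normalizes(self):
        for seed in range(5):
            dm, _ = generate_dataset(preset_spec("ev15x11", seed=seed))
            dm.validate()
            nm = normalize_matrix(dm)
            assert np.all(nm.array > 0) and np.all(nm.array <= 1)


class TestPresets:
    def test_ev15x11_shape(self):
        spec = preset_spec("ev15x11")
        assert spec.n_alternatives == 15
        assert len(spec.marginals) == 11

    def test_ev8x13_shape_and_practical_factors(self):
        spec = preset_spec("ev8x13")
        assert spec.n_alternatives == 8
        assert len(spec.marginals) == 13
        names = spec.factor_names
        assert "isolation_time_h" in names and "cost_usd_per_prep" in names
        by_name = {m.name: m for m in spec.marginals}
        assert by_name["isolation_time_h"].direction is Direction.MINIMIZE
        assert by_name["cost_usd_per_prep"].direction is Direction.MINIMIZE

    def test_negative_yield_purity_correlation_planted(self):
        spec = preset_spec("ev15x11")
        names = spec.factor_names
        i = names.index("particle_recovery_pct")
        j = names.index("protein_purity_particles_per_ug")
        assert spec.correlation[i, j] < 0

    def test_preset_value_envelopes(self):
        # generated values should land in the field-realistic envelopes
        dm, _ = generate_dataset(preset_spec("ev15x11", seed=0))
        size = dm.values["mean_size_nm"]
        assert size.between(90, 230).all()
        zeta = dm.values["zeta_potential_mV"]
        assert zeta.between(-70, 10).all()
        purity = dm.values["protein_purity_particles_per_ug"]
        assert purity.between(1e9, 1e13).all()

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown preset"):
            preset_spec("bogus")
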