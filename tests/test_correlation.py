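import numpy as np
import pandas as pd
import pytest

from evrank import (
    Direction,
    MarginalSpec,
    SyntheticSpec,
    ValidationError,
    bioactivity_correlation,
    generate_dataset,
    pearson_r,
    significance_label,
)

from conftest import make_matrix


class TestPearsonR:
    def test_perfect_linearity(self):
        r, p = pearson_r([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)

    def test_perfect_anti_linearity(self):
        r, _ = pearson_r([1, 2, 3], [6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        # cov = 0.5*((−1)(−... ) hand value: r = 0.5 for (1,2,3) vs (1,3,2)
        r, _ = pearson_r([1, 2, 3], [1, 3, 2])
        assert r == pytest.approx(0.5, abs=1e-12)

    def test_self_correlation_is_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.2])
        r, _ = pearson_r(x, x)
        assert r == pytest.approx(1.0)

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(size=8)
        r0, _ = pearson_r(x, y)
        r_pos, _ = pearson_r(2.5 * x + 7, y)
        r_neg, _ = pearson_r(-3.0 * x + 1, y)
        assert r_pos == pytest.approx(r0, abs=1e-12)
        assert r_neg == pytest.approx(-r0, abs=1e-12)

    def test_p_decreases_with_abs_r_at_fixed_n(self):
        n = 10
        rng = np.random.default_rng(1)
        x = rng.normal(size=n)
        noise = rng.normal(size=n)
        ps = []
        for lam in (0.2, 1.0, 5.0):
            y = lam * x + noise
            r, p = pearson_r(x, y)
            ps.append((abs(r), p))
        rs, pvals = zip(*sorted(ps))
        assert list(pvals) == sorted(pvals, reverse=True)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError, match="zero variance"):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError, match="at least 3"):
            pearson_r([1, 2], [3, 4])


class TestSignificanceLabels:
    @pytest.mark.parametrize(
        "p, label",
        [(0.0005, "***"), (0.001, "***"), (0.005, "**"), (0.01, "**"),
         (0.03, "*"), (0.05, "*"), (0.2, "ns")],
    )
    def test_thresholds(self, p, label):
        assert significance_label(p) == label


def bioactivity_frame(m, conditions, values_fn):
    rows = []
    for line, dose in conditions:
        for alt in m.alternatives:
            rows.append(
                {"alternative": alt, "cell_line": line, "dose": dose,
                 "viability_percent": values_fn(alt, line, dose)}
            )
    return pd.DataFrame(rows)


class TestBioactivityCorrelation:
    def test_factor_identical_to_viability_gives_r_one(self):
        m = make_matrix([[1.0, 9.0], [2.0, 5.0], [3.0, 7.0], [4.0, 2.0]])
        bio = bioactivity_frame(
            m, [("HeLa", "1e9")],
            lambda alt, line, dose: float(m.values.loc[alt, "f1"]),
        )
        tab = bioactivity_correlation(m, bio)
        row = tab[(tab["factor"] == "f1")].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["n"] == 4

    def test_output_cardinality_factors_times_conditions(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.uniform(1, 10, size=(8, 11)))
        conditions = [(line, dose) for line in ("HeLa", "MCF7", "HepG2")
                      for dose in ("1e9", "1e10", "1e11")]
        bio = bioactivity_frame(
            m, conditions, lambda alt, line, dose: float(rng.uniform(20, 100))
        )
        tab = bioactivity_correlation(m, bio)
        assert len(tab) == 11 * 9
        # ordered by condition then factor
        assert list(tab["factor"].iloc[:11]) == m.factor_names

    def test_unknown_alternative_rejected(self):
        m = make_matrix([[1.0], [2.0], [3.0]])
        bio = pd.DataFrame(
            {"alternative": ["A1", "A2", "ghost"], "cell_line": ["x"] * 3,
             "dose": ["d"] * 3, "viability_percent": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValidationError, match="ghost"):
            bioactivity_correlation(m, bio)

    def test_insufficient_pairs_rejected(self):
        m = make_matrix([[1.0], [2.0], [3.0]])
        bio = pd.DataFrame(
            {"alternative": ["A1", "A2"], "cell_line": ["x"] * 2,
             "dose": ["d"] * 2, "viability_percent": [1.0, 2.0]}
        )
        with pytest.raises(ValidationError, match=">= 3"):
            bioactivity_correlation(m, bio)

    def test_bh_adjustment_column_optional(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.uniform(1, 10, size=(5, 3)))
        bio = bioactivity_frame(
            m, [("HeLa", "1e9")], lambda *a: float(rng.uniform(0, 100))
        )
        plain = bioactivity_correlation(m, bio)
        adj = bioactivity_correlation(m, bio, bh_adjust=True)
        assert "p_adj" not in plain.columns
        assert np.all(adj["p_adj"].to_numpy() >= adj["p_value"].to_numpy() - 1e-15)


class TestPlantedCorrelationRecovery:
    def test_mean_r_over_replicates_near_copula_expectation(self):
        # two gaussian factors with latent correlation -0.9; at n=8 the mean
        # sample r over many seeds should sit near the copula-induced value
        marg = [
            MarginalSpec("factor", "gaussian", mean=50, sd=8,
                         direction=Direction.MAXIMIZE, floor=1.0),
            MarginalSpec("viability", "gaussian", mean=60, sd=10,
                         direction=Direction.MAXIMIZE, floor=1.0),
        ]
        corr = np.array([[1.0, -0.9], [-0.9, 1.0]])
        # large-sample oracle for the copula-induced correlation under the
        # same noise model (replicate noise attenuates the latent -0.9)
        big = SyntheticSpec(n_alternatives=20000, marginals=marg,
                            correlation=corr, noise_cv=0.05, replicates=3,
                            seed=10)
        dm_big, _ = generate_dataset(big)
        oracle, _ = pearson_r(dm_big.values["factor"], dm_big.values["viability"])

        rs = []
        for s in range(500):
            spec = SyntheticSpec(n_alternatives=8, marginals=marg,
                                 correlation=corr, noise_cv=0.05,
                                 replicates=3, seed=1000 + s)
            dm, _ = generate_dataset(spec)
            r, _ = pearson_r(dm.values["factor"], dm.values["viability"])
            rs.append(r)
        assert np.mean(rs) == pytest.approx(oracle, abs=0.05)
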