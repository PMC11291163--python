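"""Correlation matrices, sign-flip significance, decay fits, clustering."""

import numpy as np
import pandas as pd
import pytest

from cptstates import network as net
from cptstates.core import CalciumTraceSet


def pearson_bruteforce(x, y):
    """Direct evaluation of r = Σ(Xi−X̄)(Yi−Ȳ)/√[Σ(Xi−X̄)²·Σ(Yi−Ȳ)²]."""
    xd, yd = x - x.mean(), y - y.mean()
    return (xd * yd).sum() / np.sqrt((xd**2).sum() * (yd**2).sum())


class TestCorrelationMatrix:
    def test_duplicated_and_negated_pairs(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=200)
        ts = CalciumTraceSet(np.vstack([base, base, -base]))
        m = net.state_correlation_matrix(ts, np.ones(200, bool))
        assert m[0, 1] == pytest.approx(1.0)
        assert m[0, 2] == pytest.approx(-1.0)

    def test_toy_matches_printed_formula(self):
        """5 neurons × 20 frames against elementwise brute-force Pearson."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=(5, 20))
        m = net.state_correlation_matrix(CalciumTraceSet(x), np.ones(20, bool))
        for i in range(5):
            for j in range(5):
                expected = 0.0 if i == j else pearson_bruteforce(x[i], x[j])
                assert m[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetry_zero_diagonal(self):
        rng = np.random.default_rng(2)
        m = net.state_correlation_matrix(
            CalciumTraceSet(rng.normal(size=(8, 100))), np.ones(100, bool)
        )
        np.testing.assert_allclose(m, m.T)
        assert np.all(np.diag(m) == 0.0)
        assert np.nanmax(np.abs(m)) <= 1.0

    def test_zero_variance_neuron_nan(self):
        x = np.vstack([np.ones(50), np.random.default_rng(3).normal(size=50)])
        with pytest.warns(UserWarning, match="zero-variance"):
            m = net.state_correlation_matrix(CalciumTraceSet(x), np.ones(50, bool))
        assert np.isnan(m[0, 1])

    def test_mask_selects_frames(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(3, 100))
        mask = np.zeros(100, bool)
        mask[:40] = True
        m = net.state_correlation_matrix(CalciumTraceSet(x), mask)
        assert m[0, 1] == pytest.approx(pearson_bruteforce(x[0, :40], x[1, :40]))


class TestCellMax:
    def test_printed_row(self):
        m = np.array(
            [
                [0.0, 0.2, -0.6, 0.5],
                [0.2, 0.0, 0.1, -0.3],
                [-0.6, 0.1, 0.0, 0.4],
                [0.5, -0.3, 0.4, 0.0],
            ]
        )
        out = net.cell_max_correlations(m)
        assert out.loc[0, "max_positive"] == pytest.approx(0.5)
        assert out.loc[0, "max_negative"] == pytest.approx(-0.6)

    def test_all_positive_flags_negative_nan(self):
        m = np.full((3, 3), 0.5)
        np.fill_diagonal(m, 0.0)
        out = net.cell_max_correlations(m)
        assert out["max_negative"].isna().all()
        assert (out["max_positive"] == 0.5).all()

    def test_bruteforce_agreement(self):
        rng = np.random.default_rng(5)
        m = rng.uniform(-1, 1, size=(10, 10))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        out = net.cell_max_correlations(m)
        for i in range(10):
            row = np.delete(m[i], i)
            pos, neg = row[row > 0], row[row < 0]
            if len(pos):
                assert out.loc[i, "max_positive"] == pytest.approx(pos.max())
            if len(neg):
                assert out.loc[i, "max_negative"] == pytest.approx(neg.min())


class TestKS:
    def test_identical_and_disjoint(self):
        a = np.linspace(0, 1, 50)
        d, _, _ = net.compare_state_distributions(a, a)
        assert d == pytest.approx(0.0)
        d, _, _ = net.compare_state_distributions(a, a + 10.0)
        assert d == pytest.approx(1.0)

    def test_matches_ecdf_gap_oracle(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=40), rng.normal(0.5, 1.2, size=60)
        d, _, _ = net.compare_state_distributions(a, b)
        grid = np.sort(np.concatenate([a, b]))
        gap = max(
            abs((a <= v).mean() - (b <= v).mean()) for v in grid
        )
        assert d == pytest.approx(gap, abs=1e-12)


class TestSignFlip:
    def test_duplicated_pair_positive(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=400)
        x = np.vstack([base, base + 0.01 * rng.normal(size=400), rng.normal(size=400)])
        classes, _ = net.classify_pair_correlations(
            CalciumTraceSet(x), np.ones(400, bool), n_perm=500, seed=0
        )
        assert classes[0, 1] == "positive"
        assert classes[1, 0] == "positive"

    def test_seed_determinism(self):
        rng = np.random.default_rng(8)
        ts = CalciumTraceSet(rng.normal(size=(5, 200)))
        c1, m1 = net.classify_pair_correlations(ts, np.ones(200, bool), n_perm=300, seed=3)
        c2, m2 = net.classify_pair_correlations(ts, np.ones(200, bool), n_perm=300, seed=3)
        np.testing.assert_array_equal(c1, c2)
        np.testing.assert_array_equal(m1, m2)

    def test_low_n_perm_warns(self):
        ts = CalciumTraceSet(np.random.default_rng(9).normal(size=(3, 100)))
        with pytest.warns(UserWarning, match="unstable"):
            net.classify_pair_correlations(ts, np.ones(100, bool), n_perm=50, seed=0)

    def test_false_positive_rate_calibrated(self):
        """Independent noise: two-sided significant fraction ≈ 0.05 ± 0.02."""
        rng = np.random.default_rng(10)
        ts = CalciumTraceSet(rng.normal(size=(34, 400)))  # 561 pairs
        classes, _ = net.classify_pair_correlations(
            ts, np.ones(400, bool), n_perm=10000, seed=1
        )
        iu = np.triu_indices(34, k=1)
        sig = np.isin(classes[iu], ["positive", "negative"]).mean()
        assert 0.03 <= sig <= 0.07


class TestDecayFit:
    def test_noiseless_exact_recovery(self):
        x = np.linspace(0, 10, 200)
        y = 2.0 * np.exp(-0.5 * x)
        fit = net.fit_correlation_decay(y, x, n_boot=50, seed=0)
        assert fit.A == pytest.approx(2.0, abs=1e-6)
        assert fit.k == pytest.approx(-0.5, abs=1e-6)

    def test_negative_category_sign(self):
        x = np.linspace(0, 10, 100)
        y = -0.8 * np.exp(-0.3 * x)
        fit = net.fit_correlation_decay(y, x, category="negative", n_boot=50, seed=0)
        assert fit.sign == -1
        assert fit.A == pytest.approx(0.8, abs=1e-6)
        assert fit.k == pytest.approx(-0.3, abs=1e-6)

    def test_bootstrap_ci_coverage(self):
        """Known (A, k) inside the bootstrap 95% CI in >= 90% of seeded runs."""
        A0, k0 = 0.4, -0.004
        hits = 0
        runs = 20
        for run in range(runs):
            rng = np.random.default_rng(100 + run)
            d = rng.uniform(0, 450, size=2000)
            r = A0 * np.exp(k0 * d) + rng.normal(0, 0.05, size=2000)
            fit = net.fit_correlation_decay(r, d, n_boot=300, seed=run)
            if fit.k_ci[0] <= k0 <= fit.k_ci[1] and fit.A_ci[0] <= A0 <= fit.A_ci[1]:
                hits += 1
        assert hits / runs >= 0.9

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            net.fit_correlation_decay(np.ones(5), np.ones(5))


class TestDecayComparison:
    def _fit(self, k, se):
        return net.DecayFit(
            A=1.0, k=k, A_ci=(0.9, 1.1), k_ci=(k - se, k + se), A_se=0.05,
            k_se=se, n_pairs=100, category="positive", sign=1, converged=True,
        )

    def test_identical_fits(self):
        z, p = net.compare_decay_rates(self._fit(-0.5, 0.1), self._fit(-0.5, 0.1))
        assert z == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_two_sigma_difference(self):
        se = 0.1
        gap = 2.0 * np.sqrt(2 * se**2)
        z, _ = net.compare_decay_rates(self._fit(-0.5 + gap, se), self._fit(-0.5, se))
        assert z == pytest.approx(2.0)

    def test_antisymmetric(self):
        f1, f2 = self._fit(-0.2, 0.05), self._fit(-0.6, 0.08)
        z12, _ = net.compare_decay_rates(f1, f2)
        z21, _ = net.compare_decay_rates(f2, f1)
        assert z12 == pytest.approx(-z21)

    def test_zero_se_raises(self):
        with pytest.raises(ValueError):
            net.compare_decay_rates(self._fit(-0.5, 0.0), self._fit(-0.5, 0.0))


def block_matrix(sizes, within=0.6, between=0.0, noise=0.02, seed=0):
    """Planted block correlation matrix with small symmetric jitter."""
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    m = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    rng = np.random.default_rng(seed)
    jit = rng.normal(0, noise, size=(n, n))
    m = m + (jit + jit.T) / 2
    np.fill_diagonal(m, 0.0)
    return m, labels


class TestClustering:
    def test_two_block_recovery(self):
        m, labels = block_matrix([15, 15])
        k, assign, _ = net.cluster_states(m, seed=0)
        assert k == 2
        # exact recovery up to label permutation
        agreement = max((assign == labels).mean(), (assign == 1 - labels).mean())
        assert agreement == 1.0

    def test_three_block_selection(self):
        m, labels = block_matrix([12, 12, 12])
        k, assign, sil = net.cluster_states(m, seed=0)
        assert k == 3
        assert len(set(map(tuple, [assign[labels == g] for g in range(3)][0:1]))) == 1

    def test_seed_deterministic(self):
        m, _ = block_matrix([10, 10], noise=0.05, seed=3)
        _, a1, _ = net.cluster_states(m, seed=5)
        _, a2, _ = net.cluster_states(m, seed=5)
        np.testing.assert_array_equal(a1, a2)

    def test_degenerate_identical_rows(self):
        m = np.zeros((10, 10))
        k, assign, _ = net.cluster_states(m, seed=0)
        assert k == 1 and set(assign) == {0}


class TestClusterMetrics:
    def test_single_point_zero_compactness(self):
        pts = np.tile([10.0, 20.0], (5, 1))
        out = net.cluster_metrics(np.zeros(5, int), pts)
        assert out.loc[0, "compactness_um"] == 0.0

    def test_two_cells_ten_um_apart(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0]])
        out = net.cluster_metrics(np.zeros(2, int), pts)
        assert out.loc[0, "compactness_um"] == pytest.approx(5.0)

    def test_bruteforce_mean_distance(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 450, size=(30, 2))
        assign = rng.integers(0, 3, size=30)
        out = net.cluster_metrics(assign, pts).set_index("cluster")
        for c in np.unique(assign):
            members = pts[assign == c]
            center = members.mean(axis=0)
            expected = np.mean([np.hypot(*(p - center)) for p in members])
            assert out.loc[c, "compactness_um"] == pytest.approx(expected)
            assert out.loc[c, "size"] == (assign == c).sum()


class TestCouplingComparison:
    def _setup(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        m, labels = block_matrix([10, 10], within=0.4, between=-0.1, noise=0.03, seed=seed)
        m2 = m.copy()
        intra = labels[:, None] == labels[None, :]
        m2[intra] += shift
        np.fill_diagonal(m2, 0.0)
        dist = np.abs(rng.uniform(0, 450, 20)[:, None] - rng.uniform(0, 450, 20)[None, :])
        return m, m2, labels, dist

    def test_identical_matrices_zero_difference(self):
        m, _, labels, dist = self._setup()
        out = net.compare_cluster_coupling(m, m, labels, dist)
        paired = out[out["partition"].str.contains("_")]
        rows = paired[paired["partition"].isin(["intra_positive", "inter_negative"])]
        for _, r in rows.iterrows():
            if not r.get("skipped", False):
                assert r["mean_engaged"] == pytest.approx(r["mean_disengaged"])

    def test_detects_intra_shift(self):
        m, m2, labels, dist = self._setup(shift=0.1)
        out = net.compare_cluster_coupling(m2, m, labels, dist).set_index("partition")
        row = out.loc["intra_positive"]
        assert row["mean_engaged"] - row["mean_disengaged"] == pytest.approx(0.1, abs=0.02)
        assert row["p"] < 0.001

    def test_spearman_perfectly_decreasing(self):
        n = 8
        pts = 2.0 ** np.arange(n)  # all pairwise gaps distinct (no rank ties)
        dist = np.abs(pts[:, None] - pts[None, :])
        m = 0.9 * np.exp(-0.02 * dist)
        np.fill_diagonal(m, 0.0)
        out = net.compare_cluster_coupling(m, m, np.zeros(n, int), dist).set_index("partition")
        assert out.loc["spearman_positive_engaged", "rho"] == pytest.approx(-1.0)


class TestPairTable:
    def test_upper_triangle_contents(self):
        rng = np.random.default_rng(12)
        m = rng.normal(size=(4, 4))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        dist = rng.uniform(0, 100, size=(4, 4))
        df = net.pair_table(m, dist, assignments=np.array([0, 0, 1, 1]))
        assert len(df) == 6
        row = df[(df["cell_i"] == 0) & (df["cell_j"] == 2)].iloc[0]
        assert row["r"] == m[0, 2] and not row["intra_cluster"]
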