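import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gwasnet import simulate as sim
from gwasnet.msea import (
    MSEA,
    MarkerAssignment,
    bh_fdr,
    build_marker_assignment,
    msea_null,
    msea_pvalue,
    msea_statistic,
)


def _assignment(neglogp, gene_markers, quantiles):
    ids = np.array([f"m{i}" for i in range(len(neglogp))])
    return MarkerAssignment(ids, np.asarray(neglogp, float), gene_markers, quantiles)


class TestStatistic:
    def test_worked_value(self):
        """Background of 100 markers, set of 10, O=(8,5) at E=(5,1):
        Q = 3/sqrt(6) + 4/sqrt(2) = 4.0531."""
        # background: tiers chosen so the (1-q) quantiles give E=(5,1)
        # for a 10-marker set: f = (0.5, 0.1)
        bg = np.concatenate([np.zeros(50), np.ones(40), np.full(10, 2.0)])
        # set markers: 8 at or above cutoff1 (value>=1), 5 of them >= cutoff2
        set_vals_idx = np.concatenate(
            [np.arange(0, 2), np.arange(50, 53), np.arange(90, 95)]
        )
        asg = _assignment(bg, {"g": set_vals_idx}, (0.50, 0.10))
        q = msea_statistic(asg, ["g"])
        assert q == pytest.approx(3 / np.sqrt(6) + 4 / np.sqrt(2), abs=1e-10)
        assert q == pytest.approx(4.0531, abs=1e-4)

    def test_proportional_set_gives_zero(self):
        """A set hitting the background tiers exactly proportionally has Q=0."""
        bg = np.concatenate([np.zeros(50), np.ones(40), np.full(10, 2.0)])
        idx = np.concatenate([np.arange(0, 5), np.arange(50, 54), np.arange(90, 91)])
        asg = _assignment(bg, {"g": idx}, (0.50, 0.10))
        assert msea_statistic(asg, ["g"]) == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_smaller_p_never_decreases_q(self, seed):
        rng = np.random.default_rng(seed)
        bg = rng.random(200) * 6
        idx = rng.choice(200, size=20, replace=False)
        asg = _assignment(bg, {"g": idx}, (0.50, 0.25, 0.10))
        q0 = msea_statistic(asg, ["g"])
        j = idx[int(rng.integers(len(idx)))]
        bg2 = bg.copy()
        bg2[j] = bg2[j] + rng.random() * 4  # smaller p = larger -log10 p
        asg2 = _assignment(bg2, {"g": idx}, (0.50, 0.25, 0.10))
        assert msea_statistic(asg2, ["g"]) >= q0 - 1e-12

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(3)
        bg = rng.random(100)
        idx = np.arange(10)
        a1 = _assignment(bg, {"geneA": idx}, (0.5, 0.1))
        a2 = _assignment(bg, {"XYZ": idx}, (0.5, 0.1))
        assert msea_statistic(a1, ["geneA"]) == msea_statistic(a2, ["XYZ"])

    def test_zero_marker_set_raises(self):
        bg = np.arange(10.0)
        asg = _assignment(bg, {"g": np.arange(3)}, (0.5,))
        with pytest.raises(ValueError, match="marker"):
            msea_statistic(asg, ["not_mapped"])

    def test_bad_quantiles_rejected(self):
        with pytest.raises(ValueError):
            _assignment(np.arange(10.0), {}, (0.1, 0.5))  # not decreasing


@pytest.fixture(scope="module")
def null_assignment():
    layout = sim.simulate_genome(n_genes=300, snps_per_gene=5, genes_per_chrom=100)
    ld = sim.layout_ld(layout, rho=0.0)
    gwas = sim.simulate_gwas(layout, ld, sim.make_truth(layout, []), n=10_000, seed=7)
    return build_marker_assignment(gwas, layout.snp_gene_map(), ld)


class TestNull:
    def test_same_seed_identical(self, null_assignment):
        a = msea_null(null_assignment, 20, n_perm=200, seed=42)
        b = msea_null(null_assignment, 20, n_perm=200, seed=42)
        np.testing.assert_array_equal(a[2], b[2])
        assert a[:2] == b[:2]

    def test_n_perm_floor(self, null_assignment):
        with pytest.raises(ValueError):
            msea_null(null_assignment, 10, n_perm=99, seed=0)

    def test_oversized_set_rejected(self, null_assignment):
        with pytest.raises(ValueError):
            msea_null(null_assignment, 10**6, n_perm=100, seed=0)

    def test_empirical_p_uniform_for_random_sets(self, null_assignment):
        """Under a null GWAS the permutation p of random sets is ~U(0,1)."""
        rng = np.random.default_rng(0)
        _, _, samples = msea_null(null_assignment, 15, n_perm=2_000, seed=1)
        samples = np.sort(samples)
        universe = np.array(null_assignment.universe)
        pvals = []
        for _ in range(500):
            genes = rng.choice(universe, size=15, replace=False)
            q = msea_statistic(null_assignment, genes)
            pvals.append(1 - np.searchsorted(samples, q, side="right") / len(samples))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestPvalue:
    def test_center_is_half(self):
        assert msea_pvalue(2.0, 2.0, 1.5) == pytest.approx(0.5)

    def test_standard_quantile(self):
        assert msea_pvalue(1.644854, 0.0, 1.0) == pytest.approx(0.05, abs=1e-4)

    def test_degenerate_sd_rejected(self):
        with pytest.raises(ValueError):
            msea_pvalue(1.0, 0.0, 0.0)

    def test_tracks_empirical_p(self, null_assignment):
        """Gaussian p and empirical permutation p agree in rank order."""
        rng = np.random.default_rng(9)
        mean, sd, samples = msea_null(null_assignment, 12, n_perm=2_000, seed=5)
        samples = np.sort(samples)
        universe = np.array(null_assignment.universe)
        gauss, emp = [], []
        for _ in range(200):
            genes = rng.choice(universe, size=12, replace=False)
            q = msea_statistic(null_assignment, genes)
            gauss.append(msea_pvalue(q, mean, sd))
            emp.append(1 - np.searchsorted(samples, q, side="right") / len(samples))
        rho = stats.spearmanr(gauss, emp).statistic
        assert rho >= 0.99


def _bh_oracle(p):
    """Direct BH step-up: q_i = min over j with p_(j) >= p_i of p_(j)*m/rank."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        q[i] = running
    return np.minimum(q, 1.0)


class TestBhFdr:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.1], [0.01, 0.1]),
            ([0.7], [0.7]),
        ],
    )
    def test_hand_computed(self, p, expected):
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    def test_empty(self):
        assert len(bh_fdr([])) == 0

    def test_matches_oracle_on_random_lists(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            m = int(rng.integers(1, 13))
            p = rng.random(m)
            np.testing.assert_allclose(bh_fdr(p), _bh_oracle(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


class TestModel:
    def test_deterministic_result_table(self):
        layout = sim.simulate_genome(n_genes=100, snps_per_gene=4)
        ld = sim.layout_ld(layout, rho=0.3)
        gwas = sim.simulate_gwas(layout, ld, sim.make_truth(layout, []), n=5_000, seed=2)
        sets = sim.simulate_gene_sets(30, (10, 20), layout.gene_ids, seed=3)
        res1 = MSEA(gwas, layout.snp_gene_map(), sets, ld=ld).fit(n_perm=200, seed=4)
        res2 = MSEA(gwas, layout.snp_gene_map(), sets, ld=ld).fit(n_perm=200, seed=4)
        assert res1.frame.to_csv() == res2.frame.to_csv()

    def test_planted_set_detected(self):
        layout = sim.simulate_genome(n_genes=400, snps_per_gene=5, genes_per_chrom=100)
        ld = sim.layout_ld(layout, rho=0.3)
        sets = sim.simulate_gene_sets(50, (10, 20), layout.gene_ids, seed=6)
        planted = sets.ids()[0]
        truth = sim.make_truth(
            layout, sets.genes(planted), sqrt_n_beta=4.0, n=20_000,
            causal_sets=[planted],
        )
        gwas = sim.simulate_gwas(layout, ld, truth, n=20_000, seed=7)
        res = MSEA(gwas, layout.snp_gene_map(), sets, ld=ld).fit(n_perm=500, seed=8)
        assert planted in res.significant_sets(0.05)
        assert res.frame.iloc[0]["set_id"] == planted

    def test_summary_mentions_counts(self, null_assignment):
        layout = sim.simulate_genome(n_genes=100, snps_per_gene=4)
        ld = sim.layout_ld(layout, rho=0.0)
        gwas = sim.simulate_gwas(layout, ld, sim.make_truth(layout, []), n=5_000, seed=2)
        sets = sim.simulate_gene_sets(10, (10, 15), layout.gene_ids, seed=3)
        res = MSEA(gwas, layout.snp_gene_map(), sets, ld=ld).fit(n_perm=100, seed=1)
        text = res.summary()
        assert "sets tested: 10" in text and "seed: 1" in text
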