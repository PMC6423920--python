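import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gwasnet.io import GwasTable, LdData
from gwasnet.mapping import (
    EqtlTable,
    SnpGeneMap,
    combine_mappings,
    filter_snps_by_maf,
    ld_prune,
    map_by_distance,
    map_by_eqtl,
)
from conftest import make_gwas

GENES = pd.DataFrame(
    {"gene_id": ["G1"], "chrom": ["1"], "start": [100_000], "end": [120_000]}
)


class TestMafFilter:
    def test_strict_boundary(self, tiny_gwas):
        out = filter_snps_by_maf(tiny_gwas, 0.01)
        kept = set(out.df["snp_id"])
        assert "B" not in kept  # maf 0.005 < 1% removed
        assert "C" in kept  # maf exactly 0.01 retained
        assert list(out.df["snp_id"]) == ["A", "C", "D"]  # order preserved

    def test_no_maf_column_is_identity(self):
        g = make_gwas([0.1, 0.2])
        out = filter_snps_by_maf(g)
        pd.testing.assert_frame_equal(out.df, g.df)

    def test_bad_threshold(self, tiny_gwas):
        with pytest.raises(ValueError):
            filter_snps_by_maf(tiny_gwas, 0.6)


class TestDistanceMapping:
    @pytest.mark.parametrize(
        "pos,linked",
        [
            (150_000, True),   # 30 kb downstream of gene end
            (170_000, True),   # exactly 50 kb: inclusive window
            (170_001, False),  # 50,001 bp away
            (50_000, True),    # exactly 50 kb upstream
            (49_999, False),
            (110_000, True),   # inside the gene body
        ],
    )
    def test_window_boundaries(self, pos, linked):
        g = GwasTable(
            pd.DataFrame({"snp_id": ["s"], "chrom": ["1"], "pos": [pos], "p": [0.5]})
        )
        m = map_by_distance(g, GENES, window_bp=50_000)
        assert (("s", "G1") in m.links) == linked

    def test_window_zero_only_gene_bodies(self):
        g = make_gwas([0.5] * 3)
        g.df["pos"] = [99_999, 100_000, 120_001]
        m = map_by_distance(g, GENES, window_bp=0)
        assert m.snp_ids == {"s1"}

    def test_snp_can_map_to_multiple_genes(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["G1", "G2"],
                "chrom": ["1", "1"],
                "start": [100_000, 130_000],
                "end": [120_000, 140_000],
            }
        )
        g = GwasTable(
            pd.DataFrame({"snp_id": ["s"], "chrom": ["1"], "pos": [125_000], "p": [0.5]})
        )
        m = map_by_distance(g, genes, window_bp=50_000)
        assert {gid for _, gid in m.links} == {"G1", "G2"}

    def test_start_after_end_rejected(self):
        bad = pd.DataFrame(
            {"gene_id": ["G"], "chrom": ["1"], "start": [10], "end": [5]}
        )
        with pytest.raises(Exception, match="start"):
            map_by_distance(make_gwas([0.5]), bad)


class TestEqtlMapping:
    EQTL = EqtlTable(
        pd.DataFrame(
            {
                "snp_id": ["s1", "s2", "s3"],
                "gene_id": ["g1", "g2", "g3"],
                "tissue": ["adipose", "heart", "adipose"],
                "p": [1e-9, 5e-6, 2e-5],
                "fdr": [0.04, 0.2, 0.05],
            }
        )
    )

    def test_significant_mode_strict_fdr(self):
        m = map_by_eqtl(self.EQTL, mode="significant", fdr_max=0.05)
        assert ("s1", "g1") in m.links
        assert ("s3", "g3") not in m.links  # fdr exactly 0.05 excluded
        assert m.links[("s1", "g1")] == frozenset({"eqtl:adipose"})

    def test_suggestive_mode(self):
        m = map_by_eqtl(self.EQTL, mode="suggestive", p_max=1e-5)
        assert ("s2", "g2") in m.links
        assert ("s3", "g3") not in m.links  # p=2e-5 above cutoff

    def test_tissue_filter(self):
        m = map_by_eqtl(self.EQTL, mode="suggestive", tissues=["heart"])
        assert m.snp_ids == {"s2"}

    def test_significant_requires_fdr(self):
        no_fdr = EqtlTable(self.EQTL.df.drop(columns="fdr"))
        with pytest.raises(ValueError, match="fdr"):
            map_by_eqtl(no_fdr, mode="significant")


class TestCombine:
    def _map(self, pairs, source):
        return SnpGeneMap(
            {p: frozenset([source]) for p in pairs}, provenance=[source]
        )

    def test_union_with_source_merge(self):
        a = self._map([("s1", "g1")], "distance")
        b = self._map([("s1", "g1"), ("s2", "g2")], "eqtl:adipose")
        m = combine_mappings([a, b])
        assert len(m) == 2
        assert m.links[("s1", "g1")] == frozenset({"distance", "eqtl:adipose"})

    def test_identity_and_disjoint(self):
        a = self._map([("s1", "g1"), ("s2", "g1"), ("s3", "g2")], "x")
        assert combine_mappings([a]).links == a.links
        b = self._map([(f"t{i}", "g9") for i in range(4)], "y")
        assert len(combine_mappings([a, b])) == 7

    def test_associative_idempotent(self):
        a = self._map([("s1", "g1")], "x")
        b = self._map([("s2", "g2")], "y")
        c = self._map([("s1", "g1"), ("s3", "g3")], "z")
        left = combine_mappings([combine_mappings([a, b]), c])
        right = combine_mappings([a, combine_mappings([b, c])])
        assert left.links == right.links
        assert combine_mappings([left, left]).links == left.links

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            combine_mappings([])


def _oracle_prune(pvals, ids, r2, r2_max):
    """Independent greedy pruning by exhaustive pairwise checks."""
    order = sorted(range(len(ids)), key=lambda i: (pvals[i], ids[i]))
    kept = []
    for i in order:
        if all(r2[i][j] < r2_max for j in kept):
            kept.append(i)
    return {ids[i] for i in kept}


class TestLdPrune:
    def test_keeps_strongest_of_correlated_pair(self):
        g = make_gwas([1e-8, 1e-4], prefix="x")
        ld = LdData(pairs=[("x0", "x1", 0.8)])
        assert ld_prune(g, {"x0", "x1"}, ld) == {"x0"}

    def test_below_cutoff_keeps_both(self):
        g = make_gwas([1e-8, 1e-4], prefix="x")
        ld = LdData(pairs=[("x0", "x1", 0.69)])
        assert ld_prune(g, {"x0", "x1"}, ld) == {"x0", "x1"}

    def test_missing_snp_named(self):
        g = make_gwas([0.5])
        with pytest.raises(ValueError, match="zzz"):
            ld_prune(g, {"zzz"}, LdData())

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 13))
        pvals = rng.random(k)
        ids = [f"s{i}" for i in range(k)]
        r2 = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                if rng.random() < 0.5:
                    r2[i, j] = r2[j, i] = rng.random()
        g = make_gwas(pvals)
        ld = LdData(
            pairs=[
                (ids[i], ids[j], r2[i, j])
                for i in range(k)
                for j in range(i + 1, k)
                if r2[i, j] > 0
            ]
        )
        got = ld_prune(g, set(ids), ld, r2_max=0.7)
        assert got == _oracle_prune(pvals, ids, r2, 0.7)
        # pairwise r2 of the kept set all below the cutoff
        kept = sorted(got)
        assert all(
            ld.r2(a, b) < 0.7 for x, a in enumerate(kept) for b in kept[x + 1:]
        )

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        pvals = rng.random(8)
        g = make_gwas(pvals)
        ids = list(g.df["snp_id"])
        ld = LdData(pairs=[(ids[0], ids[3], 0.9), (ids[2], ids[5], 0.75)])
        a = ld_prune(g, ids, ld)
        b = ld_prune(g, list(reversed(ids)), ld)
        assert a == b
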