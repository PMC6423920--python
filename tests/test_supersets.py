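from math import comb

import numpy as np
import pytest
from scipy.stats import hypergeom

from gwasnet import simulate as sim
from gwasnet.io import GeneSet, GeneSetCollection
from gwasnet.msea import MSEA
from gwasnet.supersets import (
    annotate_supersets,
    confirm_supersets,
    fisher_exact_2x2,
    merge_gene_sets,
    supersets_to_collection,
)


def _coll(d, source="pathway"):
    return GeneSetCollection(
        {k: GeneSet(k, frozenset(v), source) for k, v in d.items()}
    )


def _enumerate_fisher(a, b, c, d, sided):
    """Hypergeometric enumeration over all tables with the fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {x: hypergeom.pmf(x, n, r1, c1) for x in range(lo, hi + 1)}
    if sided == "greater":
        return sum(probs[x] for x in probs if x >= a)
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_small_table_one_sided(self):
        # [[2,0],[0,2]]: only 3 tables share the margins; upper tail = 1/6
        assert fisher_exact_2x2(2, 0, 0, 2, "greater") == pytest.approx(1 / 6, abs=1e-12)

    def test_independence_gives_one(self):
        assert fisher_exact_2x2(1, 1, 1, 1, "two") == pytest.approx(1.0)

    def test_diagonal_two_sided(self):
        assert fisher_exact_2x2(10, 0, 0, 10, "two") == pytest.approx(
            2 / comb(20, 10), rel=1e-9
        )

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 0, 0, 1)

    @pytest.mark.parametrize("sided", ["greater", "two"])
    def test_matches_enumeration_small_margins(self, sided):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 7, size=4)
            if a + b + c + d == 0:
                continue
            got = fisher_exact_2x2(int(a), int(b), int(c), int(d), sided)
            want = _enumerate_fisher(int(a), int(b), int(c), int(d), sided)
            assert got == pytest.approx(want, rel=1e-7, abs=1e-12)


UNIVERSE = {f"g{i}" for i in range(1, 1001)}


class TestMerge:
    def test_disjoint_sets_pass_through(self):
        coll = _coll({"A": [f"g{i}" for i in range(1, 11)],
                      "B": [f"g{i}" for i in range(100, 110)]})
        out = merge_gene_sets(coll, UNIVERSE)
        assert len(out) == 2
        assert {tuple(ss.member_set_ids) for ss in out} == {("A",), ("B",)}
        assert {ss.genes for ss in out} == {coll.genes("A"), coll.genes("B")}

    def test_identical_sets_merge(self):
        genes = [f"g{i}" for i in range(1, 16)]
        out = merge_gene_sets(_coll({"A": genes, "B": genes}), UNIVERSE)
        assert len(out) == 1
        assert out[0].member_set_ids == ["A", "B"]

    def test_transitive_chain_single_superset(self):
        """A-B and B-C each share 5 of 10 genes: one superset by closure."""
        A = [f"g{i}" for i in range(1, 11)]
        B = [f"g{i}" for i in range(1, 6)] + [f"g{i}" for i in range(11, 16)]
        C = [f"g{i}" for i in range(11, 16)] + [f"g{i}" for i in range(16, 21)]
        out = merge_gene_sets(_coll({"A": A, "B": B, "C": C}), UNIVERSE)
        assert len(out) == 1
        assert out[0].member_set_ids == ["A", "B", "C"]
        assert out[0].genes == frozenset(A) | frozenset(B) | frozenset(C)

    def test_empty_collection(self):
        assert merge_gene_sets(_coll({}), UNIVERSE) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_invariants_on_random_collections(self, seed):
        universe = [f"g{i}" for i in range(400)]
        overlaps = [("S0000", "S0001", 0.6), ("S0002", "S0003", 0.5)]
        coll = sim.simulate_gene_sets(
            12, (10, 25), universe, overlap_spec=overlaps, seed=seed
        )
        out = merge_gene_sets(coll, set(universe))
        # union preservation
        assert frozenset().union(*(ss.genes for ss in out)) == coll.all_genes()
        # member partition
        members = [m for ss in out for m in ss.member_set_ids]
        assert sorted(members) == sorted(coll.ids())
        # idempotence: merging the supersets again changes nothing
        again = merge_gene_sets(supersets_to_collection(out), set(universe))
        assert {ss.genes for ss in again} == {ss.genes for ss in out}
        assert len(again) == len(out)


class TestAnnotate:
    def test_reference_equal_to_superset_is_top_hit(self):
        genes = [f"g{i}" for i in range(1, 21)]
        out = merge_gene_sets(_coll({"A": genes}), UNIVERSE)
        ref = _coll({"PATH1": genes, "PATH2": [f"g{i}" for i in range(500, 540)]})
        annotated = annotate_supersets(out, ref, UNIVERSE)
        assert annotated[0].annotations
        top_id, p, p_bonf = annotated[0].annotations[0]
        assert top_id == "PATH1" and p_bonf < 0.05

    def test_no_shared_genes_no_annotations(self):
        out = merge_gene_sets(_coll({"A": [f"g{i}" for i in range(1, 11)]}), UNIVERSE)
        ref = _coll({"P": [f"g{i}" for i in range(900, 950)]})
        assert annotate_supersets(out, ref, UNIVERSE)[0].annotations == []

    def test_annotations_sorted_ascending(self):
        genes = [f"g{i}" for i in range(1, 31)]
        out = merge_gene_sets(_coll({"A": genes}), UNIVERSE)
        ref = _coll({"P1": genes[:30], "P2": genes[:15] + [f"g{i}" for i in range(800, 815)]})
        ann = annotate_supersets(out, ref, UNIVERSE)[0].annotations
        ps = [p for _, p, _ in ann]
        assert ps == sorted(ps)


class TestConfirm:
    def test_single_superset_bonferroni_factor_one(self):
        layout = sim.simulate_genome(n_genes=300, snps_per_gene=5, genes_per_chrom=100)
        ld = sim.layout_ld(layout, rho=0.3)
        sets = sim.simulate_gene_sets(20, (12, 20), layout.gene_ids, seed=1)
        planted = sets.ids()[0]
        truth = sim.make_truth(layout, sets.genes(planted), sqrt_n_beta=4.0, n=20_000)
        gwas = sim.simulate_gwas(layout, ld, truth, n=20_000, seed=2)
        supersets = merge_gene_sets(
            sets.subset([planted]), set(layout.gene_ids)
        )
        conf = confirm_supersets(
            supersets, gwas, layout.snp_gene_map(), ld=ld, n_perm=300, seed=3
        )
        assert len(conf) == 1
        row = conf.iloc[0]
        assert row["p_bonferroni"] == pytest.approx(min(row["p"] * 1, 1.0))
        assert bool(row["confirmed"]) == (row["p"] < 0.05)
        assert row["confirmed"]  # planted signal is confirmed

    def test_random_superset_rarely_confirmed(self):
        layout = sim.simulate_genome(n_genes=300, snps_per_gene=5, genes_per_chrom=100)
        ld = sim.layout_ld(layout, rho=0.3)
        gwas = sim.simulate_gwas(layout, ld, sim.make_truth(layout, []), n=20_000, seed=4)
        sets = sim.simulate_gene_sets(10, (12, 20), layout.gene_ids, seed=5)
        supersets = merge_gene_sets(sets, set(layout.gene_ids))
        conf = confirm_supersets(
            supersets, gwas, layout.snp_gene_map(), ld=ld, n_perm=300, seed=6
        )
        # under the null, Bonferroni confirmation at 0.05 is rare
        assert conf["confirmed"].sum() <= 1
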