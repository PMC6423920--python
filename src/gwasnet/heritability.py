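"""SNP-set heritability from GWAS summary statistics and block LD.

Within an LD block with z-scores ``z``, correlation matrix ``V`` and
GWAS sample size ``n``, the variance explained by the block's SNPs is
estimated in the standard summary-statistics form

    h2_block = (z' V+ z − q) / (n − q)

where ``V+`` is the pseudo-inverse of V truncating eigenvalues below
``eig_min`` and ``q`` the number retained.  Only z² enters, so the sign
of z (unavailable when derived from two-sided p-values) is irrelevant.
Set-level heritability sums block estimates over the blocks a SNP set
touches; SNPs outside any block act as singleton blocks with V = [1].
Negative block estimates are retained so the sum stays unbiased.  The
standard error is a delete-one-block jackknife.

The significance of a gene subnetwork's heritability is judged against
random gene sets of matching gene count drawn from a pool of non-member
genes, with P = #(h2_random > h2_target) / n_perm — the resolution of
this p-value is exactly 1/n_perm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .io import GwasTable, LdData
from .mapping import SnpGeneMap, ld_prune

logger = logging.getLogger(__name__)

__all__ = [
    "HeritabilityEstimate",
    "PermutationComparison",
    "block_h2",
    "set_h2",
    "gwas_hits_h2",
    "kd_subnetwork_h2_test",
]


@dataclass
class HeritabilityEstimate:
    label: str
    h2: float
    se: float
    n_snps: int
    n_blocks: int


@dataclass
class PermutationComparison:
    h2_target: float
    h2_random_mean: float
    h2_random_sd: float
    p_kd: float
    n_perm: int

    def p_kd_display(self) -> str:
        """p as printed: zero counts are reported as below resolution."""
        if self.p_kd == 0.0:
            return f"< {1.0 / self.n_perm:g}"
        return f"{self.p_kd:g}"


def block_h2(z, V, n: int, eig_min: float = 1e-8) -> float:
    """Heritability of one LD block from its z-scores.

    ``V`` is the block correlation matrix; its pseudo-inverse truncates
    eigenvalues below ``eig_min``.  Requires n > q (retained rank).
    """
    z = np.asarray(z, dtype=float)
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if V.shape[0] != len(z):
        raise ValueError("z length does not match V dimension")
    w, U = linalg.eigh(V)
    keep = w >= eig_min
    q = int(keep.sum())
    if n <= q:
        raise ValueError(f"sample size n={n} must exceed retained rank q={q}")
    proj = U[:, keep].T @ z
    quad = float(np.sum(proj**2 / w[keep]))  # z' V+ z  (= n * beta' V+ beta)
    return (quad - q) / (n - q)


def _block_values(gwas: GwasTable, ld: LdData, snps, n: int, zmap=None) -> np.ndarray:
    """Per-block heritability values for a SNP set.

    SNPs sharing an LD block are estimated jointly on the block's
    sub-matrix; SNPs outside any block are singleton blocks with V=[1],
    for which the estimate reduces to (z^2 - 1)/(n - 1) in closed form.
    """
    if zmap is None:
        zmap = dict(zip(gwas.df["snp_id"], gwas.zscores()))
    by_block: dict[int, list[str]] = {}
    singles: list[str] = []
    for s in sorted(snps):
        b = ld.block_of(s)
        if b is None:
            singles.append(s)
        else:
            by_block.setdefault(b, []).append(s)
    vals = []
    for b in sorted(by_block):
        ids = by_block[b]
        blk = ld.blocks[b]
        if len(ids) == 1:
            vals.append((zmap[ids[0]] ** 2 - 1.0) / (n - 1))
            continue
        index = {s: i for i, s in enumerate(blk.snp_ids)}
        pos = [index[s] for s in ids]
        V = blk.V[np.ix_(pos, pos)]
        vals.append(block_h2(np.array([zmap[s] for s in ids]), V, n))
    if singles:
        zs = np.array([zmap[s] for s in singles])
        vals.extend(((zs**2 - 1.0) / (n - 1)).tolist())
    return np.asarray(vals)


def set_h2(gwas: GwasTable, ld: LdData, snps, n: int, label: str = "set") -> HeritabilityEstimate:
    """Summed block heritability of a SNP set, with jackknife SE."""
    snps = set(snps)
    if not snps:
        raise ValueError("empty SNP set")
    missing = snps - gwas.snp_ids
    if missing:
        raise ValueError(f"SNP {sorted(missing)[0]!r} not in GWAS table")
    vals = _block_values(gwas, ld, snps, n)
    h2 = float(vals.sum())
    B = len(vals)
    if B > 1:
        # delete-one-block jackknife on the additive estimator
        theta = h2 - vals  # leave-one-out sums
        se = float(np.sqrt((B - 1) / B * np.sum((theta - theta.mean()) ** 2)))
    else:
        se = 0.0
        logger.warning("single LD block: jackknife SE unavailable, reported 0")
    return HeritabilityEstimate(label, h2, se, n_snps=len(snps), n_blocks=B)


def gwas_hits_h2(
    gwas: GwasTable, ld: LdData, n: int, p_max: float = 5e-8, label: str = "gwas_hits"
) -> HeritabilityEstimate:
    """Heritability of genome-wide significant SNPs only (p < ``p_max``)."""
    hits = set(gwas.df.loc[gwas.df["p"] < p_max, "snp_id"])
    if not hits:
        logger.warning("no SNP below p=%g: hits heritability is 0", p_max)
        return HeritabilityEstimate(label, 0.0, 0.0, n_snps=0, n_blocks=0)
    return set_h2(gwas, ld, hits, n, label=label)


def _prune_fast(pmap, snps, ld: LdData, r2_max: float) -> set[str]:
    order = sorted(snps, key=lambda s: (pmap[s], s))
    kept: set[str] = set()
    for s in order:
        if all(other not in kept or r2 < r2_max for other, r2 in ld.correlated_with(s)):
            kept.add(s)
    return kept


def _genes_h2(g2s, zmap, pmap, valid, gwas, ld, genes, n, r2_max, prune) -> float:
    snps: set[str] = set()
    for g in genes:
        snps.update(g2s.get(g, ()))
    snps &= valid
    if not snps:
        return 0.0
    if prune:
        snps = _prune_fast(pmap, snps, ld, r2_max)
    return float(_block_values(gwas, ld, snps, n, zmap=zmap).sum())


def kd_subnetwork_h2_test(
    gwas: GwasTable,
    ld: LdData,
    snp_gene_map: SnpGeneMap,
    subnetwork_genes,
    pool_genes,
    n: int,
    n_perm: int = 10_000,
    seed: int = 0,
    r2_max: float = 0.7,
    prune: bool = True,
) -> PermutationComparison:
    """Compare a gene subnetwork's heritability with matched random sets.

    The target is the summed block heritability of the LD-pruned SNPs
    mapped to ``subnetwork_genes``.  Each of ``n_perm`` permutations
    draws the same number of genes from ``pool_genes`` (which must
    exclude the subnetwork genes) and recomputes the quantity;
    P = #(h2_random > h2_target) / n_perm.
    """
    sub = sorted(set(subnetwork_genes))
    pool = sorted(set(pool_genes) - set(sub))
    if len(pool) < len(sub):
        raise ValueError("pool of non-member genes smaller than the subnetwork")
    g2s = snp_gene_map.genes_to_snps()
    zmap = dict(zip(gwas.df["snp_id"], gwas.zscores()))
    pmap = dict(zip(gwas.df["snp_id"], gwas.df["p"]))
    valid = gwas.snp_ids
    h2_target = _genes_h2(g2s, zmap, pmap, valid, gwas, ld, sub, n, r2_max, prune)
    rng = np.random.default_rng(seed)
    pool_arr = np.array(pool)
    draws = np.empty(n_perm)
    for t in range(n_perm):
        pick = rng.choice(len(pool_arr), size=len(sub), replace=False)
        draws[t] = _genes_h2(
            g2s, zmap, pmap, valid, gwas, ld, pool_arr[pick], n, r2_max, prune
        )
    p_kd = float((draws > h2_target).sum()) / n_perm
    return PermutationComparison(
        h2_target, float(draws.mean()), float(draws.std(ddof=1)), p_kd, n_perm
    )
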