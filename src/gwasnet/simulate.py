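"""Synthetic data generators mirroring the statistical structure of the
real inputs: block-structured LD, GWAS z-scores with planted gene-set
signals, multi-tissue eQTL maps, gene-set collections with controlled
overlap, and scale-free networks with planted key drivers.

Every generator is a pure function of its parameters and seed, and each
simulation records its ground truth in a :class:`SyntheticTruth` so that
planted quantities can be recomputed independently.

GWAS z-scores follow the standard summary-statistics model: within an
LD block with correlation matrix V and standardized effects beta,

    z ~ MultivariateNormal(sqrt(n) * V * beta,  V)

so the variance explained by SNP j is beta_j^2 and the planted
heritability of a causal set is sum(beta^2).  Simulating z directly
(rather than genotypes) keeps the generator exact and fast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneNetwork, GeneSet, GeneSetCollection, LdBlock, LdData, GwasTable
from .mapping import EqtlTable, SnpGeneMap

__all__ = [
    "SyntheticTruth",
    "GenomeLayout",
    "simulate_genome",
    "simulate_ld_blocks",
    "make_truth",
    "simulate_gwas",
    "simulate_gene_sets",
    "simulate_eqtl_table",
    "simulate_network_with_kds",
    "write_two_trait_bundle",
]


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation, serialisable to JSON."""

    causal_gene_sets: list[str] = field(default_factory=list)
    causal_snps: dict[str, float] = field(default_factory=dict)  # snp -> beta
    planted_h2: float = 0.0
    planted_kds: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(b * b for b in self.causal_snps.values())
        if self.causal_snps and abs(total - self.planted_h2) > 1e-12:
            raise ValueError(
                f"sum of beta^2 ({total}) does not equal planted_h2 ({self.planted_h2})"
            )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class GenomeLayout:
    """A toy genome: genes in non-overlapping regions, SNPs inside them.

    ``snps`` has columns snp_id, chrom, pos, block; ``genes`` has
    gene_id, chrom, start, end.  Block k holds exactly the SNPs of gene
    k, so distance mapping at the default window reproduces the layout's
    implied SNP-to-gene map.
    """

    snps: pd.DataFrame
    genes: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes["gene_id"])

    def snp_gene_map(self) -> SnpGeneMap:
        links = {}
        gid = self.genes["gene_id"].to_numpy()
        for s, b in zip(self.snps["snp_id"], self.snps["block"]):
            links[(s, str(gid[b]))] = frozenset(["distance"])
        return SnpGeneMap(links, provenance=["distance"])

    def snps_of_genes(self, genes) -> list[str]:
        genes = set(genes)
        idx = {g: i for i, g in enumerate(self.genes["gene_id"])}
        blocks = {idx[g] for g in genes if g in idx}
        mask = self.snps["block"].isin(blocks)
        return list(self.snps.loc[mask, "snp_id"])


def simulate_genome(
    n_genes: int = 200,
    snps_per_gene: int = 10,
    gene_length: int = 20_000,
    gene_spacing: int = 200_000,
    genes_per_chrom: int = 100,
) -> GenomeLayout:
    """Deterministic gene/SNP layout with one LD block per gene."""
    genes = []
    snps = []
    for k in range(n_genes):
        chrom = str(1 + k // genes_per_chrom)
        start = 1 + (k % genes_per_chrom) * gene_spacing
        end = start + gene_length - 1
        gid = f"G{k:04d}"
        genes.append({"gene_id": gid, "chrom": chrom, "start": start, "end": end})
        step = max(gene_length // (snps_per_gene + 1), 1)
        for j in range(snps_per_gene):
            snps.append(
                {
                    "snp_id": f"rs{k:04d}_{j:02d}",
                    "chrom": chrom,
                    "pos": start + (j + 1) * step,
                    "block": k,
                }
            )
    return GenomeLayout(pd.DataFrame(snps), pd.DataFrame(genes))


def simulate_ld_blocks(
    n_blocks: int,
    block_size: int,
    rho: float,
    seed: int = 0,
    snp_ids: list[list[str]] | None = None,
    structure: str = "ar1",
) -> LdData:
    """AR(1) LD blocks: V_ij = rho^|i-j| (positive-definite for rho < 1).

    A compound-symmetry alternative (constant off-diagonal rho) is
    available via ``structure='cs'``.  ``snp_ids`` overrides the default
    per-block id lists.  The generator is deterministic; ``seed`` is
    accepted for interface uniformity.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must lie in [0, 1), got {rho}")
    if structure not in ("ar1", "cs"):
        raise ValueError("structure must be 'ar1' or 'cs'")
    idx = np.arange(block_size)
    if structure == "ar1":
        V = rho ** np.abs(idx[:, None] - idx[None, :])
    else:
        V = np.full((block_size, block_size), rho)
        np.fill_diagonal(V, 1.0)
    blocks = []
    for b in range(n_blocks):
        ids = snp_ids[b] if snp_ids is not None else [f"rs{b:04d}_{j:02d}" for j in range(block_size)]
        blocks.append(LdBlock(list(ids), V.copy()))
    return LdData(blocks=blocks)


def layout_ld(layout: GenomeLayout, rho: float, structure: str = "ar1") -> LdData:
    """LD blocks aligned with a :class:`GenomeLayout` (one block per gene)."""
    ids = [
        list(sub["snp_id"])
        for _, sub in layout.snps.groupby("block", sort=True)
    ]
    sizes = {len(b) for b in ids}
    if len(sizes) != 1:
        raise ValueError("layout blocks must share one size")
    return simulate_ld_blocks(len(ids), sizes.pop(), rho, snp_ids=ids, structure=structure)


def make_truth(
    layout: GenomeLayout,
    causal_genes,
    planted_h2: float | None = None,
    sqrt_n_beta: float | None = None,
    n: int | None = None,
    causal_sets=(),
    seed: int = 0,
) -> SyntheticTruth:
    """Spread a planted signal evenly over the SNPs of the causal genes.

    Either ``planted_h2`` (total variance explained, split equally) or
    ``sqrt_n_beta`` with ``n`` (a per-causal-SNP non-centrality) fixes
    the per-SNP standardized effect.
    """
    snps = layout.snps_of_genes(causal_genes)
    if not snps:
        return SyntheticTruth(list(causal_sets), {}, 0.0, seed=seed)
    if sqrt_n_beta is not None:
        if n is None:
            raise ValueError("sqrt_n_beta requires n")
        beta = sqrt_n_beta / np.sqrt(n)
    elif planted_h2 is not None:
        beta = float(np.sqrt(planted_h2 / len(snps)))
    else:
        raise ValueError("provide planted_h2 or sqrt_n_beta")
    causal = {s: beta for s in snps}
    return SyntheticTruth(
        list(causal_sets), causal, float(beta * beta * len(snps)), seed=seed
    )


def simulate_gwas(
    layout: GenomeLayout,
    ld: LdData,
    truth: SyntheticTruth,
    n: int,
    seed: int = 0,
) -> GwasTable:
    """Draw per-block z ~ MVN(sqrt(n) V beta, V) and convert to p-values."""
    rng = np.random.default_rng(seed)
    snp_order = list(layout.snps["snp_id"])
    beta = np.array([truth.causal_snps.get(s, 0.0) for s in snp_order])
    unknown = set(truth.causal_snps) - set(snp_order)
    if unknown:
        raise ValueError(f"causal SNP {sorted(unknown)[0]!r} not in layout")
    z = np.empty(len(snp_order))
    pos_of = {s: i for i, s in enumerate(snp_order)}
    covered = np.zeros(len(snp_order), dtype=bool)
    for blk in ld.blocks:
        idx = np.array([pos_of[s] for s in blk.snp_ids if s in pos_of])
        if len(idx) == 0:
            continue
        if len(idx) != len(blk.snp_ids):
            raise ValueError("LD block SNPs not all present in layout")
        V = blk.V
        mean = np.sqrt(n) * V @ beta[idx]
        L = np.linalg.cholesky(V + 1e-12 * np.eye(len(idx)))
        z[idx] = mean + L @ rng.standard_normal(len(idx))
        covered[idx] = True
    if not covered.all():
        free = ~covered
        z[free] = np.sqrt(n) * beta[free] + rng.standard_normal(int(free.sum()))
    p = 2.0 * stats.norm.sf(np.abs(z))
    maf = rng.uniform(0.05, 0.5, size=len(snp_order))
    df = pd.DataFrame(
        {
            "snp_id": snp_order,
            "chrom": layout.snps["chrom"].to_numpy(),
            "pos": layout.snps["pos"].to_numpy(),
            "p": p,
            "z": z,
            "n": n,
            "maf": maf,
        }
    )
    return GwasTable(df)


def simulate_gene_sets(
    n_sets: int,
    size_range: tuple[int, int],
    universe,
    overlap_spec=None,
    seed: int = 0,
    source: str = "pathway",
) -> GeneSetCollection:
    """Random gene sets, optionally with pairs of controlled overlap.

    ``overlap_spec`` is a list of (set_id_a, set_id_b, coeff) asking for
    |A ∩ B| = round(coeff * min(|A|, |B|)) between two of the generated
    sets; sizes are drawn uniformly from ``size_range`` (inclusive,
    minimum 10 to respect the module-size filter).
    """
    lo, hi = size_range
    if lo < 10:
        raise ValueError("set sizes must be >= 10")
    rng = np.random.default_rng(seed)
    universe = np.array(sorted(set(universe)))
    sets: dict[str, GeneSet] = {}
    for k in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        if size > len(universe):
            raise ValueError("set size exceeds universe")
        genes = frozenset(rng.choice(universe, size=size, replace=False))
        sets[f"S{k:04d}"] = GeneSet(f"random set {k}", genes, source)
    for (sa, sb, coeff) in overlap_spec or []:
        if sa not in sets or sb not in sets:
            raise ValueError(f"overlap_spec names unknown set {sa!r}/{sb!r}")
        A = sorted(sets[sa].genes)
        k_target = round(coeff * min(len(A), len(sets[sb].genes)))
        size_b = len(sets[sb].genes)
        if k_target > size_b or size_b - k_target > len(universe) - len(A):
            raise ValueError("requested overlap impossible for these sizes")
        shared = rng.choice(np.array(A), size=k_target, replace=False)
        rest_pool = np.array(sorted(set(universe) - set(A)))
        rest = rng.choice(rest_pool, size=size_b - k_target, replace=False)
        sets[sb] = GeneSet(sets[sb].description, frozenset(shared) | frozenset(rest), source)
    return GeneSetCollection(sets)


def simulate_eqtl_table(
    layout: GenomeLayout,
    tissues=("adipose", "liver", "blood"),
    frac_esnp: float = 0.3,
    frac_trans: float = 0.1,
    seed: int = 0,
) -> EqtlTable:
    """Multi-tissue eQTL records over the layout's SNPs.

    A fraction of SNPs are eSNPs per tissue; most target their own gene
    (cis), a fraction a random distant gene (trans).  FDR values are
    drawn so that roughly half the records pass the 5% cutoff.
    """
    rng = np.random.default_rng(seed)
    rows = []
    gid = layout.genes["gene_id"].to_numpy()
    for tissue in tissues:
        mask = rng.random(len(layout.snps)) < frac_esnp
        for s, b in zip(layout.snps.loc[mask, "snp_id"], layout.snps.loc[mask, "block"]):
            if rng.random() < frac_trans:
                g = gid[int(rng.integers(len(gid)))]
                cis = False
            else:
                g = gid[b]
                cis = True
            p = 10.0 ** (-rng.uniform(3, 12))
            rows.append(
                {
                    "snp_id": s,
                    "gene_id": g,
                    "tissue": tissue,
                    "p": p,
                    "fdr": min(p * rng.uniform(10, 1e4), 1.0),
                    "cis_flag": cis,
                }
            )
    return EqtlTable(pd.DataFrame(rows))


def simulate_network_with_kds(
    n_nodes: int,
    attachment_m: int,
    planted_kds: int,
    disease_set_size: int | None,
    enrich_pi: float,
    seed: int = 0,
    name: str = "synthetic",
    node_prefix: str = "G",
    base_rate: float | None = None,
) -> tuple[GeneNetwork, set[str], SyntheticTruth]:
    """Preferential-attachment network with planted disease-enriched hubs.

    The ``planted_kds`` highest-degree nodes become key drivers: their
    neighbors enter the disease set with probability ``enrich_pi``,
    remaining disease genes are drawn from the background so the total
    matches ``disease_set_size``.  Instead of a fixed total, a
    ``base_rate`` may be given (with ``disease_set_size=None``): the
    background rate is then ``base_rate`` and the total follows, so
    ``enrich_pi / base_rate`` is the planted fold-enrichment.
    ``enrich_pi`` equal to the base rate yields a null network.
    """
    if not 0.0 < enrich_pi <= 1.0:
        raise ValueError("enrich_pi must lie in (0, 1]")
    if (disease_set_size is None) == (base_rate is None):
        raise ValueError("give exactly one of disease_set_size and base_rate")
    if disease_set_size is not None and disease_set_size > n_nodes:
        raise ValueError("disease_set_size exceeds number of nodes")
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n_nodes, attachment_m, seed=int(rng.integers(2**31)))
    mapping = {i: f"{node_prefix}{i:05d}" for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)
    net = GeneNetwork(g, name)
    by_degree = sorted(g.degree, key=lambda t: (-t[1], t[0]))
    kds = [n_ for n_, _ in by_degree[:planted_kds]]
    neighbor_pool = sorted(set().union(*(set(g.neighbors(k)) for k in kds)) - set(kds)) if kds else []
    if disease_set_size is None:
        disease_set_size = round(enrich_pi * len(neighbor_pool)) + round(
            base_rate * (n_nodes - len(neighbor_pool) - len(kds))
        )
    n_from_nb = round(enrich_pi * len(neighbor_pool))
    if n_from_nb > disease_set_size:
        raise ValueError(
            f"enrich_pi={enrich_pi} needs {n_from_nb} disease genes in the KD "
            f"neighborhoods but disease_set_size is only {disease_set_size}"
        )
    disease = set(rng.choice(np.array(neighbor_pool), size=n_from_nb, replace=False)) if n_from_nb else set()
    background = np.array(sorted(set(g.nodes) - set(neighbor_pool) - set(kds)))
    n_bg = disease_set_size - len(disease)
    if n_bg > len(background):
        raise ValueError("disease_set_size too large for the background pool")
    if n_bg > 0:
        disease |= set(rng.choice(background, size=n_bg, replace=False))
    truth = SyntheticTruth(planted_kds=kds, seed=seed)
    return net, disease, truth


def write_two_trait_bundle(
    out_dir,
    n_genes: int = 300,
    snps_per_gene: int = 4,
    rho: float = 0.3,
    n_sets: int = 40,
    set_size_range: tuple[int, int] = (10, 15),
    sqrt_n_beta: float = 4.0,
    n: int = 20_000,
    n_perm: dict | None = None,
    seed: int = 0,
) -> str:
    """Write a complete synthetic two-trait pipeline input bundle.

    Both traits carry the same planted causal gene set (independent GWAS
    noise), so the planted set should appear in the shared-set table; a
    scale-free gene network is augmented so one hub's neighborhood
    contains the planted genes, making it the planted key driver.
    Returns the path of the generated YAML configuration.
    """
    import os

    from . import io as gio

    os.makedirs(out_dir, exist_ok=True)
    layout = simulate_genome(n_genes=n_genes, snps_per_gene=snps_per_gene)
    ld = layout_ld(layout, rho=rho)
    sets = simulate_gene_sets(n_sets, set_size_range, layout.gene_ids, seed=seed)
    planted_set = sets.ids()[0]
    planted_genes = sorted(sets.genes(planted_set))
    truth = make_truth(
        layout, planted_genes, sqrt_n_beta=sqrt_n_beta, n=n,
        causal_sets=[planted_set], seed=seed,
    )
    for t_i, trait in enumerate(("SBP", "DBP")):
        gwas = simulate_gwas(layout, ld, truth, n=n, seed=seed * 1_000 + t_i)
        gio.write_gwas_summary(gwas, os.path.join(out_dir, f"gwas_{trait}.tsv"))
    layout.genes.to_csv(os.path.join(out_dir, "genes.tsv"), sep="\t", index=False)
    gio.write_gene_sets_gmt(sets, os.path.join(out_dir, "gene_sets.gmt"))
    gio.write_ld_blocks(
        ld, os.path.join(out_dir, "ld_matrix.txt"), os.path.join(out_dir, "ld_snps.txt")
    )
    eqtls = simulate_eqtl_table(layout, seed=seed + 17)
    eqtls.df.to_csv(os.path.join(out_dir, "eqtl.tsv"), sep="\t", index=False)
    rng = np.random.default_rng(seed + 29)
    g = nx.barabasi_albert_graph(n_genes, 3, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, dict(enumerate(layout.gene_ids)))
    hub = max(g.degree, key=lambda t: (t[1], t[0]))[0]
    g.add_edges_from((hub, gene) for gene in planted_genes if gene != hub)
    gio.write_network_edges(GeneNetwork(g, "tissue1"), os.path.join(out_dir, "network_tissue1.tsv"))
    truth.planted_kds = [hub]
    truth.to_json(os.path.join(out_dir, "truth.json"))
    essential = sorted(set(planted_genes[:5]) | {hub} | set(layout.gene_ids[-20:]))
    with open(os.path.join(out_dir, "essential_genes.txt"), "w") as fh:
        fh.write("\n".join(essential) + "\n")
    cfg = {
        "seed": seed,
        "n": n,
        "output_dir": "out",
        "traits": {"SBP": "gwas_SBP.tsv", "DBP": "gwas_DBP.tsv"},
        "gene_annotation": "genes.tsv",
        "gene_sets": "gene_sets.gmt",
        "eqtl": "eqtl.tsv",
        "essential_genes": "essential_genes.txt",
        "networks": {"tissue1": "network_tissue1.tsv"},
        "ld": {"matrix": "ld_matrix.txt", "snplist": "ld_snps.txt"},
        "n_perm": n_perm or {"msea": 300, "kda": 500, "h2": 200},
    }
    cfg_path = os.path.join(out_dir, "config.yaml")
    gio.write_config(cfg, cfg_path)
    return cfg_path
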