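"""SNP-to-gene mapping and LD pruning.

SNPs are tied to genes either by chromosomal proximity (within a window
of the gene body, 50 kb by default) or through eQTL evidence (an eSNP is
mapped to the gene whose expression it associates with, at FDR < 5% for
"significant" sets or P < 1e-5 for "suggestive" sets).  Mappings from
different sources combine by union.  Before enrichment testing, mapped
SNPs are pruned so that no retained pair exceeds an r^2 cutoff,
preferentially keeping the SNP with the stronger association.

Boundary conventions (documented, configurable): MAF removal is strict
(< maf_min); eQTL FDR/p cutoffs are strict (<); the distance window is
inclusive at exactly ``window_bp``.  Coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io import FormatError, GwasTable, LdData

logger = logging.getLogger(__name__)

__all__ = [
    "SnpGeneMap",
    "EqtlTable",
    "read_eqtl_table",
    "read_gene_annotation",
    "read_snp_gene_map",
    "write_snp_gene_map",
    "filter_snps_by_maf",
    "map_by_distance",
    "map_by_eqtl",
    "combine_mappings",
    "ld_prune",
]


@dataclass
class SnpGeneMap:
    """Many-to-many SNP->gene links annotated with mapping source.

    ``links`` maps (snp_id, gene_id) to a frozenset of source tags
    (``distance``, ``eqtl:<tissue>``, or arbitrary external names).
    """

    links: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.links)

    @property
    def snp_ids(self) -> set[str]:
        return {s for s, _ in self.links}

    @property
    def gene_ids(self) -> set[str]:
        return {g for _, g in self.links}

    def genes_to_snps(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for (s, g) in self.links:
            out.setdefault(g, []).append(s)
        return {g: sorted(ss) for g, ss in out.items()}

    def snps_for_genes(self, genes) -> set[str]:
        genes = set(genes)
        return {s for (s, g) in self.links if g in genes}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"snp_id": s, "gene_id": g, "sources": ",".join(sorted(src))}
            for (s, g), src in sorted(self.links.items())
        ]
        return pd.DataFrame(rows, columns=["snp_id", "gene_id", "sources"])


@dataclass
class EqtlTable:
    """eQTL records: (snp_id, gene_id, tissue, p, optional fdr, cis flag)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("snp_id", "gene_id", "tissue", "p"):
            if col not in self.df.columns:
                raise FormatError(f"eQTL table missing column {col!r}")
        p = self.df["p"].astype(float)
        if ((p <= 0) | (p > 1)).any():
            raise FormatError("eQTL p-values must lie in (0, 1]")


def read_eqtl_table(path) -> EqtlTable:
    df = pd.read_csv(path, sep="\t")
    return EqtlTable(df)


def read_gene_annotation(path) -> pd.DataFrame:
    """Gene annotation TSV: gene_id, chrom, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "chrom", "start", "end"):
        if col not in df.columns:
            raise FormatError(f"gene annotation missing column {col!r}")
    df["chrom"] = df["chrom"].astype(str)
    if (df["start"] > df["end"]).any():
        bad = df.loc[df["start"] > df["end"], "gene_id"].iloc[0]
        raise FormatError(f"gene {bad!r} has start > end")
    return df


def read_snp_gene_map(path, source: str | None = None) -> SnpGeneMap:
    """Read a mapping TSV (snp_id, gene_id[, sources comma-joined]).

    Externally supplied mappings (e.g. regulatory-annotation based) load
    through here and combine like any other map.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("snp_id", "gene_id"):
        if col not in df.columns:
            raise FormatError(f"mapping file missing column {col!r}")
    links: dict[tuple[str, str], frozenset[str]] = {}
    for row in df.itertuples(index=False):
        key = (str(row.snp_id), str(row.gene_id))
        if "sources" in df.columns and isinstance(getattr(row, "sources", None), str):
            src = frozenset(row.sources.split(","))
        else:
            src = frozenset([source or "external"])
        links[key] = links.get(key, frozenset()) | src
    return SnpGeneMap(links, provenance=[source or "external"])


def write_snp_gene_map(m: SnpGeneMap, path) -> None:
    m.to_frame().to_csv(path, sep="\t", index=False)


def filter_snps_by_maf(gwas: GwasTable, maf_min: float = 0.01) -> GwasTable:
    """Remove SNPs with minor allele frequency strictly below ``maf_min``.

    If the table carries no maf column the input is returned unchanged
    with a warning (the filter cannot apply).
    """
    if not 0 < maf_min <= 0.5:
        raise ValueError(f"maf_min must lie in (0, 0.5], got {maf_min}")
    if "maf" not in gwas.df.columns:
        logger.warning("GWAS table has no maf column; MAF filter skipped")
        return gwas
    keep = gwas.df["maf"] >= maf_min
    logger.info("MAF filter removed %d of %d SNPs", int((~keep).sum()), len(gwas))
    return GwasTable(gwas.df.loc[keep].reset_index(drop=True))


def map_by_distance(gwas: GwasTable, genes: pd.DataFrame, window_bp: int = 50_000) -> SnpGeneMap:
    """Map each SNP to every gene whose body +/- ``window_bp`` contains it.

    ``genes`` is a DataFrame with columns gene_id, chrom, start, end,
    1-based inclusive; the window is inclusive at exactly ``window_bp``.
    """
    if (genes["start"] > genes["end"]).any():
        bad = genes.loc[genes["start"] > genes["end"], "gene_id"].iloc[0]
        raise FormatError(f"gene {bad!r} has start > end")
    links: dict[tuple[str, str], frozenset[str]] = {}
    src = frozenset(["distance"])
    by_chrom = {c: sub for c, sub in genes.groupby(genes["chrom"].astype(str))}
    for chrom, snps in gwas.df.groupby("chrom"):
        sub = by_chrom.get(str(chrom))
        if sub is None:
            continue
        starts = sub["start"].to_numpy() - window_bp
        ends = sub["end"].to_numpy() + window_bp
        gids = sub["gene_id"].to_numpy()
        for snp_id, pos in zip(snps["snp_id"], snps["pos"]):
            hit = (starts <= pos) & (pos <= ends)
            for g in gids[hit]:
                links[(snp_id, str(g))] = src
    return SnpGeneMap(links, provenance=["distance"])


def map_by_eqtl(
    eqtls: EqtlTable,
    mode: str = "significant",
    fdr_max: float = 0.05,
    p_max: float = 1e-5,
    tissues=None,
) -> SnpGeneMap:
    """Map eSNPs to their target genes.

    ``significant`` mode keeps records with fdr < ``fdr_max`` (requires an
    fdr column); ``suggestive`` keeps records with p < ``p_max``.  Both
    cis and trans eSNPs are retained; sources are tagged ``eqtl:<tissue>``.
    """
    df = eqtls.df
    if tissues is not None:
        df = df[df["tissue"].isin(set(tissues))]
    if mode == "significant":
        if "fdr" not in df.columns:
            raise ValueError("significant mode requires an fdr column")
        df = df[df["fdr"].astype(float) < fdr_max]
    elif mode == "suggestive":
        df = df[df["p"].astype(float) < p_max]
    else:
        raise ValueError(f"unknown eQTL mode {mode!r}")
    links: dict[tuple[str, str], frozenset[str]] = {}
    for row in df.itertuples(index=False):
        key = (str(row.snp_id), str(row.gene_id))
        links[key] = links.get(key, frozenset()) | frozenset([f"eqtl:{row.tissue}"])
    tissues_seen = sorted({t for src in links.values() for t in src})
    return SnpGeneMap(links, provenance=tissues_seen or ["eqtl"])


def combine_mappings(maps: list[SnpGeneMap]) -> SnpGeneMap:
    """Union of mappings; (snp, gene) pairs deduplicate, sources accumulate."""
    if not maps:
        raise ValueError("combine_mappings requires at least one map")
    links: dict[tuple[str, str], frozenset[str]] = {}
    prov: list[str] = []
    for m in maps:
        for key, src in m.links.items():
            links[key] = links.get(key, frozenset()) | src
        for p in m.provenance:
            if p not in prov:
                prov.append(p)
    return SnpGeneMap(links, provenance=prov)


def ld_prune(gwas: GwasTable, snps, ld: LdData, r2_max: float = 0.7) -> set[str]:
    """Greedy LD pruning preferring strong associations.

    SNPs are visited in ascending p (ties broken lexicographically by
    snp_id); a SNP is kept iff its r^2 against every already-kept SNP is
    below ``r2_max``.  The smallest-p SNP is therefore always retained,
    and the result is independent of the input ordering.
    """
    snps = set(snps)
    pmap = dict(zip(gwas.df["snp_id"], gwas.df["p"]))
    missing = snps - pmap.keys()
    if missing:
        raise ValueError(f"SNP {sorted(missing)[0]!r} not present in GWAS table")
    order = sorted(snps, key=lambda s: (pmap[s], s))
    kept: set[str] = set()
    for s in order:
        ok = True
        for other, r2 in ld.correlated_with(s):
            if other in kept and r2 >= r2_max:
                ok = False
                break
        if ok:
            kept.add(s)
    return kept
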