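"""Readers and writers for the external file formats.

Every downstream stage consumes only the in-memory types defined here:
:class:`GwasTable`, :class:`GeneSetCollection`, :class:`GeneNetwork`,
:class:`LdData` and the run configuration.  Formats are plain text: TSV
for GWAS summary statistics, eQTL records, LD pairs and network edge
lists; Broad-dialect GMT for gene sets; a SNP-list file plus a
whitespace-delimited dense matrix for per-block LD; YAML for run
configuration.

Gene and SNP identifiers are opaque, case-sensitive strings; no
symbol/alias resolution is performed.  Unknown extra columns in TSV
inputs are ignored so real-world exports load unchanged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "GwasTable",
    "GeneSet",
    "GeneSetCollection",
    "GeneNetwork",
    "LdBlock",
    "LdData",
    "read_gwas_summary",
    "write_gwas_summary",
    "read_gene_sets_gmt",
    "write_gene_sets_gmt",
    "read_network_edges",
    "write_network_edges",
    "read_ld",
    "write_ld_pairs",
    "write_ld_blocks",
    "read_config",
    "write_config",
]


class FormatError(ValueError):
    """A malformed input file; the message locates the offending field/line."""


# smallest positive normal double; p = 0 entries are floored here rather than
# rejected so that extreme meta-analysis signals keep their rank
_P_FLOOR = float(np.finfo(float).tiny)


@dataclass
class GwasTable:
    """Per-SNP association records: the full spectrum of GWAS statistics.

    ``df`` holds columns ``snp_id, chrom, pos, p`` and optionally
    ``z, n, maf``.  Invariants: unique snp_id, p in (0, 1], pos >= 1.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        required = ["snp_id", "chrom", "pos", "p"]
        for col in required:
            if col not in df.columns:
                raise FormatError(f"GWAS table missing required column {col!r}")
        if df["snp_id"].duplicated().any():
            dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise FormatError(f"duplicate snp_id {dup!r} in GWAS table")
        df = df.copy()
        df["pos"] = df["pos"].astype(np.int64)
        if (df["pos"] < 1).any():
            raise FormatError("GWAS table positions must be >= 1 (1-based bp)")
        df["p"] = df["p"].astype(float)
        n_zero = int((df["p"] == 0).sum())
        if n_zero:
            logger.warning("floored %d p=0 rows to %.3e", n_zero, _P_FLOOR)
            df.loc[df["p"] == 0, "p"] = _P_FLOOR
        bad = (df["p"] < 0) | (df["p"] > 1) | ~np.isfinite(df["p"])
        if bad.any():
            logger.warning("rejected %d rows with p outside (0,1]", int(bad.sum()))
            df = df.loc[~bad]
        if "z" in df.columns and df["z"].notna().any():
            mask = df["z"].notna() & (df["p"] < 1)
            p_from_z = 2.0 * stats.norm.sf(np.abs(df.loc[mask, "z"]))
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.abs(p_from_z - df.loc[mask, "p"]) / df.loc[mask, "p"]
            n_bad = int((rel > 0.10).sum())
            if n_bad:
                logger.warning(
                    "%d rows have p inconsistent with 2*(1-Phi(|z|)) beyond 10%%",
                    n_bad,
                )
        if "maf" in df.columns:
            maf = df["maf"].dropna()
            if ((maf < 0) | (maf > 0.5)).any():
                raise FormatError("maf values must lie in [0, 0.5]")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> set[str]:
        return set(self.df["snp_id"])

    def neglog10p(self) -> pd.Series:
        return -np.log10(self.df["p"])

    def zscores(self) -> pd.Series:
        """Per-SNP |z|, from the z column when present, else from p.

        Only z**2 enters the heritability estimator, so the sign is
        irrelevant and two-sided p-values invert cleanly.
        """
        if "z" in self.df.columns and self.df["z"].notna().all():
            return self.df["z"].abs()
        return pd.Series(stats.norm.isf(self.df["p"] / 2.0), index=self.df.index)


@dataclass(frozen=True)
class GeneSet:
    description: str
    genes: frozenset[str]
    source: str = "pathway"  # pathway | coexpression_module | positive_control | superset


@dataclass
class GeneSetCollection:
    """Named gene sets with provenance; set ids unique, no empty sets."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, s in self.sets.items():
            if not s.genes:
                raise FormatError(f"gene set {sid!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    def ids(self) -> list[str]:
        return list(self.sets)

    def genes(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id].genes

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s.genes
        return out

    def filter_min_size(self, min_size: int) -> "GeneSetCollection":
        kept = {}
        for sid, s in self.sets.items():
            if len(s.genes) >= min_size:
                kept[sid] = s
            else:
                logger.info("dropped set %s (%d genes < min_size %d)", sid, len(s.genes), min_size)
        return GeneSetCollection(kept)

    def subset(self, set_ids) -> "GeneSetCollection":
        return GeneSetCollection({sid: self.sets[sid] for sid in set_ids})


@dataclass
class GeneNetwork:
    """Gene-gene interaction graph for one tissue (or a PPI network).

    Directed inputs are accepted but neighborhoods treat edges as
    undirected; self-loops are removed at load time.
    """

    graph: nx.Graph
    name: str = "network"

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            logger.info("removed %d self-loops from network %s", len(loops), self.name)
            self.graph.remove_edges_from(loops)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class LdBlock:
    snp_ids: list[str]
    V: np.ndarray  # pairwise correlation r, unit diagonal, symmetric PSD

    def __post_init__(self) -> None:
        V = np.asarray(self.V, dtype=float)
        if V.shape != (len(self.snp_ids), len(self.snp_ids)):
            raise FormatError("LD block matrix shape does not match SNP list")
        if not np.allclose(V, V.T, atol=1e-8):
            raise FormatError("LD block matrix is not symmetric within 1e-8")
        if not np.allclose(np.diag(V), 1.0, atol=1e-6):
            raise FormatError("LD block matrix diagonal must be 1")
        self.V = 0.5 * (V + V.T)


class LdData:
    """Pairwise r^2 records and/or per-block LD correlation matrices.

    Unlisted pairs have r^2 = 0.  Each SNP belongs to at most one block.
    """

    def __init__(self, pairs=None, blocks: list[LdBlock] | None = None):
        self._pairs: dict[tuple[str, str], float] = {}
        self._adj: dict[str, dict[str, float]] = {}
        self.blocks: list[LdBlock] = list(blocks or [])
        self._snp_block: dict[str, tuple[int, int]] = {}
        for bi, blk in enumerate(self.blocks):
            for i, sid in enumerate(blk.snp_ids):
                if sid in self._snp_block:
                    raise FormatError(f"SNP {sid!r} appears in more than one LD block")
                self._snp_block[sid] = (bi, i)
        for s1, s2, r2 in pairs or []:
            self.add_pair(s1, s2, r2)

    def add_pair(self, s1: str, s2: str, r2: float) -> None:
        r2 = float(r2)
        if not 0.0 <= r2 <= 1.0:
            raise FormatError(f"r^2 value {r2} outside [0, 1] for pair ({s1}, {s2})")
        key = (s1, s2) if s1 <= s2 else (s2, s1)
        self._pairs[key] = r2
        self._adj.setdefault(s1, {})[s2] = r2
        self._adj.setdefault(s2, {})[s1] = r2

    @property
    def pairs(self) -> dict[tuple[str, str], float]:
        return dict(self._pairs)

    def r2(self, s1: str, s2: str) -> float:
        if s1 == s2:
            return 1.0
        b1 = self._snp_block.get(s1)
        b2 = self._snp_block.get(s2)
        if b1 is not None and b2 is not None and b1[0] == b2[0]:
            return float(self.blocks[b1[0]].V[b1[1], b2[1]] ** 2)
        key = (s1, s2) if s1 <= s2 else (s2, s1)
        return self._pairs.get(key, 0.0)

    def correlated_with(self, snp: str):
        """Yield (other_snp, r2) over SNPs with potentially nonzero r2."""
        loc = self._snp_block.get(snp)
        if loc is not None:
            bi, i = loc
            blk = self.blocks[bi]
            for j, other in enumerate(blk.snp_ids):
                if j != i:
                    yield other, float(blk.V[i, j] ** 2)
        for other, r2 in self._adj.get(snp, {}).items():
            yield other, r2

    def block_of(self, snp: str) -> int | None:
        loc = self._snp_block.get(snp)
        return None if loc is None else loc[0]


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    return df


def read_gwas_summary(path, column_spec: dict[str, str] | None = None) -> GwasTable:
    """Read tab-delimited GWAS summary statistics.

    ``column_spec`` maps canonical names (snp_id, chrom, pos, p, z, n, maf)
    to the file's column headers; identity by default.
    """
    df = _read_tsv(path)
    spec = dict(column_spec or {})
    rename = {}
    for canon in ("snp_id", "chrom", "pos", "p", "z", "n", "maf"):
        src = spec.get(canon, canon)
        if src in df.columns:
            rename[src] = canon
        elif canon in ("snp_id", "chrom", "pos", "p"):
            raise FormatError(f"{path}: missing required column {src!r} ({canon})")
    df = df.rename(columns=rename)
    keep = [c for c in ("snp_id", "chrom", "pos", "p", "z", "n", "maf") if c in df.columns]
    df = df[keep]
    df["chrom"] = df["chrom"].astype(str)
    df["snp_id"] = df["snp_id"].astype(str)
    return GwasTable(df)


def write_gwas_summary(gwas: GwasTable, path) -> None:
    gwas.df.to_csv(path, sep="\t", index=False)


def read_gene_sets_gmt(path, min_size: int = 10, source: str = "pathway") -> GeneSetCollection:
    """Read a Broad-dialect GMT file: set_id <tab> description <tab> genes...

    Sets with fewer than ``min_size`` genes (after within-line
    deduplication) are dropped and logged; a duplicate set id or a line
    with fewer than three fields is a format error.
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            sid, desc = fields[0], fields[1]
            if sid in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set id {sid!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if len(genes) < min_size:
                logger.info("dropped set %s (%d genes < %d)", sid, len(genes), min_size)
                continue
            sets[sid] = GeneSet(desc, genes, source)
    return GeneSetCollection(sets)


def write_gene_sets_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for sid, s in collection.sets.items():
            fh.write("\t".join([sid, s.description, *sorted(s.genes)]) + "\n")


def read_network_edges(path, name: str | None = None) -> GeneNetwork:
    """Read a 2-or-3-column tab-delimited edge list.

    The optional third column is an edge weight; direction is ignored.
    Duplicate edges collapse; self-loops are dropped with a count logged.
    """
    g = nx.Graph()
    n_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: edge line has fewer than 2 columns")
            a, b = fields[0], fields[1]
            if a == b:
                n_loops += 1
                continue
            if len(fields) >= 3 and fields[2]:
                try:
                    g.add_edge(a, b, weight=float(fields[2]))
                except ValueError:
                    g.add_edge(a, b)
            else:
                g.add_edge(a, b)
    if n_loops:
        logger.info("dropped %d self-loop edges from %s", n_loops, path)
    import os

    return GeneNetwork(g, name or os.path.splitext(os.path.basename(str(path)))[0])


def write_network_edges(net: GeneNetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b, data in net.graph.edges(data=True):
            if "weight" in data:
                fh.write(f"{a}\t{b}\t{data['weight']}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def read_ld(path, mode: str = "pairs", snplist_path=None) -> LdData:
    """Read LD as 3-column r^2 pairs or as block SNP-list + dense matrix.

    ``pairs`` mode: TSV of (snp1, snp2, r2).  ``blocks`` mode: ``path`` is
    a whitespace-delimited dense correlation matrix and ``snplist_path``
    lists SNP ids, one per line, with blank lines separating blocks; a
    single file may carry several stacked square matrices.
    """
    if mode == "pairs":
        pairs = []
        with open(path) as fh:
            header = fh.readline()
            for lineno, line in enumerate(fh, 2):
                line = line.strip()
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise FormatError(f"{path}:{lineno}: expected snp1, snp2, r2")
                try:
                    r2 = float(fields[2])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: r2 not numeric") from None
                if not 0.0 <= r2 <= 1.0:
                    raise FormatError(f"{path}:{lineno}: r2 {r2} outside [0,1]")
                pairs.append((fields[0], fields[1], r2))
        return LdData(pairs=pairs)
    if mode == "blocks":
        if snplist_path is None:
            raise FormatError("blocks mode requires snplist_path")
        block_ids: list[list[str]] = [[]]
        with open(snplist_path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    if block_ids[-1]:
                        block_ids.append([])
                else:
                    block_ids[-1].append(line)
        if not block_ids[-1]:
            block_ids.pop()
        values = np.loadtxt(path, ndmin=2)
        blocks = []
        row = 0
        for ids in block_ids:
            k = len(ids)
            V = values[row : row + k, :k]
            row += k
            blocks.append(LdBlock(ids, V))
        if row != values.shape[0]:
            raise FormatError(f"{path}: matrix rows ({values.shape[0]}) do not match SNP lists ({row})")
        return LdData(blocks=blocks)
    raise ValueError(f"unknown LD mode {mode!r}")


def write_ld_pairs(ld: LdData, path) -> None:
    with open(path, "w") as fh:
        fh.write("snp1\tsnp2\tr2\n")
        for (s1, s2), r2 in sorted(ld.pairs.items()):
            fh.write(f"{s1}\t{s2}\t{r2:.10g}\n")


def write_ld_blocks(ld: LdData, matrix_path, snplist_path) -> None:
    width = max((len(b.snp_ids) for b in ld.blocks), default=0)
    with open(snplist_path, "w") as fh:
        for blk in ld.blocks:
            for sid in blk.snp_ids:
                fh.write(sid + "\n")
            fh.write("\n")
    with open(matrix_path, "w") as fh:
        for blk in ld.blocks:
            k = len(blk.snp_ids)
            for i in range(k):
                row = [f"{blk.V[i, j]:.10g}" for j in range(k)]
                row += ["0"] * (width - k)
                fh.write(" ".join(row) + "\n")


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: configuration must be a YAML mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
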