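"""Marker Set Enrichment Analysis (MSEA).

MSEA asks whether the SNPs (markers) mapped to a gene set carry stronger
GWAS association signal than the background of all mapped markers, using
the full spectrum of association statistics rather than only top hits.

The enrichment statistic is chi-square-like across a ladder of quantile
thresholds.  For threshold j, let the cutoff be the (1 - q_j) quantile of
the background -log10 p distribution, O_j the number of set markers at or
above the cutoff, and E_j = m_set * f_j the expected count, with f_j the
background fraction at or above the cutoff.  Then

    Q = sum_j (O_j - E_j) / sqrt(E_j + kappa)

with kappa a variance-stabilising shift (default 1).  The null is built
by drawing random gene sets of matched gene count from the mapped-gene
universe — each sampled gene keeps its real marker list, so gene-size
bias enters the null exactly as it enters the observed statistic — and
the one-sided upper-tail p-value comes from a Gaussian fitted to the
permuted statistics.  Benjamini-Hochberg FDR is applied across all sets
tested.

The model surface follows the fit/results convention: build an
:class:`MSEA` from the data, call :meth:`MSEA.fit`, inspect the returned
:class:`MSEAResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection, GwasTable, LdData
from .mapping import SnpGeneMap, ld_prune

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_QUANTILES",
    "MarkerAssignment",
    "build_marker_assignment",
    "msea_statistic",
    "msea_null",
    "msea_pvalue",
    "bh_fdr",
    "MSEA",
    "MSEAResults",
    "run_msea",
    "flag_shared_across_mappings",
]

#: Quantile ladder: thresholds at the background 50th/75th/90th/95th/99th
#: percentiles of -log10 p.
DEFAULT_QUANTILES: tuple[float, ...] = (0.50, 0.25, 0.10, 0.05, 0.01)


@dataclass
class MarkerAssignment:
    """Background markers, per-gene marker lists, and derived cutoffs.

    ``marker_ids``/``neglogp`` describe the post-pruning background;
    ``gene_markers`` maps each gene in the universe to indices into the
    background arrays.  Genes with zero surviving markers are excluded
    from the universe.
    """

    marker_ids: np.ndarray
    neglogp: np.ndarray
    gene_markers: dict[str, np.ndarray]
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES
    cutoffs: np.ndarray = field(init=False)
    bg_fraction: np.ndarray = field(init=False)
    _tier: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        q = np.asarray(self.quantiles, dtype=float)
        if np.any(q <= 0) or np.any(q >= 1) or np.any(np.diff(q) >= 0):
            raise ValueError("quantiles must be strictly decreasing proportions in (0,1)")
        self.neglogp = np.asarray(self.neglogp, dtype=float)
        self.cutoffs = np.quantile(self.neglogp, 1.0 - q)
        m = float(len(self.neglogp))
        self.bg_fraction = np.array(
            [(self.neglogp >= c).sum() / m for c in self.cutoffs]
        )
        # tier[i] = number of (ascending) cutoffs marker i reaches
        self._tier = np.searchsorted(self.cutoffs, self.neglogp, side="right").astype(np.int64)
        self.gene_markers = {
            g: np.asarray(idx, dtype=np.int64)
            for g, idx in self.gene_markers.items()
            if len(idx) > 0
        }

    @property
    def universe(self) -> list[str]:
        return list(self.gene_markers)

    @property
    def n_background(self) -> int:
        return len(self.neglogp)

    def marker_indices(self, genes) -> np.ndarray:
        """Deduplicated background indices of the markers of ``genes``."""
        arrs = [self.gene_markers[g] for g in genes if g in self.gene_markers]
        if not arrs:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(arrs))

    def _q_from_indices(self, idx: np.ndarray, kappa: float) -> float:
        nthr = len(self.cutoffs)
        counts = np.bincount(self._tier[idx], minlength=nthr + 1)
        # O_j = number of markers reaching cutoff j  (tier >= j+1)
        O = counts[::-1].cumsum()[::-1][1:]
        E = len(idx) * self.bg_fraction
        return float(np.sum((O - E) / np.sqrt(E + kappa)))


def build_marker_assignment(
    gwas: GwasTable,
    snp_gene_map: SnpGeneMap,
    ld: LdData | None = None,
    r2_max: float = 0.7,
    quantiles=DEFAULT_QUANTILES,
    max_markers_per_gene: int | None = None,
) -> MarkerAssignment:
    """Prune mapped markers by LD and index them per gene.

    The background is the set of all mapped SNPs surviving the greedy
    r^2 pruning; each gene's marker list is intersected with it.  Gene
    size bias (many markers per large gene) is deliberately retained —
    the permutation null controls for it — unless a per-gene cap is
    requested.
    """
    mapped = snp_gene_map.snp_ids & gwas.snp_ids
    if not mapped:
        raise ValueError("no mapped SNP is present in the GWAS table")
    if ld is not None:
        kept = ld_prune(gwas, mapped, ld, r2_max=r2_max)
    else:
        kept = mapped
    sub = gwas.df[gwas.df["snp_id"].isin(kept)]
    marker_ids = sub["snp_id"].to_numpy()
    neglogp = -np.log10(sub["p"].to_numpy())
    index = {s: i for i, s in enumerate(marker_ids)}
    gene_markers: dict[str, list[int]] = {}
    for (s, g) in snp_gene_map.links:
        i = index.get(s)
        if i is not None:
            gene_markers.setdefault(g, []).append(i)
    arrays: dict[str, np.ndarray] = {}
    for g, idx in gene_markers.items():
        arr = np.unique(np.asarray(idx, dtype=np.int64))
        if max_markers_per_gene is not None and len(arr) > max_markers_per_gene:
            order = np.argsort(-neglogp[arr])
            arr = np.sort(arr[order[:max_markers_per_gene]])
        arrays[g] = arr
    return MarkerAssignment(marker_ids, neglogp, arrays, tuple(quantiles))


def msea_statistic(assignment: MarkerAssignment, genes, kappa: float = 1.0) -> float:
    """Observed enrichment statistic Q for the genes of one set."""
    idx = assignment.marker_indices(genes)
    if len(idx) == 0:
        raise ValueError("set has no mapped markers")
    return assignment._q_from_indices(idx, kappa)


def msea_null(
    assignment: MarkerAssignment,
    set_size_genes: int,
    n_perm: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
    kappa: float = 1.0,
) -> tuple[float, float, np.ndarray]:
    """Permutation null for a set of ``set_size_genes`` genes.

    Each permutation draws that many genes uniformly without replacement
    from the mapped-gene universe, keeps their real marker lists, and
    recomputes Q.  Returns (null_mean, null_sd, null_samples).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    universe = assignment.universe
    if set_size_genes > len(universe):
        raise ValueError(
            f"set size {set_size_genes} exceeds mapped-gene universe ({len(universe)})"
        )
    rng = np.random.default_rng(seed)
    gene_arrays = [assignment.gene_markers[g] for g in universe]
    n_genes = len(gene_arrays)
    samples = np.empty(n_perm)
    for t in range(n_perm):
        pick = rng.choice(n_genes, size=set_size_genes, replace=False)
        idx = np.unique(np.concatenate([gene_arrays[i] for i in pick]))
        samples[t] = assignment._q_from_indices(idx, kappa)
    return float(samples.mean()), float(samples.std(ddof=1)), samples


def msea_pvalue(Q: float, null_mean: float, null_sd: float) -> float:
    """One-sided upper-tail Gaussian p-value for an observed Q."""
    if null_sd <= 0:
        raise ValueError("degenerate null: null_sd must be positive")
    return float(stats.norm.sf((Q - null_mean) / null_sd))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class MSEA:
    """Marker Set Enrichment Analysis model.

    Parameters
    ----------
    gwas : GwasTable
        Full-spectrum GWAS summary statistics.
    snp_gene_map : SnpGeneMap
        SNP-to-gene links from one mapping (distance, eQTL, combined...).
    gene_sets : GeneSetCollection
        Pathways / co-expression modules to score.
    ld : LdData, optional
        Pairwise or block LD; when given, mapped markers are greedily
        pruned at ``r2_max`` before scoring.
    quantiles, kappa
        Statistic configuration (threshold ladder and stabiliser).
    min_mapped_genes : int
        Sets with fewer mapped genes are skipped (logged), default 2.
    """

    def __init__(
        self,
        gwas: GwasTable,
        snp_gene_map: SnpGeneMap,
        gene_sets: GeneSetCollection,
        ld: LdData | None = None,
        r2_max: float = 0.7,
        quantiles=DEFAULT_QUANTILES,
        kappa: float = 1.0,
        min_mapped_genes: int = 2,
        max_markers_per_gene: int | None = None,
    ) -> None:
        self.gene_sets = gene_sets
        self.kappa = float(kappa)
        self.min_mapped_genes = int(min_mapped_genes)
        self.assignment = build_marker_assignment(
            gwas,
            snp_gene_map,
            ld,
            r2_max=r2_max,
            quantiles=quantiles,
            max_markers_per_gene=max_markers_per_gene,
        )

    def fit(self, n_perm: int = 10_000, seed: int = 0) -> "MSEAResults":
        """Score every set, estimate the permutation null, adjust by BH.

        The gene-sampling null distribution depends only on the number of
        genes drawn, so permutations are shared across sets of equal
        mapped-gene count; each size receives an independent substream of
        the master ``seed``.
        """
        universe = set(self.assignment.universe)
        rows = []
        sizes_needed = set()
        per_set: dict[str, tuple[list[str], int]] = {}
        for sid in self.gene_sets.ids():
            genes = sorted(self.gene_sets.genes(sid) & universe)
            if len(genes) < self.min_mapped_genes:
                logger.info("skipped set %s: %d mapped genes", sid, len(genes))
                continue
            per_set[sid] = (genes, len(genes))
            sizes_needed.add(len(genes))
        if not per_set:
            raise ValueError("no gene set has enough mapped genes to test")
        root = np.random.SeedSequence(seed)
        nulls: dict[int, tuple[float, float]] = {}
        for size in sorted(sizes_needed):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(size,))
            mean, sd, _ = msea_null(self.assignment, size, n_perm=n_perm, seed=ss, kappa=self.kappa)
            nulls[size] = (mean, sd)
        for sid, (genes, size) in per_set.items():
            idx = self.assignment.marker_indices(genes)
            Q = self.assignment._q_from_indices(idx, self.kappa)
            mean, sd = nulls[size]
            p = msea_pvalue(Q, mean, sd)
            rows.append(
                {
                    "set_id": sid,
                    "n_genes_mapped": size,
                    "n_markers": len(idx),
                    "Q": Q,
                    "null_mean": mean,
                    "null_sd": sd,
                    "p": p,
                }
            )
        frame = pd.DataFrame(rows)
        frame["fdr"] = bh_fdr(np.clip(frame["p"].to_numpy(), 1e-300, 1.0))
        frame = frame.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)
        return MSEAResults(frame, n_perm=n_perm, seed=seed, root_seed=root)


@dataclass
class MSEAResults:
    """Per-set enrichment table with null parameters, p and BH FDR."""

    frame: pd.DataFrame
    n_perm: int
    seed: int
    root_seed: np.random.SeedSequence | None = None

    def significant_sets(self, fdr_max: float = 0.05) -> list[str]:
        return list(self.frame.loc[self.frame["fdr"] < fdr_max, "set_id"])

    def summary(self, top: int = 10) -> str:
        lines = [
            "Marker Set Enrichment Analysis",
            f"  sets tested: {len(self.frame)}   permutations: {self.n_perm}   seed: {self.seed}",
            f"  significant at FDR<0.05: {int((self.frame['fdr'] < 0.05).sum())}",
            "",
            self.frame.head(top).to_string(
                index=False,
                formatters={
                    "Q": "{:.3f}".format,
                    "null_mean": "{:.3f}".format,
                    "null_sd": "{:.3f}".format,
                    "p": "{:.3g}".format,
                    "fdr": "{:.3g}".format,
                },
            ),
        ]
        return "\n".join(lines)

    def to_tsv(self, path, fdr_max: float = 0.05) -> None:
        out = self.frame.copy()
        out["significant"] = out["fdr"] < fdr_max
        out.to_csv(path, sep="\t", index=False)


def run_msea(
    gwas: GwasTable,
    snp_gene_map: SnpGeneMap,
    gene_sets: GeneSetCollection,
    ld: LdData | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    **kwargs,
) -> MSEAResults:
    """Functional one-call wrapper around :class:`MSEA`."""
    model = MSEA(gwas, snp_gene_map, gene_sets, ld=ld, **kwargs)
    return model.fit(n_perm=n_perm, seed=seed)


def flag_shared_across_mappings(results_by_mapping: dict[str, MSEAResults], fdr_max: float = 0.05) -> set[str]:
    """Set ids significant at FDR < ``fdr_max`` in at least one mapping."""
    out: set[str] = set()
    for res in results_by_mapping.values():
        out |= set(res.significant_sets(fdr_max))
    return out
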