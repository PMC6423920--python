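"""Key Driver Analysis (KDA).

A key driver (KD) is a network node whose local neighborhood is
enriched for members of a disease gene set.  For a candidate with
neighborhood H in a network of node set N and disease genes D:

    O = |H ∩ D ∩ N|,   E = |H| · |D ∩ N| / |N|,
    statistic = (O − E) / sqrt(E + kappa)

analogous to the marker-set enrichment statistic.  Significance comes
from permuting disease labels over nodes (for this statistic that is
exactly equivalent to drawing |H|-node sets uniformly, so the default
null samples overlap counts from the hypergeometric distribution; a
literal label-permutation mode is retained for validation), a Gaussian
upper-tail p as in MSEA, and BH FDR across candidates.  The top-k
candidates by p among those under the FDR cutoff are flagged as key
drivers and their subnetworks (KD plus neighborhood) reported.

Directed networks are analyzed as undirected for neighborhood purposes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneNetwork
from .msea import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "KdSubnetwork",
    "KDAResults",
    "KeyDriverAnalysis",
    "extract_neighborhood",
    "kda_statistic",
    "kda_test",
    "essential_gene_enrichment",
]


def extract_neighborhood(net: GeneNetwork, gene: str, depth: int = 1) -> set[str]:
    """Nodes within ``depth`` edges of ``gene`` (BFS), excluding the seed."""
    if gene not in net.graph:
        raise ValueError(f"gene {gene!r} is not a node of network {net.name!r}")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    reached = nx.single_source_shortest_path_length(net.graph, gene, cutoff=depth)
    return set(reached) - {gene}


def kda_statistic(
    neighborhood: set[str], disease_genes: set[str], net_nodes: set[str], kappa: float = 1.0
) -> tuple[int, float, float]:
    """(O, E, statistic) for one candidate's neighborhood."""
    if not neighborhood:
        raise ValueError("empty neighborhood: statistic undefined")
    d_in_net = disease_genes & net_nodes
    O = len(neighborhood & d_in_net)
    E = len(neighborhood) * len(d_in_net) / len(net_nodes)
    return O, E, (O - E) / np.sqrt(E + kappa)


@dataclass
class KdSubnetwork:
    kd_gene: str
    member_genes: set[str]  # KD plus its neighborhood
    network_name: str


@dataclass
class KDAResults:
    """Per-candidate table plus subnetworks of the flagged key drivers."""

    frame: pd.DataFrame
    subnetworks: list[KdSubnetwork]
    network_name: str
    n_perm: int
    seed: int

    def top_kds(self) -> list[str]:
        return list(self.frame.loc[self.frame["is_top_kd"], "candidate_gene"])

    def summary(self, top: int = 10) -> str:
        lines = [
            f"Key Driver Analysis — network {self.network_name!r}",
            f"  candidates: {len(self.frame)}   permutations: {self.n_perm}   seed: {self.seed}",
            f"  key drivers flagged: {len(self.subnetworks)}",
            "",
            self.frame.head(top).to_string(
                index=False,
                formatters={
                    "E": "{:.2f}".format,
                    "statistic": "{:.3f}".format,
                    "p": "{:.3g}".format,
                    "fdr": "{:.3g}".format,
                },
            ),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


class KeyDriverAnalysis:
    """KDA model over one network and one disease gene set.

    Candidates default to every node whose depth-``depth`` neighborhood
    has at least ``min_neighbors`` members (leaves give degenerate
    nulls).  ``null_mode`` selects the hypergeometric resampling null
    (default, exact equivalent of label permutation) or literal label
    permutation (``"permute"``).
    """

    def __init__(
        self,
        network: GeneNetwork,
        disease_genes: set[str],
        candidates=None,
        depth: int = 1,
        min_neighbors: int = 5,
        kappa: float = 1.0,
        null_mode: str = "resample",
    ) -> None:
        if null_mode not in ("resample", "permute"):
            raise ValueError("null_mode must be 'resample' or 'permute'")
        self.network = network
        self.disease_genes = set(disease_genes)
        self.depth = int(depth)
        self.min_neighbors = int(min_neighbors)
        self.kappa = float(kappa)
        self.null_mode = null_mode
        self._neigh: dict[str, set[str]] = {}
        nodes = sorted(network.graph.nodes)
        pool = candidates if candidates is not None else nodes
        for g in pool:
            nb = extract_neighborhood(network, g, depth)
            if len(nb) >= self.min_neighbors:
                self._neigh[g] = nb
            elif candidates is not None:
                logger.info("candidate %s skipped: %d neighbors", g, len(nb))
        if not self._neigh:
            logger.warning("no eligible KDA candidate in network %s", network.name)

    def fit(
        self,
        n_perm: int = 10_000,
        seed: int = 0,
        fdr_max: float = 0.01,
        top_k: int = 5,
    ) -> KDAResults:
        net_nodes = self.network.nodes
        N = len(net_nodes)
        K = len(self.disease_genes & net_nodes)
        if not self._neigh:
            empty = pd.DataFrame(
                columns=[
                    "candidate_gene", "network_name", "neighborhood_size",
                    "O", "E", "statistic", "p", "fdr", "is_top_kd",
                ]
            )
            return KDAResults(empty, [], self.network.name, n_perm, seed)
        sizes = sorted({len(nb) for nb in self._neigh.values()})
        nulls: dict[int, tuple[float, float]] = {}
        if self.null_mode == "resample":
            for s in sizes:
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=seed, spawn_key=(s,))
                )
                O_draws = rng.hypergeometric(K, N - K, s, size=n_perm)
                E = s * K / N
                stat = (O_draws - E) / np.sqrt(E + self.kappa)
                nulls[s] = (float(stat.mean()), float(stat.std(ddof=1)))
        else:
            # literal mode: disease labels shuffled over nodes, neighborhood
            # slots fixed; one permutation matrix shared across candidates
            node_list = sorted(net_nodes)
            labels = np.array([g in self.disease_genes for g in node_list])
            node_index = {g: i for i, g in enumerate(node_list)}
            rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
            perm_matrix = np.stack([rng.permutation(labels) for _ in range(n_perm)])
            nulls = {}
            for g, nb in self._neigh.items():
                idx = np.array([node_index[x] for x in nb])
                O_draws = perm_matrix[:, idx].sum(axis=1)
                s = len(nb)
                E = s * K / N
                stat = (O_draws - E) / np.sqrt(E + self.kappa)
                nulls[g] = (float(stat.mean()), float(stat.std(ddof=1)))
        rows = []
        for g in sorted(self._neigh):
            nb = self._neigh[g]
            O, E, stat = kda_statistic(nb, self.disease_genes, net_nodes, self.kappa)
            mean, sd = nulls[len(nb)] if self.null_mode == "resample" else nulls[g]
            if sd <= 0:
                logger.info("candidate %s skipped: degenerate null", g)
                continue
            p = float(stats.norm.sf((stat - mean) / sd))
            rows.append(
                {
                    "candidate_gene": g,
                    "network_name": self.network.name,
                    "neighborhood_size": len(nb),
                    "O": O,
                    "E": E,
                    "statistic": stat,
                    "p": p,
                }
            )
        frame = pd.DataFrame(rows)
        frame["fdr"] = bh_fdr(np.clip(frame["p"].to_numpy(), 1e-300, 1.0))
        frame = frame.sort_values(["p", "candidate_gene"], kind="mergesort").reset_index(drop=True)
        passing = frame.index[frame["fdr"] < fdr_max]
        top_idx = set(passing[:top_k])
        frame["is_top_kd"] = [i in top_idx for i in frame.index]
        subnets = [
            KdSubnetwork(g, self._neigh[g] | {g}, self.network.name)
            for g in frame.loc[frame["is_top_kd"], "candidate_gene"]
        ]
        return KDAResults(frame, subnets, self.network.name, n_perm, seed)


def kda_test(
    net: GeneNetwork,
    disease_genes,
    candidates=None,
    depth: int = 1,
    min_neighbors: int = 5,
    n_perm: int = 10_000,
    seed: int = 0,
    fdr_max: float = 0.01,
    top_k: int = 5,
    kappa: float = 1.0,
    null_mode: str = "resample",
) -> KDAResults:
    """Functional one-call wrapper around :class:`KeyDriverAnalysis`."""
    model = KeyDriverAnalysis(
        net, set(disease_genes), candidates=candidates, depth=depth,
        min_neighbors=min_neighbors, kappa=kappa, null_mode=null_mode,
    )
    return model.fit(n_perm=n_perm, seed=seed, fdr_max=fdr_max, top_k=top_k)


def essential_gene_enrichment(
    kds: set[str], essential: set[str], universe: set[str]
) -> tuple[float, float]:
    """Fisher enrichment of key drivers among essential genes.

    Essential genes are those intolerant to loss-of-function variation
    (pLI >= 0.9).  Returns (odds_ratio, one-sided p).
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    kds = set(kds) & universe
    essential = set(essential) & universe
    a = len(kds & essential)
    b = len(kds - essential)
    c = len(essential - kds)
    d = len(universe) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)
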