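"""Interaction-network construction and connectivity statistics.

Two kinds of network are analyzed: a protein-protein interaction (PPI)
network loaded from a STRING-style scored edge list, and a co-expression
network whose edges join gene pairs with absolute Pearson correlation
above a threshold (default 0.6) in a spatiotemporal expression matrix.

The question the permutation test answers: do the candidate genes connect
to the partner genes (e.g. known risk genes) more than a random gene set
of the same size would? Each iteration resamples a query-sized set
uniformly without replacement from the gene universe, recomputes the
number of connected query genes and the number of query-partner edges,
and the empirical p-value is (#{null >= observed} + 1) / (n_iter + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .modules import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_R_THRESHOLD = 0.6
DEFAULT_PPI_SCORE_CUTOFF = 400.0
DEFAULT_N_ITER = 100_000


@dataclass
class Network:
    """Undirected weighted network over an explicit node universe.

    The graph holds only genes with >= 1 edge; ``universe`` lists every
    gene eligible to appear (e.g. all genes scored for co-expression),
    which is what the permutation test resamples from.
    """

    graph: nx.Graph
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops not allowed: {loops[:3]}")
        stray = set(self.graph.nodes) - self.universe
        if stray:
            raise ValueError(f"edge endpoints outside universe: {sorted(stray)[:5]}")

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree_to(self, gene: str, targets: frozenset[str] | set[str]) -> int:
        if gene not in self.graph:
            return 0
        return sum(1 for nb in self.graph.neighbors(gene) if nb in targets)


@dataclass(frozen=True)
class ConnectivityStats:
    n_connected_nodes: int  # query genes with >= 1 qualifying edge
    n_edges: int  # edges with one endpoint in query, the other in partners


@dataclass
class PermutationTestResult:
    observed: ConnectivityStats
    p_nodes: float
    p_edges: float
    p_nodes_uncorrected: float  # r/n convention, reported alongside
    p_edges_uncorrected: float
    n_iter: int
    seed: int
    null_nodes: np.ndarray
    null_edges: np.ndarray


@dataclass(frozen=True)
class KsResult:
    statistic: float
    p_value: float


# ---------------------------------------------------------------------------


def coexpression_edges(
    expr: ExpressionMatrix,
    set_a: Iterable[str],
    set_b: Iterable[str],
    r_threshold: float = DEFAULT_R_THRESHOLD,
) -> Network:
    """Build the bipartite-ish co-expression network between two gene sets.

    An edge joins a in set_a to b in set_b (a != b) when |Pearson r| of
    their expression profiles exceeds ``r_threshold``; the weight is |r|.
    Genes absent from the matrix or with zero variance are skipped with a
    warning. The universe is every gene in the matrix with nonzero variance.
    """
    usable = expr.drop_zero_variance()
    present = set(usable.values.index)

    def resolve(genes: Iterable[str], label: str) -> list[str]:
        genes = list(dict.fromkeys(genes))
        missing = [g for g in genes if g not in present]
        if missing:
            logger.warning(
                "%s: %d genes not scorable (absent or zero variance): %s%s",
                label,
                len(missing),
                missing[:5],
                "..." if len(missing) > 5 else "",
            )
        return [g for g in genes if g in present]

    a_genes = resolve(set_a, "set_a")
    b_genes = resolve(set_b, "set_b")
    graph = nx.Graph()
    if a_genes and b_genes:
        xa = usable.values.loc[a_genes].to_numpy(dtype=float)
        xb = usable.values.loc[b_genes].to_numpy(dtype=float)
        za = (xa - xa.mean(axis=1, keepdims=True)) / xa.std(axis=1, keepdims=True)
        zb = (xb - xb.mean(axis=1, keepdims=True)) / xb.std(axis=1, keepdims=True)
        r = za @ zb.T / xa.shape[1]
        for i, a in enumerate(a_genes):
            for j, b in enumerate(b_genes):
                if a == b:
                    continue
                w = abs(float(r[i, j]))
                if w > r_threshold and not graph.has_edge(a, b):
                    graph.add_edge(a, b, weight=min(w, 1.0))
    return Network(graph=graph, universe=frozenset(present))


def read_ppi(
    path: str | Path,
    score_cutoff: float = DEFAULT_PPI_SCORE_CUTOFF,
    universe: Iterable[str] | None = None,
) -> Network:
    """Load a STRING-style edge list TSV (gene1, gene2, score).

    Edges below ``score_cutoff`` are dropped at load. The universe defaults
    to every gene appearing in the file (either column, any score).
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("gene1", "gene2", "score"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    all_genes = set(df["gene1"]) | set(df["gene2"])
    kept = df[df["score"] >= score_cutoff]
    graph = nx.Graph()
    for g1, g2, score in kept[["gene1", "gene2", "score"]].itertuples(index=False):
        if g1 == g2:
            continue
        graph.add_edge(str(g1), str(g2), weight=float(score))
    uni = frozenset(universe) if universe is not None else frozenset(map(str, all_genes))
    return Network(graph=graph, universe=uni | frozenset(graph.nodes))


def write_edge_list(net: Network, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene1\tgene2\tscore\n")
        for g1, g2, data in sorted(net.graph.edges(data=True)):
            fh.write(f"{g1}\t{g2}\t{data.get('weight', 1.0):.6g}\n")


# ---------------------------------------------------------------------------


def connectivity_stats(
    net: Network, query: Iterable[str], partners: Iterable[str]
) -> ConnectivityStats:
    """Count query-partner edges and connected query genes.

    An edge qualifies when one endpoint is in the query set and the other
    in the partner set; each undirected edge counts once even if both
    endpoints belong to both sets.
    """
    query = frozenset(query)
    partners = frozenset(partners)
    n_edges = 0
    connected: set[str] = set()
    for u, v in net.graph.edges():
        if (u in query and v in partners) or (v in query and u in partners):
            n_edges += 1
            if u in query:
                connected.add(u)
            if v in query:
                connected.add(v)
    return ConnectivityStats(n_connected_nodes=len(connected), n_edges=n_edges)


def permutation_connectivity_test(
    net: Network,
    query: Iterable[str],
    partners: Iterable[str],
    universe: Iterable[str] | None = None,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    exclude_partners: bool = False,
) -> PermutationTestResult:
    """Permutation test of query-partner connectivity.

    ``universe`` defaults to the network's node universe; with
    ``exclude_partners`` the partner genes are removed from it before
    sampling. Reports the +1-corrected empirical p (primary) and the
    uncorrected r/n convention alongside.
    """
    query = frozenset(query)
    partners = frozenset(partners)
    uni = frozenset(universe) if universe is not None else net.universe
    if exclude_partners:
        uni = uni - partners
    uni_list = sorted(uni)
    k = len(query)
    if k > len(uni_list):
        raise ValueError(f"query size {k} exceeds universe size {len(uni_list)}")

    observed = connectivity_stats(net, query, partners)

    # per-universe-gene number of partner neighbours; summing over a sampled
    # set counts each qualifying edge once per sampled endpoint, so edges with
    # both endpoints sampled AND both in the partner set need a -1 correction
    pdeg = np.array([net.degree_to(g, partners) for g in uni_list], dtype=np.int64)
    gene_index = {g: i for i, g in enumerate(uni_list)}
    pp_u, pp_v = [], []
    for u, v in net.graph.edges():
        if u in partners and v in partners and u in uni and v in uni:
            pp_u.append(gene_index[u])
            pp_v.append(gene_index[v])
    pp_u_arr = np.array(pp_u, dtype=np.int64)
    pp_v_arr = np.array(pp_v, dtype=np.int64)

    rng = np.random.default_rng(seed)
    n_uni = len(uni_list)
    null_nodes = np.empty(n_iter, dtype=np.int64)
    null_edges = np.empty(n_iter, dtype=np.int64)
    mask = np.zeros(n_uni, dtype=bool)
    for it in range(n_iter):
        idx = rng.choice(n_uni, size=k, replace=False)
        d = pdeg[idx]
        edges = int(d.sum())
        if pp_u_arr.size:
            mask[idx] = True
            edges -= int(np.count_nonzero(mask[pp_u_arr] & mask[pp_v_arr]))
            mask[idx] = False
        null_nodes[it] = int(np.count_nonzero(d))
        null_edges[it] = edges

    r_nodes = int(np.sum(null_nodes >= observed.n_connected_nodes))
    r_edges = int(np.sum(null_edges >= observed.n_edges))
    return PermutationTestResult(
        observed=observed,
        p_nodes=(r_nodes + 1) / (n_iter + 1),
        p_edges=(r_edges + 1) / (n_iter + 1),
        p_nodes_uncorrected=max(r_nodes, 0) / n_iter,
        p_edges_uncorrected=max(r_edges, 0) / n_iter,
        n_iter=n_iter,
        seed=seed,
        null_nodes=null_nodes,
        null_edges=null_edges,
    )


def ks_interaction_comparison(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    log_transform: bool = True,
) -> KsResult:
    """Two-sample Kolmogorov-Smirnov test on per-gene interaction counts.

    With ``log_transform`` the counts enter as log10(count + 1), matching
    how interaction-degree distributions are usually compared; the KS
    statistic itself is invariant to this monotone transform, the scale of
    the reported CDFs is not.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if log_transform:
        a = np.log10(a + 1.0)
        b = np.log10(b + 1.0)
    res = stats.ks_2samp(a, b, method="asymp")
    return KsResult(statistic=float(res.statistic), p_value=float(res.pvalue))
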