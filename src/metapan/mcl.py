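"""Markov Cluster algorithm (MCL) on the minbit graph.

MCL simulates flow on the graph: the column-stochastic transition matrix is
alternately squared (*expansion*, letting flow spread) and raised entrywise
to the inflation power then renormalized (*inflation*, strengthening strong
currents and demoting weak ones). Small entries are pruned to keep the
matrix sparse. At convergence the support of the matrix decomposes into
attractor systems; gene clusters are the connected components of that
support. Everything here is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .model import AnalysisParams, GeneCluster, MetapanError, MinbitEdge

__all__ = [
    "GeneCluster",
    "StochasticMatrix",
    "build_stochastic_matrix",
    "mcl_cluster",
    "name_clusters",
    "clusters_to_tsv",
    "clusters_from_tsv",
]

logger = logging.getLogger(__name__)


@dataclass
class StochasticMatrix:
    """A column-stochastic transition matrix over gene nodes."""

    node_ids: list[str]
    matrix: sp.csc_matrix

    def validate(self) -> "StochasticMatrix":
        n = len(self.node_ids)
        if self.matrix.shape != (n, n):
            raise MetapanError("matrix dimension does not match node count")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise MetapanError("negative entries in stochastic matrix")
        colsums = np.asarray(self.matrix.sum(axis=0)).ravel()
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise MetapanError("columns do not sum to 1")
        return self


def _normalize_columns(m: sp.csc_matrix) -> sp.csc_matrix:
    colsums = np.asarray(m.sum(axis=0)).ravel()
    if np.any(colsums <= 0):
        raise MetapanError("zero column during normalization")
    scale = sp.diags(1.0 / colsums)
    return (m @ scale).tocsc()


def build_stochastic_matrix(
    edges: list[MinbitEdge], all_nodes: list[str]
) -> StochasticMatrix:
    """Symmetric adjacency from edge weights, self-loops, column-normalized.

    Each node gets a self-loop equal to its maximum incident edge weight
    (1.0 for isolated nodes) — the standard damping that prevents the
    period-2 oscillations of bipartite-ish flow.
    """
    node_ids = sorted(set(all_nodes))
    if len(node_ids) != len(all_nodes):
        raise MetapanError("duplicate node ids")
    index = {nid: i for i, nid in enumerate(node_ids)}
    n = len(node_ids)

    rows, cols, vals = [], [], []
    loop = np.zeros(n)
    for e in edges:
        if e.gene_a not in index or e.gene_b not in index:
            raise MetapanError(f"edge ({e.gene_a}, {e.gene_b}) references unknown node")
        if e.weight < 0:
            raise MetapanError("negative edge weight")
        i, j = index[e.gene_a], index[e.gene_b]
        rows += [i, j]
        cols += [j, i]
        vals += [e.weight, e.weight]
        loop[i] = max(loop[i], e.weight)
        loop[j] = max(loop[j], e.weight)
    loop[loop == 0] = 1.0
    rows += list(range(n))
    cols += list(range(n))
    vals += list(loop)

    m = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    return StochasticMatrix(node_ids=node_ids, matrix=_normalize_columns(m)).validate()


def _inflate(m: sp.csc_matrix, power: float, eps: float) -> sp.csc_matrix:
    m = m.copy()
    m.data = np.power(m.data, power)
    m = _normalize_columns(m)
    if eps > 0:
        # prune, but never a column's largest entry: a column must keep support
        keep = m.data >= eps
        for j in range(m.shape[1]):
            lo, hi = m.indptr[j], m.indptr[j + 1]
            if lo < hi:
                keep[lo + int(np.argmax(m.data[lo:hi]))] = True
        m.data[~keep] = 0.0
        m.eliminate_zeros()
        m = _normalize_columns(m)
    return m


def mcl_cluster(
    m: StochasticMatrix, params: AnalysisParams | None = None
) -> list[GeneCluster]:
    """Run MCL to convergence and extract clusters.

    Iterates expansion (matrix square), inflation (entrywise power +
    renormalize) and pruning (drop entries below ``mcl_prune_epsilon``,
    renormalize) until the max absolute entrywise change falls below
    ``mcl_convergence_tol`` or ``mcl_max_iterations`` is reached (the
    latter logs a warning and returns the current partition). Clusters are
    the connected components of the converged matrix's support, which makes
    the result a partition of all nodes and keeps overlapping attractor
    systems together.
    """
    params = (params or AnalysisParams()).validate()
    m.validate()
    cur = m.matrix.astype(np.float64)

    converged = False
    for _ in range(params.mcl_max_iterations):
        nxt = (cur @ cur).tocsc()
        nxt = _inflate(nxt, params.mcl_inflation, params.mcl_prune_epsilon)
        diff = abs(nxt - cur)
        change = diff.max() if diff.nnz else 0.0
        cur = nxt
        if change < params.mcl_convergence_tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "MCL did not converge in %d iterations; returning current partition",
            params.mcl_max_iterations,
        )

    support = cur + cur.T
    n_comp, labels = connected_components(support, directed=False)
    members: dict[int, list[str]] = {}
    for node, comp in zip(m.node_ids, labels):
        members.setdefault(int(comp), []).append(node)
    clusters = [
        GeneCluster(cluster_id="", member_gene_ids=sorted(v))
        for v in members.values()
    ]
    return name_clusters(clusters)


def name_clusters(clusters: list[GeneCluster]) -> list[GeneCluster]:
    """Stable cluster ids: GC_%08d by (size desc, smallest member asc)."""
    ordered = sorted(
        clusters, key=lambda c: (-c.size, min(c.member_gene_ids))
    )
    return [
        GeneCluster(
            cluster_id=f"GC_{i + 1:08d}",
            member_gene_ids=sorted(c.member_gene_ids),
            genome_multiplicity=dict(c.genome_multiplicity),
        )
        for i, c in enumerate(ordered)
    ]


def clusters_to_tsv(clusters: list[GeneCluster], path: str | Path) -> None:
    """Write the gene -> cluster partition as a two-column TSV."""
    sizes = sum(c.size for c in clusters)
    seen: set[str] = set()
    for c in clusters:
        dup = seen & set(c.member_gene_ids)
        if dup:
            raise MetapanError(f"gene(s) {sorted(dup)[:5]} in more than one cluster")
        seen.update(c.member_gene_ids)
    if len(seen) != sizes:
        raise MetapanError("cluster membership is not a partition")
    with open(path, "w") as fh:
        fh.write("gene_id\tcluster_id\n")
        for c in sorted(clusters, key=lambda c: c.cluster_id):
            for gid in c.member_gene_ids:
                fh.write(f"{gid}\t{c.cluster_id}\n")


def clusters_from_tsv(path: str | Path) -> list[GeneCluster]:
    members: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_id"):
            raise MetapanError(f"{path}: not a cluster TSV")
        for line in fh:
            gid, cid = line.rstrip("\n").split("\t")
            members.setdefault(cid, []).append(gid)
    return [
        GeneCluster(cluster_id=cid, member_gene_ids=sorted(gids))
        for cid, gids in sorted(members.items())
    ]
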