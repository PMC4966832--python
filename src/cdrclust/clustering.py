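"""Two-stage length-independent clustering of CDR loops.

Loops are first grouped by average-linkage (UPGMA) agglomeration on the
precomputed DTW distance matrix, cutting the dendrogram at 1.5 Å.  Clusters
that hold many unique sequences but predict poorly from sequence are then
re-clustered with DBSCAN, with the neighbourhood radius per CDR type either
taken from configuration or chosen from the OPTICS reachability profile.
Cluster names encode the CDR type, the loop lengths present and a rank
letter, e.g. ``L1-13,14-A``.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .similarity import LoopDistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Cluster",
    "ClusterSet",
    "ClusteringConfig",
    "dbscan",
    "medoid",
    "name_clusters",
    "recluster_failing",
    "select_eps_optics",
    "summarize",
    "upgma_cluster",
]

#: DBSCAN neighbourhood radii per CDR type (Å).  L2 has no entry: for that
#: CDR the UPGMA stage alone is sufficient and no re-clustering is done.
DEFAULT_DBSCAN_EPS: dict[str, float | None] = {
    "L1": 0.82,
    "L2": None,
    "L3": 0.91,
    "H1": 0.80,
    "H2": 0.63,
}


@dataclass
class ClusteringConfig:
    upgma_cutoff: float = 1.5
    dbscan_eps: dict[str, float | None] = field(
        default_factory=lambda: dict(DEFAULT_DBSCAN_EPS))
    dbscan_min_pts: int = 3
    large_cluster_min_unique: int = 6
    recluster_min_unique: int = 6  # gate is "more than" this many unique sequences
    recluster_precision: float = 0.75
    recluster_recall: float = 0.25
    recluster_mode: str = "and"  # "and": both must fail; "or": either


@dataclass
class Cluster:
    members: list[str]
    name: str | None = None
    lengths: tuple[int, ...] = ()
    n_unique_sequences: int = 0
    medoid: str | None = None

    @property
    def n_structures(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    noise: list[str] = field(default_factory=list)

    def assigned(self) -> list[str]:
        return [m for c in self.clusters for m in c.members]

    def is_partition(self) -> bool:
        members = self.assigned() + list(self.noise)
        return len(members) == len(set(members))

    def by_name(self, name: str) -> Cluster:
        for c in self.clusters:
            if c.name == name:
                return c
        raise KeyError(name)


def upgma_cluster(matrix: LoopDistanceMatrix, cutoff: float = 1.5) -> ClusterSet:
    """Average-linkage flat clusters from cutting the dendrogram at ``cutoff``.

    Every loop is assigned (there is no noise at this stage): two loops
    share a cluster iff their cophenetic distance is at most the cutoff.
    """
    values = np.asarray(matrix.values, float)
    if np.any(~np.isfinite(values)):
        raise ValueError("distance matrix contains NaN or infinite entries")
    n = len(matrix.ids)
    if n == 1:
        return ClusterSet(clusters=[Cluster(members=list(matrix.ids))])
    condensed = squareform(values, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    flat = hierarchy.fcluster(Z, t=cutoff, criterion="distance")
    groups: dict[int, list[str]] = {}
    for label, source in zip(flat, matrix.ids):
        groups.setdefault(int(label), []).append(source)
    clusters = [Cluster(members=sorted(v)) for _, v in sorted(groups.items())]
    return ClusterSet(clusters=clusters)


def upgma_linkage_newick(matrix: LoopDistanceMatrix) -> str:
    """UPGMA dendrogram as a Newick string, for external inspection."""
    condensed = squareform(np.asarray(matrix.values, float), checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{matrix.ids[node.id]}:{length:.6f}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6f}"

    return walk(tree, tree.dist) + ";"


def select_eps_optics(matrix: LoopDistanceMatrix, min_pts: int,
                      override: float | None = None) -> float:
    """Choose the DBSCAN radius from the OPTICS reachability profile.

    The heuristic sorts the finite reachability values in decreasing order
    and places eps just below the largest consecutive drop (the deepest
    valley between density levels).  A configured per-CDR value always wins
    when supplied via ``override``.
    """
    if override is not None:
        return float(override)
    n = len(matrix.ids)
    if min_pts > n:
        raise ValueError(f"min_pts={min_pts} exceeds the number of points ({n})")
    from sklearn.cluster import OPTICS

    values = np.asarray(matrix.values, float)
    if np.allclose(values, 0.0):
        raise ValueError("all points identical; OPTICS reachability is degenerate")
    model = OPTICS(min_samples=min_pts, metric="precomputed", max_eps=np.inf)
    model.fit(values)
    reach = model.reachability_[model.ordering_]
    finite = np.sort(reach[np.isfinite(reach)])[::-1]
    if finite.size < 2:
        raise ValueError("not enough finite reachability values")
    drops = finite[:-1] - finite[1:]
    k = int(np.argmax(drops))
    return float((finite[k] + finite[k + 1]) / 2.0)


def dbscan(matrix: LoopDistanceMatrix, eps: float, min_pts: int) -> ClusterSet:
    """Density-based clustering on the precomputed distance matrix.

    Classic DBSCAN: a point is core if at least ``min_pts`` points
    (including itself) lie within ``eps``; clusters are the density-reachable
    sets, border points join the first discovered core's cluster, and
    unreachable points end up as noise.  Iteration order follows the matrix
    ids, which makes the outcome deterministic.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    values = np.asarray(matrix.values, float)
    n = len(matrix.ids)
    neighbours = [np.flatnonzero(values[i] <= eps) for i in range(n)]
    is_core = np.array([len(nb) >= min_pts for nb in neighbours])
    labels = np.full(n, -1, dtype=int)
    visited = np.zeros(n, dtype=bool)
    current = 0
    for i in range(n):
        if visited[i] or not is_core[i]:
            continue
        # breadth-first expansion from this core point
        queue = [i]
        visited[i] = True
        labels[i] = current
        while queue:
            p = queue.pop(0)
            if not is_core[p]:
                continue
            for q in neighbours[p]:
                if labels[q] == -1:
                    labels[q] = current
                if not visited[q]:
                    visited[q] = True
                    queue.append(q)
        current += 1
    groups: dict[int, list[str]] = {}
    noise = []
    for lab, source in zip(labels, matrix.ids):
        if lab == -1:
            noise.append(source)
        else:
            groups.setdefault(int(lab), []).append(source)
    clusters = [Cluster(members=sorted(v)) for _, v in sorted(groups.items())]
    return ClusterSet(clusters=clusters, noise=sorted(noise))


def medoid(members: list[str], matrix: LoopDistanceMatrix) -> str:
    """Member minimising the summed DTW distance to the rest of the cluster.

    Ties break to the lexicographically smallest source id.
    """
    if not members:
        raise ValueError("empty cluster has no medoid")
    if len(members) == 1:
        return members[0]
    idx = [matrix.ids.index(m) for m in members]
    sub = matrix.values[np.ix_(idx, idx)]
    sums = sub.sum(axis=1)
    order = np.lexsort((np.asarray(members, dtype=object), sums))
    return members[int(order[0])]


def annotate(cluster_set: ClusterSet, lengths: dict[str, int],
             sequences: dict[str, str],
             matrix: LoopDistanceMatrix | None = None) -> ClusterSet:
    """Fill in per-cluster lengths, unique-sequence counts and medoids."""
    out = []
    for c in cluster_set.clusters:
        out.append(replace(
            c,
            members=list(c.members),
            lengths=tuple(sorted({lengths[m] for m in c.members})),
            n_unique_sequences=len({sequences[m] for m in c.members}),
            medoid=medoid(c.members, matrix) if matrix is not None else c.medoid,
        ))
    return ClusterSet(clusters=out, noise=list(cluster_set.noise))


def _letter(rank: int) -> str:
    letters = string.ascii_uppercase
    if rank < 26:
        return letters[rank]
    return letters[rank // 26 - 1] + letters[rank % 26]


def name_clusters(cluster_set: ClusterSet, cdr_type: str,
                  lengths: dict[str, int], sequences: dict[str, str],
                  matrix: LoopDistanceMatrix | None = None) -> ClusterSet:
    """Assign canonical-class names: CDR type, lengths present, rank letter.

    Clusters sharing a length signature are lettered in the reporting order:
    first by length, then by number of structures (descending), finally by
    number of unique sequences (descending).
    """
    annotated = annotate(cluster_set, lengths, sequences, matrix)
    by_signature: dict[tuple[int, ...], list[Cluster]] = {}
    for c in annotated.clusters:
        by_signature.setdefault(c.lengths, []).append(c)
    named = []
    for signature, group in by_signature.items():
        group.sort(key=lambda c: (-c.n_structures, -c.n_unique_sequences,
                                  c.medoid or c.members[0]))
        sig = ",".join(str(v) for v in signature)
        for rank, c in enumerate(group):
            named.append(replace(c, name=f"{cdr_type}-{sig}-{_letter(rank)}"))
    named.sort(key=lambda c: (c.lengths, -c.n_structures, -c.n_unique_sequences))
    return ClusterSet(clusters=named, noise=list(annotated.noise))


def recluster_failing(cluster_set: ClusterSet,
                      prediction_stats: dict[str, tuple[float, float]],
                      config: ClusteringConfig,
                      matrix: LoopDistanceMatrix,
                      cdr_type: str) -> ClusterSet:
    """Replace poorly predictable large clusters by their DBSCAN sub-partition.

    A cluster is re-clustered when it holds more than
    ``config.recluster_min_unique`` unique sequences but its sequence-based
    prediction fails both gates (precision < 0.75 and recall < 0.25 by
    default).  Sub-cluster noise points move to the set-level noise.  For a
    CDR type with no configured radius (L2), clusters are left untouched.
    """
    eps = config.dbscan_eps.get(cdr_type)
    out: list[Cluster] = []
    noise = list(cluster_set.noise)
    for c in cluster_set.clusters:
        large = c.n_unique_sequences > config.recluster_min_unique
        if large:
            if c.name not in prediction_stats:
                raise KeyError(f"no prediction stats for large cluster {c.name}")
            precision, recall = prediction_stats[c.name]
            bad_p = precision < config.recluster_precision
            bad_r = recall < config.recluster_recall
            failing = (bad_p and bad_r) if config.recluster_mode == "and" else (bad_p or bad_r)
        else:
            failing = False
        if not failing or eps is None:
            out.append(c)
            continue
        sub = dbscan(matrix.submatrix(c.members), eps, config.dbscan_min_pts)
        logger.info("re-clustered %s into %d sub-clusters (%d noise)",
                    c.name, len(sub.clusters), len(sub.noise))
        out.extend(sub.clusters)
        noise.extend(sub.noise)
    return ClusterSet(clusters=out, noise=noise)


def summarize(cluster_set: ClusterSet, min_unique: int = 6) -> pd.DataFrame:
    """Tabulate the large clusters (>= ``min_unique`` unique sequences).

    Columns: name, lengths, n_structures, medoid, n_unique_sequences;
    ordered first by length, then by number of structures, then by number
    of sequences.
    """
    rows = [
        {
            "name": c.name,
            "lengths": ",".join(str(v) for v in c.lengths),
            "n_structures": c.n_structures,
            "medoid": c.medoid,
            "n_unique_sequences": c.n_unique_sequences,
        }
        for c in sorted(cluster_set.clusters,
                        key=lambda c: (c.lengths, -c.n_structures, -c.n_unique_sequences))
        if c.n_unique_sequences >= min_unique
    ]
    return pd.DataFrame(rows, columns=["name", "lengths", "n_structures",
                                       "medoid", "n_unique_sequences"])
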