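"""Sample clustering on a signature and cluster-label enrichment.

Samples are clustered on their expression profiles over a signature's
miRNAs using Pearson-correlation distance (d = 1 - r) and average (UPGMA)
linkage, the tree is cut into a requested number of clusters, and each
(cluster, clinical label) pair is tested for over-representation with a
one-sided Fisher exact test comparing the cluster against all other
samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .diffexpr import bh_adjust

ENRICHMENT_COLUMNS = ["cluster", "label", "a", "b", "c", "d", "p"]


@dataclass
class Dendrogram:
    """Merge history of an agglomerative clustering.

    ``linkage`` is a scipy linkage matrix; ``labels`` are the sample ids in
    input-column order (leaf i of the linkage is ``labels[i]``).
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def merges(self) -> list[tuple[frozenset, frozenset, float]]:
        """Merge steps as (left leaf-set, right leaf-set, height), in merge order."""
        members: list[frozenset] = [frozenset([lab]) for lab in self.labels]
        out = []
        for left, right, height, _count in self.linkage:
            a, b = members[int(left)], members[int(right)]
            out.append((a, b, float(height)))
            members.append(a | b)
        return out

    def to_newick(self) -> str:
        """Ultrametric newick string (branch lengths from merge heights)."""
        heights = [0.0] * self.n_leaves + [h for _, _, h, _ in self.linkage]
        parts: list[str] = [_quote(lab) for lab in self.labels]
        for idx, (left, right, height, _count) in enumerate(self.linkage):
            i, j = int(left), int(right)
            bl_i = (height - heights[i]) / 2.0
            bl_j = (height - heights[j]) / 2.0
            parts.append(f"({parts[i]}:{bl_i:.10g},{parts[j]}:{bl_j:.10g})")
        return parts[-1] + ";"


def _quote(label: str) -> str:
    if any(c in label for c in "(),:; \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass
class ClusterAssignment:
    """Flat clustering: sample -> cluster id in 1..k.

    Cluster ids are numbered by first sample occurrence in input order.
    """

    assignment: dict[str, int]
    dendrogram: Dendrogram

    @property
    def k(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, cluster: int) -> list[str]:
        return [s for s, c in self.assignment.items() if c == cluster]

    def to_series(self) -> pd.Series:
        return pd.Series(self.assignment, name="cluster")


def pearson_average_hclust(values: pd.DataFrame) -> Dendrogram:
    """UPGMA dendrogram of samples under Pearson-correlation distance.

    ``values`` is a miRNA x sample table (samples are clustered on their
    profiles over the rows).  Distance d = 1 - r ranges from 0 (identical
    profiles) to 2 (perfectly anti-correlated).  A sample with zero
    variance has no defined correlation and is an error.
    """
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = values.to_numpy(dtype=float)
    sd = x.std(axis=0)
    flat = [values.columns[i] for i in np.where(sd == 0)[0]]
    if flat:
        raise ValueError(f"zero-variance sample(s): {flat}")
    r = np.corrcoef(x, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # symmetrize away rounding noise
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    return Dendrogram(linkage=z, labels=list(values.columns))


def cut_clusters(dendrogram: Dendrogram, k: int) -> ClusterAssignment:
    """Cut the tree into exactly ``k`` clusters (at the (k-1) largest merges)."""
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    raw = hierarchy.fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    if len(set(raw)) != k:
        raise ValueError(
            f"tied merge heights prevent a cut into exactly {k} clusters"
        )
    relabel: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for sample, cluster in zip(dendrogram.labels, raw):
        if cluster not in relabel:
            relabel[cluster] = len(relabel) + 1
        assignment[sample] = relabel[cluster]
    return ClusterAssignment(assignment=assignment, dendrogram=dendrogram)


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact p for the 2x2 table [[a,b],[c,d]].

    Hypergeometric upper tail P(X >= a) with all margins fixed: the chance
    of seeing at least ``a`` labelled samples in the cluster.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    n_total = a + b + c + d
    if n_total == 0:
        return 1.0
    return float(np.clip(stats.hypergeom.sf(a - 1, n_total, a + c, a + b), 0.0, 1.0))


def cluster_enrichment(
    assignment: ClusterAssignment,
    labels: Mapping[str, str],
    adjust: bool = False,
) -> pd.DataFrame:
    """Label over-representation per cluster, one 2x2 Fisher test each.

    For every (cluster, label) pair the table is (a) in-cluster with label,
    (b) in-cluster without, (c) out-of-cluster with label, (d) out-of-cluster
    without.  P-values are reported unadjusted (per-cluster reporting);
    ``adjust=True`` appends a BH ``q`` column over all pairs.
    """
    samples = list(assignment.assignment)
    unlabelled = [s for s in samples if s not in labels]
    if unlabelled:
        raise ValueError(f"samples without labels: {unlabelled}")
    label_values = sorted(set(labels[s] for s in samples))
    clusters = sorted(set(assignment.assignment.values()))
    rows = []
    for cluster in clusters:
        in_cluster = set(assignment.members(cluster))
        for label in label_values:
            a = sum(1 for s in in_cluster if labels[s] == label)
            b = len(in_cluster) - a
            c = sum(1 for s in samples if s not in in_cluster and labels[s] == label)
            d = len(samples) - len(in_cluster) - c
            rows.append(
                {
                    "cluster": cluster,
                    "label": label,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "p": fisher_one_sided(a, b, c, d),
                }
            )
    out = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
    if adjust:
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out
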