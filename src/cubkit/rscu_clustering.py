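"""Genome clustering on pooled RSCU vectors.

Each genome is summarised by its pooled 59-dimensional RSCU vector;
genomes are compared by Euclidean distance and clustered agglomeratively
(average linkage by default).  The dendrogram exports to Newick with
ultrametric branch lengths (leaf-to-merge height = half the merge
distance), so a merge at distance d places its two children d/2 apart
from the merge point.

A user-supplied reference tree (e.g. a sequence-alignment phylogeny) can
be compared against the RSCU dendrogram topology via the Robinson–Foulds
distance — a comparison aid only, not a phylogenetic inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .genetic_code import SYNONYMOUS_CODONS

LINKAGE_METHODS = ("average", "single", "complete", "ward")


def build_feature_matrix(
    rscu_by_genome: Mapping[str, pd.Series] | pd.DataFrame,
) -> pd.DataFrame:
    """Stack pooled per-genome RSCU vectors into a genomes x 59 matrix.

    Row order follows input order; columns are the 59 synonymous codons
    in alphabetical order (fixed so file outputs are reproducible).
    """
    if isinstance(rscu_by_genome, pd.DataFrame):
        fm = rscu_by_genome.reindex(columns=list(SYNONYMOUS_CODONS))
    else:
        fm = pd.DataFrame(
            {g: v.reindex(list(SYNONYMOUS_CODONS)) for g, v in rscu_by_genome.items()}
        ).T
        fm.columns = list(SYNONYMOUS_CODONS)
    if len(fm) < 2:
        raise ValueError("need at least 2 genomes")
    if fm.isna().any().any():
        bad = fm.stack(future_stack=True)
        bad = bad[bad.isna()].index[0]
        raise ValueError(
            f"undefined RSCU for genome {bad[0]!r}, codon {bad[1]!r} "
            "(amino acid absent from the pooled counts)"
        )
    fm.index = fm.index.astype(str)
    return fm


def euclidean_distance_matrix(fm: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Euclidean distance matrix between genome RSCU rows."""
    d = squareform(pdist(fm.to_numpy(), metric="euclidean"))
    return pd.DataFrame(d, index=fm.index, columns=fm.index)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree over genome labels.

    ``linkage_matrix`` is in scipy format: row i merges clusters
    Z[i, 0] and Z[i, 1] at height Z[i, 2] into cluster n + i.
    """

    labels: tuple[str, ...]
    linkage_matrix: np.ndarray
    method: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths = half merge heights."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}

        for i, (_, _, h, _) in enumerate(self.linkage_matrix):
            height[n + i] = h / 2.0

        def render(node: int) -> str:
            if node < n:
                return self.labels[node]
            a, b, h, _ = self.linkage_matrix[node - n]
            a, b = int(a), int(b)
            # each child hangs (merge height)/2 - (its own height)/2 below
            la = h / 2.0 - height[a]
            lb = h / 2.0 - height[b]
            return f"({render(a)}:{la:.10g},{render(b)}:{lb:.10g})"

        return render(2 * n - 2) + ";"


def agglomerate(dist: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Hierarchical agglomerative clustering of a distance matrix."""
    if linkage not in LINKAGE_METHODS:
        raise ValueError(f"linkage must be one of {LINKAGE_METHODS}")
    if len(dist) < 2:
        raise ValueError("need at least 2 items")
    condensed = squareform(dist.to_numpy(), checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(
        labels=tuple(dist.index.astype(str)), linkage_matrix=Z, method=linkage
    )


def cut_clusters(dn: Dendrogram, k: int) -> pd.Series:
    """Cut the dendrogram into exactly k flat clusters.

    Implemented directly from the merge list: applying the first n - k
    merges (lowest heights) and leaving the k - 1 highest unmade yields
    exactly k clusters.  Cluster ids are 1..k in order of each cluster's
    first label.
    """
    n = len(dn.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n - k):
        a, b = int(dn.linkage_matrix[i, 0]), int(dn.linkage_matrix[i, 1])
        root = n + i
        parent[find(a)] = root
        parent[find(b)] = root

    roots = [find(i) for i in range(n)]
    ids: dict[int, int] = {}
    labels = []
    for r in roots:
        if r not in ids:
            ids[r] = len(ids) + 1
        labels.append(ids[r])
    return pd.Series(labels, index=list(dn.labels), name="cluster")


def robinson_foulds(newick_a: str, newick_b: str) -> int:
    """Robinson–Foulds (symmetric difference) distance between two trees.

    Both trees are treated as unrooted; taxa must match.
    """
    import dendropy

    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(t1, t2))
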