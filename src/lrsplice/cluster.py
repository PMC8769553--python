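"""Jaccard similarity of per-sample isoform sets and hierarchical clustering."""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator


def jaccard(a: Set[str], b: Set[str]) -> float:
    """|a & b| / |a | b|; defined as 1.0 when both sets are empty."""
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


class JaccardClustering(BaseEstimator):
    """Agglomerative clustering of samples on 1 - Jaccard distance.

    Samples are ordered lexicographically by id before linkage, which makes
    the dendrogram deterministic under permutation of the input mapping.
    """

    def __init__(self, linkage: str = "average"):
        self.linkage = linkage

    def fit(self, sets: Dict[str, Set[str]], y=None):
        if len(sets) < 2:
            raise ValueError("need >= 2 samples")
        self.sample_ids_ = sorted(sets)
        n = len(self.sample_ids_)
        sim = np.ones((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                s = jaccard(sets[self.sample_ids_[i]], sets[self.sample_ids_[j]])
                sim[i, j] = sim[j, i] = s
        self.similarity_ = pd.DataFrame(sim, index=self.sample_ids_, columns=self.sample_ids_)
        dist = 1.0 - sim
        condensed = dist[np.triu_indices(n, k=1)]
        self.linkage_ = hierarchy.linkage(condensed, method=self.linkage)
        return self

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_)

        def rec(node) -> str:
            if node.is_leaf():
                return self.sample_ids_[node.id]
            left, right = rec(node.get_left()), rec(node.get_right())
            dl = node.dist - node.get_left().dist
            dr = node.dist - node.get_right().dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return rec(tree) + ";"


def cluster_samples(
    sets: Dict[str, Set[str]], linkage: str = "average"
) -> Tuple[np.ndarray, pd.DataFrame]:
    """Linkage matrix plus the pairwise Jaccard similarity matrix."""
    model = JaccardClustering(linkage=linkage).fit(sets)
    return model.linkage_, model.similarity_


def read_sample_sets(path: str) -> Dict[str, Set[str]]:
    """TSV with columns sample_id, isoform_id (one membership per row)."""
    df = pd.read_csv(path, sep="\t")
    out: Dict[str, Set[str]] = {}
    for sid, grp in df.groupby("sample_id"):
        out[str(sid)] = set(grp["isoform_id"].astype(str))
    return out
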