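"""Cross-platform expression-profile comparison on ranks.

Microarray intensities, RPKM and FPKM live on incompatible scales, so
samples from heterogeneous sources are compared non-parametrically: genes
are ranked within each sample, Euclidean distances are computed between
rank vectors, and samples are clustered with Ward's hierarchical method.
Any strictly monotone per-sample transform of the raw values leaves the
result unchanged, which is the whole point of the construction.

Also provides marker-percentile reporting (is a marker gene above the
50th/75th percentile of a sample's genome-wide distribution?) and a
centred/scaled PCA that drops zero-variance genes first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "common_gene_panel",
    "rank_transform",
    "ward_cluster",
    "Dendrogram",
    "marker_quartile_report",
    "pca",
]


def common_gene_panel(
    panel: Mapping[str, pd.DataFrame], expressed_threshold: float = 0.0
) -> dict[str, pd.DataFrame]:
    """Restrict every source to genes present and expressed in all sources.

    A gene counts as expressed in a source when its maximum value across
    that source's samples exceeds the threshold (default 0); genes missing
    from any source or unexpressed in any source are dropped everywhere.
    """
    if len(panel) < 2:
        raise ValueError("need at least two sources")
    common: set[str] | None = None
    for name, df in panel.items():
        genes = set(df.index)
        common = genes if common is None else common & genes
    assert common is not None
    expressed = set(common)
    for name, df in panel.items():
        sub = df.loc[sorted(common)]
        keep = sub.max(axis=1) > expressed_threshold
        expressed &= set(sub.index[keep])
    if not expressed:
        raise ValueError("no gene is present and expressed in every source")
    order = sorted(expressed)
    return {name: df.loc[order] for name, df in panel.items()}


def rank_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Within-column ranks 1..n (average ranks on ties)."""
    ranked = stats.rankdata(matrix.to_numpy(dtype=float), axis=0, method="average")
    return pd.DataFrame(ranked, index=matrix.index, columns=matrix.columns)


@dataclass
class Dendrogram:
    """Ward merge tree over samples (scipy linkage encoding + leaf labels)."""

    linkage: np.ndarray
    labels: list[str]

    def cut(self, k: int) -> dict[str, int]:
        """Sample -> cluster id for the k-cluster cut."""
        assignments = hierarchy.fcluster(self.linkage, k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignments)))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = rec(node.get_left()), rec(node.get_right())
            dl = node.dist - node.get_left().dist
            dr = node.dist - node.get_right().dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return rec(tree) + ";"


def ward_cluster(rank_matrix: pd.DataFrame) -> Dendrogram:
    """Ward hierarchical clustering of samples on Euclidean rank distances.

    Uses the squared-Euclidean Lance-Williams update ("ward.D2"-equivalent
    on Euclidean input).  Samples are ordered by label beforehand so exact
    distance ties resolve deterministically.
    """
    if rank_matrix.shape[1] < 2:
        raise ValueError("need at least two samples to cluster")
    if rank_matrix.isna().any().any():
        raise ValueError("rank matrix contains NaN")
    cols = sorted(rank_matrix.columns)
    X = rank_matrix[cols].to_numpy(dtype=float).T  # samples x genes
    Z = hierarchy.linkage(X, method="ward")
    return Dendrogram(linkage=Z, labels=list(cols))


def marker_quartile_report(
    matrix: pd.DataFrame,
    marker_genes: Sequence[str],
    pluripotency_genes: Sequence[str] = (),
) -> pd.DataFrame:
    """Flag marker genes above per-sample expression percentiles.

    For each (marker, sample) pair, reports the expression value and
    whether it exceeds the 50th and 75th percentiles of that sample's
    genome-wide distribution.  Markers absent from the matrix appear with
    ``present = False``.  Pluripotency genes, if given, are reported the
    same way under role "pluripotency" (expected to sit low in
    well-differentiated samples).
    """
    roles = [(g, "marker") for g in marker_genes] + [
        (g, "pluripotency") for g in pluripotency_genes
    ]
    q50 = matrix.quantile(0.5, axis=0)
    q75 = matrix.quantile(0.75, axis=0)
    rows = []
    for gene, role in roles:
        present = gene in matrix.index
        for sample in matrix.columns:
            value = float(matrix.at[gene, sample]) if present else np.nan
            rows.append(
                {
                    "gene": gene,
                    "role": role,
                    "sample": sample,
                    "present": present,
                    "value": value,
                    "above_p50": bool(present and value > q50[sample]),
                    "above_p75": bool(present and value > q75[sample]),
                }
            )
    return pd.DataFrame(rows)


def pca(
    matrix: pd.DataFrame, center: bool = True, scale: bool = True
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of samples over genes (zero-variance genes dropped).

    ``matrix`` is gene x sample; samples are the observations.  Returns
    (scores: sample x component DataFrame, variance fractions summing to 1).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    X = matrix.to_numpy(dtype=float).T  # samples x genes
    var = X.var(axis=0, ddof=1)
    X = X[:, var > 0]
    if X.shape[1] == 0:
        raise ValueError("all genes have zero variance")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        X = X / X.std(axis=0, ddof=1)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    frac = S**2 / np.sum(S**2)
    scores = pd.DataFrame(
        U * S,
        index=matrix.columns,
        columns=[f"PC{i+1}" for i in range(len(S))],
    )
    return scores, frac
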