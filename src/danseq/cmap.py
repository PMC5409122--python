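"""Drug-signature connectivity matching against perturbation rank profiles.

A signed disease signature (up- and down-regulated gene lists) is matched
against columns of a probe x instance rank matrix, where rank 1 marks the
probe most up-regulated by the perturbation.  Concentration of the
signature's probes at either end of a column is measured with a
KS-statistic enrichment score in [-1, 1]; an instance's combined
connectivity score is (es_up - es_down)/2 when the two scores disagree in
sign and 0 otherwise, so that a profile has to move the up genes one way
and the down genes the other to score at all.  Perturbagen-level
significance comes from random signatures of identical shape.

A separate rule extracts the genes a perturbagen moves consistently: a
gene is called up (down) only if every one of its probes sits in the top
(bottom) k ranks of every instance of that perturbagen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import SignedGeneSet

__all__ = [
    "ks_enrichment",
    "score_instance",
    "score_all_instances",
    "perturbagen_significance",
    "consistent_genes",
    "ConnectivityResult",
]


def ks_enrichment(tag_positions: Sequence[int], n: int) -> float:
    """KS enrichment score of a tag set within a ranked list of length n.

    With V(1) < ... < V(t) the sorted tag positions (1-based),
    a = max_j (j/t - V(j)/n) and b = max_j (V(j)/n - (j-1)/t); the score is
    a if a > b else -b.  Positive scores mean concentration at the top.

    The degenerate full-list tag set (t = n) is permitted and scores -1/n,
    the analytic value of the a/b construction.
    """
    V = np.sort(np.asarray(tag_positions, dtype=float))
    t = V.size
    if t == 0:
        raise ValueError("tag set is empty")
    if t > n or V[0] < 1 or V[-1] > n or len(np.unique(V)) != t:
        raise ValueError("tag positions must be distinct and within 1..n")
    j = np.arange(1, t + 1)
    a = np.max(j / t - V / n)
    b = np.max(V / n - (j - 1) / t)
    return float(a if a > b else -b)


def _signature_probe_positions(
    genes: Sequence[str], column: pd.Series, probe_map: Mapping[str, str]
) -> np.ndarray:
    wanted = set(genes)
    probes = [p for p in column.index if probe_map.get(p) in wanted]
    return column.loc[probes].to_numpy(dtype=int)


def score_instance(
    signature: SignedGeneSet,
    column: pd.Series,
    probe_map: Mapping[str, str],
) -> tuple[float, float, float]:
    """(es_up, es_down, combined) for one instance column.

    Signature genes are expanded to their probes; the combined score is
    (es_up - es_down)/2 when the scores disagree in sign, else 0.
    """
    n = len(column)
    up_pos = _signature_probe_positions(signature.up, column, probe_map)
    down_pos = _signature_probe_positions(signature.down, column, probe_map)
    if up_pos.size == 0 or down_pos.size == 0:
        raise ValueError("no mapped probes for one signature direction")
    es_up = ks_enrichment(up_pos, n)
    es_down = ks_enrichment(down_pos, n)
    combined = (es_up - es_down) / 2.0 if es_up * es_down < 0 else 0.0
    return es_up, es_down, combined


class _SignatureScorer:
    """Precomputed probe-row lookups for fast repeated instance scoring."""

    def __init__(self, rank_matrix: pd.DataFrame, probe_map: Mapping[str, str]) -> None:
        self.arr = rank_matrix.to_numpy(dtype=np.int64)
        self.n = self.arr.shape[0]
        self.columns = list(rank_matrix.columns)
        self.gene_rows: dict[str, list[int]] = {}
        for i, p in enumerate(rank_matrix.index):
            g = probe_map.get(p)
            if g is not None:
                self.gene_rows.setdefault(g, []).append(i)

    def rows_for(self, genes: Sequence[str]) -> np.ndarray:
        rows = [r for g in genes for r in self.gene_rows.get(g, [])]
        return np.asarray(rows, dtype=int)

    def combined(self, up_rows: np.ndarray, down_rows: np.ndarray, col: int) -> tuple[float, float, float]:
        if up_rows.size == 0 or down_rows.size == 0:
            raise ValueError("no mapped probes for one signature direction")
        es_up = ks_enrichment(self.arr[up_rows, col], self.n)
        es_down = ks_enrichment(self.arr[down_rows, col], self.n)
        c = (es_up - es_down) / 2.0 if es_up * es_down < 0 else 0.0
        return es_up, es_down, c


def score_all_instances(
    signature: SignedGeneSet,
    rank_matrix: pd.DataFrame,
    probe_map: Mapping[str, str],
) -> pd.DataFrame:
    """Per-instance (es_up, es_down, combined) table; unmappable instances skipped."""
    scorer = _SignatureScorer(rank_matrix, probe_map)
    up_rows = scorer.rows_for(signature.up)
    down_rows = scorer.rows_for(signature.down)
    rows = {}
    for j, col in enumerate(scorer.columns):
        try:
            es_up, es_down, combined = scorer.combined(up_rows, down_rows, j)
        except ValueError as exc:
            warnings.warn(f"instance {col!r} skipped: {exc}", stacklevel=2)
            continue
        rows[col] = {"es_up": es_up, "es_down": es_down, "combined": combined}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "instance_id"
    return out


@dataclass
class ConnectivityResult:
    """Perturbagen-level connectivity: observed mean score and permutation null."""

    perturbagen: str
    instance_scores: pd.DataFrame
    observed: float
    null_scores: np.ndarray
    p_value: float  # two-sided, add-one permutation p


def perturbagen_significance(
    signature: SignedGeneSet,
    rank_matrix: pd.DataFrame,
    instance_meta: pd.DataFrame,
    perturbagen: str,
    probe_map: Mapping[str, str],
    n_perm: int = 1000,
    seed: int = 0,
) -> ConnectivityResult:
    """Permutation test of a perturbagen's mean combined connectivity score.

    The null redraws random signatures of identical up/down sizes from the
    mapped gene universe and rescores the perturbagen's instances.  The
    two-sided p compares |observed| with |null| (add-one estimator).
    """
    if n_perm < 100:
        warnings.warn("n_perm below 100 gives a very coarse p-value", stacklevel=2)
    inst = instance_meta.index[instance_meta["perturbagen"] == perturbagen]
    if len(inst) == 0:
        raise ValueError(f"perturbagen {perturbagen!r} has no instances")
    sub = rank_matrix[list(inst)]
    scorer = _SignatureScorer(sub, probe_map)
    scores = score_all_instances(signature, sub, probe_map)
    observed = float(scores["combined"].mean())

    mapped_genes = sorted(scorer.gene_rows)
    rng = np.random.default_rng(seed)
    n_up, n_down = len(signature.up), len(signature.down)
    n_cols = len(scorer.columns)
    null = np.empty(n_perm)
    for i in range(n_perm):
        pick = rng.choice(len(mapped_genes), size=n_up + n_down, replace=False)
        up_rows = scorer.rows_for([mapped_genes[j] for j in pick[:n_up]])
        down_rows = scorer.rows_for([mapped_genes[j] for j in pick[n_up:]])
        null[i] = float(
            np.mean([scorer.combined(up_rows, down_rows, j)[2] for j in range(n_cols)])
        )
    p = (np.sum(np.abs(null) >= abs(observed)) + 1.0) / (n_perm + 1.0)
    return ConnectivityResult(
        perturbagen=perturbagen,
        instance_scores=scores,
        observed=observed,
        null_scores=null,
        p_value=float(p),
    )


def consistent_genes(
    rank_matrix: pd.DataFrame,
    instance_meta: pd.DataFrame,
    perturbagen: str,
    probe_map: Mapping[str, str],
    top_k: int = 1000,
) -> SignedGeneSet:
    """Genes every probe of which is extreme in every instance of a drug.

    A probe is "up" in an instance iff its rank <= top_k and "down" iff its
    rank >= n_probes - top_k + 1; a gene is called up (down) only when all
    of its probes are up (down) in all instances.  Requires
    top_k < n_probes / 2, which makes the up and down calls disjoint.
    """
    n_probes = len(rank_matrix)
    if not 0 < top_k < n_probes / 2:
        raise ValueError("top_k must satisfy 0 < top_k < n_probes / 2")
    inst = instance_meta.index[instance_meta["perturbagen"] == perturbagen]
    if len(inst) == 0:
        raise ValueError(f"perturbagen {perturbagen!r} has no instances")
    sub = rank_matrix[list(inst)]
    gene_probes: dict[str, list[str]] = {}
    for p in rank_matrix.index:
        g = probe_map.get(p)
        if g is not None:
            gene_probes.setdefault(g, []).append(p)
    up, down = [], []
    for gene, probes in gene_probes.items():
        block = sub.loc[probes].to_numpy()
        if (block <= top_k).all():
            up.append(gene)
        elif (block >= n_probes - top_k + 1).all():
            down.append(gene)
    return SignedGeneSet(up=sorted(up), down=sorted(down))
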