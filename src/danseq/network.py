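"""Functional-convergence tests on a weighted gene network.

The central statistic is the sum of edge weights among all pairs of a gene
set.  Its significance is assessed against two nulls:

* attribute-matched random gene sets — each target gene replaced by a gene
  from the same joint (degree, CDS length, FPKM) quantile cell, so a
  cluster of merely "expressed-in-this-cell-type" genes does not score;
* simulated case/control transcriptomes — null count matrices matched to
  the observed per-gene means pushed through the full DE stage, taking the
  top-k most significant genes each time, to show that convergence is
  genotype-driven rather than a property of any top-k selection.

A simplified likelihood-ratio integration scheme for building a weighted
network from multiple gene-pair evidence sources is also provided.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ClusterTestResult, CountMatrix, empirical_p_value
from .synthetic import simulate_matched_null

__all__ = [
    "clustering_statistic",
    "network_attributes",
    "sample_matched",
    "cluster_test",
    "permuted_direction_test",
    "simulation_null_test",
    "build_integrated_network",
]


def clustering_statistic(genes: Iterable[str], network: nx.Graph) -> tuple[float, int]:
    """(weight sum, link count) over within-set edges.

    Genes absent from the network contribute no edges but still count
    toward the set size; an empty set returns (0, 0) with a warning.
    """
    gene_list = list(dict.fromkeys(genes))
    if not gene_list:
        warnings.warn("empty gene set", stacklevel=2)
        return 0.0, 0
    present = [g for g in gene_list if g in network]
    weight_sum, links = 0.0, 0
    for i, u in enumerate(present):
        adj = network.adj[u]
        for v in present[i + 1 :]:
            if v in adj:
                weight_sum += adj[v].get("weight", 1.0)
                links += 1
    return weight_sum, links


def _clustered_members(genes: Sequence[str], network: nx.Graph) -> list[str]:
    """Subset of genes with at least one within-set edge."""
    inset = set(g for g in genes if g in network)
    out = []
    for g in inset:
        if any(v in inset for v in network.adj[g]):
            out.append(g)
    return sorted(out)


def network_attributes(
    network: nx.Graph, attributes: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Attach network degree (incident-edge count) to an attribute table.

    Degree is the unweighted incident-edge count.  Genes absent from the
    table but present in the network get degree only.
    """
    deg = pd.Series(dict(network.degree()), name="degree")
    if attributes is None:
        return deg.to_frame()
    out = attributes.copy()
    out["degree"] = deg.reindex(out.index).fillna(0).astype(int)
    return out


class _MatchedSampler:
    """Draws random gene sets matched on joint attribute quantile bins.

    Each attribute is cut into ``bins`` quantile bins over the universe;
    the joint cell of a target gene defines its donor pool (excluding all
    target-set members).  Cells with fewer than ``min_donors`` donors are
    widened one quantile step per attribute at a time until large enough.
    Sets are drawn without within-set replacement.
    """

    def __init__(
        self,
        target: Sequence[str],
        attributes: pd.DataFrame,
        attrs: Sequence[str],
        bins: int = 10,
        min_donors: int = 20,
    ) -> None:
        self.target = list(dict.fromkeys(target))
        missing = [g for g in self.target if g not in attributes.index]
        if missing:
            raise ValueError(f"attribute table does not cover target genes: {missing[:5]}")
        if len(attributes) < len(self.target):
            raise ValueError("gene universe smaller than the target set")
        self.universe = attributes.index.to_numpy()
        self.codes = np.column_stack(
            [
                pd.qcut(attributes[a].rank(method="first"), q=bins, labels=False, duplicates="drop")
                for a in attrs
            ]
        )
        self.gene_pos = {g: i for i, g in enumerate(self.universe)}
        target_set = set(self.target)
        eligible = np.array([g not in target_set for g in self.universe])
        # widening schedule: loosen the last-listed attribute first, one
        # quantile step at a time, so the first attribute (degree, in the
        # network test) keeps the tightest match
        d = self.codes.shape[1]
        schedule = [np.zeros(d, dtype=int)]
        widths = np.zeros(d, dtype=int)
        while widths.min() <= bins:
            for j in range(d - 1, -1, -1):
                widths = widths.copy()
                widths[j] += 1
                schedule.append(widths)
        self.pools: list[np.ndarray] = []
        for g in self.target:
            code = self.codes[self.gene_pos[g]]
            ok = eligible
            for widths in schedule:
                ok = (np.abs(self.codes - code[None, :]) <= widths[None, :]).all(
                    axis=1
                ) & eligible
                if ok.sum() >= min_donors:
                    break
            self.pools.append(np.flatnonzero(ok))
        if any(len(p) == 0 for p in self.pools):
            raise ValueError("no donors available for some target genes")

    def draw(self, rng: np.random.Generator) -> list[str]:
        chosen: set[int] = set()
        out: list[str] = []
        for pool in self.pools:
            for _ in range(1000):
                pick = int(pool[rng.integers(0, len(pool))])
                if pick not in chosen:
                    break
            chosen.add(pick)
            out.append(self.universe[pick])
        return out


def sample_matched(
    genes: Sequence[str],
    attributes: pd.DataFrame,
    n_sets: int,
    bins_per_attribute: int = 10,
    seed: int = 0,
    attrs: Sequence[str] = ("degree", "cds_length", "fpkm"),
    min_donors: int = 20,
) -> list[list[str]]:
    """Random gene sets matched to the target on joint attribute bins."""
    sampler = _MatchedSampler(genes, attributes, attrs, bins_per_attribute, min_donors)
    rng = np.random.default_rng(seed)
    return [sampler.draw(rng) for _ in range(n_sets)]


def cluster_test(
    genes: Sequence[str],
    network: nx.Graph,
    attributes: pd.DataFrame,
    n_null: int = 10_000,
    seed: int = 0,
    bins_per_attribute: int = 10,
    attrs: Sequence[str] = ("degree", "cds_length", "fpkm"),
) -> ClusterTestResult:
    """Test whether a gene set clusters in the network vs matched nulls.

    Empirical p uses the add-one estimator (#{null >= obs} + 1)/(n + 1)
    and therefore can never reach zero; the weight sum is the primary
    statistic, with the link count reported alongside.
    """
    if n_null < 100:
        raise ValueError("n_null must be at least 100")
    observed, links = clustering_statistic(genes, network)
    sampler = _MatchedSampler(genes, attributes, attrs, bins_per_attribute)
    rng = np.random.default_rng(seed)
    null_stats = np.empty(n_null)
    null_links = np.empty(n_null, dtype=int)
    for i in range(n_null):
        s, l = clustering_statistic(sampler.draw(rng), network)
        null_stats[i] = s
        null_links[i] = l
    return ClusterTestResult(
        observed_stat=observed,
        observed_links=links,
        null_stats=null_stats,
        null_links=null_links,
        empirical_p=empirical_p_value(null_stats, observed),
        empirical_p_links=empirical_p_value(null_links, links),
        clustered_genes=_clustered_members(list(genes), network),
    )


def permuted_direction_test(
    up: Sequence[str],
    down: Sequence[str],
    attributes: pd.DataFrame,
    network: nx.Graph,
    n_null: int = 1000,
    seed: int = 0,
    **kwargs,
) -> tuple[ClusterTestResult | None, ClusterTestResult | None]:
    """Shuffle membership between the up and down sets, then test each.

    Direction-specific structure shows as significant clustering of the
    intact sets but not of the shuffled ones.  Sizes are preserved; returns
    (shuffled-up-result, shuffled-down-result), with None for an empty set.
    """
    if set(up) & set(down):
        raise ValueError("up and down sets must be disjoint")
    rng = np.random.default_rng(seed)
    combined = list(up) + list(down)
    perm = rng.permutation(len(combined))
    new_up = [combined[i] for i in perm[: len(up)]]
    new_down = [combined[i] for i in perm[len(up) :]]
    res_up = res_down = None
    if new_up:
        res_up = cluster_test(
            new_up, network, attributes, n_null=n_null,
            seed=int(rng.integers(2**31)), **kwargs,
        )
    else:
        warnings.warn("empty up set; testing down only", stacklevel=2)
    if new_down:
        res_down = cluster_test(
            new_down, network, attributes, n_null=n_null,
            seed=int(rng.integers(2**31)), **kwargs,
        )
    else:
        warnings.warn("empty down set; testing up only", stacklevel=2)
    return res_up, res_down


def top_k_genes(de_table: pd.DataFrame, k: int) -> list[str]:
    """The k most significant genes, deterministically tie-broken.

    Sort key: (p ascending, |Wald| descending, gene id ascending).
    """
    t = de_table.dropna(subset=["p_value"]).copy()
    t["_abs_stat"] = -t["wald_stat"].abs()
    t["_gene"] = t.index
    t = t.sort_values(["p_value", "_abs_stat", "_gene"], kind="stable")
    return list(t.index[:k])


def simulation_null_test(
    template: CountMatrix,
    k: int,
    n_sim: int,
    network: nx.Graph,
    observed_stat: float,
    seed: int = 0,
    group_sizes: tuple[int, int] = (3, 3),
    covariates: tuple[str, ...] = ("sex", "age"),
) -> dict:
    """Simulated-transcriptome null for the clustering statistic.

    Each simulated null dataset (means matched to the template, no
    condition effect) is run through the DE stage; the top-k genes by
    nominal p form a null signature whose clustering statistic is recorded.
    Returns the empirical p of ``observed_stat`` against these nulls plus
    the null statistics themselves.
    """
    from .de import fit_nb_glm_wald  # local import to avoid a cycle

    if n_sim < 1:
        raise ValueError("n_sim must be positive")
    if k > len(template.gene_ids):
        raise ValueError("k exceeds the number of genes")
    null_stats, null_links, skipped = [], [], 0
    for cm in simulate_matched_null(template, n_sim, group_sizes, seed):
        try:
            de = fit_nb_glm_wald(cm, covariates)
        except Exception as exc:  # degenerate draw; count and continue
            skipped += 1
            warnings.warn(f"simulated set skipped: {exc}", stacklevel=2)
            continue
        top = top_k_genes(de.table, k)
        s, l = clustering_statistic(top, network)
        null_stats.append(s)
        null_links.append(l)
    null_stats = np.array(null_stats)
    return {
        "empirical_p": empirical_p_value(null_stats, observed_stat),
        "null_stats": null_stats,
        "null_links": np.array(null_links),
        "n_skipped": skipped,
        "observed_stat": observed_stat,
    }


def build_integrated_network(
    datasets: Mapping[str, pd.DataFrame],
    benchmark: Mapping[str, set[str]],
    top_m: int = 1_000_000,
    bins: int = 10,
    min_pairs_per_bin: int = 100,
) -> nx.Graph:
    """Combine gene-pair evidence sources into one weighted network.

    Each dataset is a frame with columns (gene_a, gene_b, score).  Scores
    are quantile-binned; each bin is calibrated against a phenotype
    benchmark (two genes "share" if they have a common annotation term):
    LR(bin) = P(share | bin) / P(share), and a pair's weight is the sum of
    log LR over datasets, floored at zero (the network keeps only positive
    evidence).  The top_m heaviest pairs are retained.  Bins with fewer
    than ``min_pairs_per_bin`` benchmark pairs are merged downward.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    if not benchmark:
        raise ValueError("empty phenotype benchmark")
    gene_terms: dict[str, set[str]] = {}
    for term, members in benchmark.items():
        for g in members:
            gene_terms.setdefault(g, set()).add(term)

    def shares(a: str, b: str) -> bool:
        ta = gene_terms.get(a)
        return bool(ta and not ta.isdisjoint(gene_terms.get(b, set())))

    weights: dict[tuple[str, str], float] = {}
    for name, df in datasets.items():
        pairs = [
            (min(a, b), max(a, b))
            for a, b in zip(df["gene_a"], df["gene_b"])
        ]
        scores = df["score"].to_numpy(dtype=float)
        share_flags = np.array([shares(a, b) for a, b in pairs])
        overall = share_flags.mean()
        if overall == 0:
            raise ValueError(f"benchmark shares no annotations on dataset {name!r}")
        codes = pd.qcut(
            pd.Series(scores).rank(method="first"), q=bins, labels=False, duplicates="drop"
        ).to_numpy()
        # merge sparse bins downward so every calibration bin is supported
        for code in range(int(codes.max()), 0, -1):
            if (codes == code).sum() < min_pairs_per_bin:
                codes[codes == code] = code - 1
        lr = {}
        for code in np.unique(codes):
            sel = codes == code
            lr[code] = share_flags[sel].mean() / overall
        for (a, b), code in zip(pairs, codes):
            contrib = np.log(lr[code]) if lr[code] > 0 else -np.inf
            weights[(a, b)] = weights.get((a, b), 0.0) + contrib

    ranked = sorted(
        ((w, pair) for pair, w in weights.items() if w > 0), reverse=True
    )[:top_m]
    G = nx.Graph()
    for w, (a, b) in ranked:
        G.add_edge(a, b, weight=float(w))
    return G
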