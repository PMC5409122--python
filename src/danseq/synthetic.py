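"""Synthetic-data generators for every pipeline input.

The study design being emulated is a small case/control RNA-seq comparison
(three mutation-carrier lines vs three control lines) whose downstream
analyses need, besides the count matrix itself: a weighted gene functional
network with planted modules, phenotype annotation terms overlapping those
modules, per-gene attributes (CDS length, FPKM) for matched background
sampling, and drug-perturbation rank matrices with planted concordant or
anti-concordant perturbagens.

Counts are negative binomial with per-gene (mu, phi) pairs resampled
jointly from fitted estimates, so the mean-dispersion relationship of the
template data is preserved.  Truly differential genes have their case-group
mean multiplied or divided by a fold change (default 3); a small fraction
of genes receive a single-count outlier; the top fraction of extreme
dispersions is discarded before resampling (defaults: pOutlier = 0.01,
drop fraction = 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import CountMatrix, SignedGeneSet

__all__ = [
    "NBGeneParams",
    "SimulationConfig",
    "SyntheticNetworkConfig",
    "fit_nb_params",
    "default_nb_params",
    "resample_joint_params",
    "simulate_counts",
    "simulate_matched_null",
    "generate_synthetic_network",
    "generate_annotations",
    "generate_rank_matrix",
]


@dataclass(frozen=True)
class NBGeneParams:
    """Per-gene negative binomial parameters: variance = mu + phi * mu**2."""

    gene_id: str
    mu: float
    phi: float
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.mu < 0 or self.phi < 0:
            raise ValueError("mu and phi must be non-negative")


@dataclass
class SimulationConfig:
    """Settings for the case/control count simulation.

    ``fold_diff`` is the expression fold change of truly differential
    genes, ``p_diff`` the fraction of genes that are differential,
    ``p_outlier`` the per-gene probability of a single-count outlier and
    ``drop_extreme_dispersion`` the top fraction of phi estimates
    discarded before joint resampling.
    """

    n_genes: int = 2000
    n_cases: int = 3
    n_controls: int = 3
    fold_diff: float = 3.0
    p_diff: float = 0.1
    p_outlier: float = 0.01
    outlier_mech: str = "single"
    drop_extreme_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_diff", "p_outlier", "drop_extreme_dispersion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fold_diff <= 1.0:
            raise ValueError("fold_diff must exceed 1")
        if self.outlier_mech != "single":
            raise ValueError("only the 'single'-count outlier mechanism is supported")
        if self.n_genes < 1 or self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_genes, n_cases and n_controls must be positive")


@dataclass
class SyntheticNetworkConfig:
    """Planted-module weighted network settings.

    Modules occupy disjoint gene blocks; within-module edges are denser and
    heavier than background edges, so module gene sets carry a larger
    within-set weight sum than random sets of equal size.
    """

    n_genes: int = 1000
    module_sizes: Sequence[int] = (50, 50)
    within_density: float = 0.5
    background_density: float = 0.01
    within_weight_mean: float = 2.0
    background_weight_mean: float = 0.5
    weight_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        for name in ("within_density", "background_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def gene_names(n: int, prefix: str = "G") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# NB parameter fitting and count simulation
# ---------------------------------------------------------------------------

def fit_nb_params(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Method-of-moments (mu, phi) per gene, retained as joint pairs.

    mu is the sample mean and phi = max(0, (var - mean) / mean**2) with the
    unbiased sample variance; all-zero genes get (0, 0) and are flagged.
    Pairs are meant to be resampled jointly, never marginally.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = mat.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("need at least two samples per gene to fit dispersion")
    mu = arr.mean(axis=1)
    var = arr.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(mu > 0, np.maximum(0.0, (var - mu) / mu**2), 0.0)
    return pd.DataFrame(
        {"mu": mu, "phi": phi, "flagged": mu == 0}, index=mat.index.rename("gene_id")
    )


def default_nb_params(n_genes: int = 500, seed: int = 20170117) -> pd.DataFrame:
    """Built-in synthetic template (mu, phi) table.

    A stand-in for parameters fitted to real sorted-line counts: log-normal
    means (median ~60 counts) and a dispersion trend falling with the mean
    (phi = 0.04 + 1.2 / mu^0.7, log-normal scatter), i.e. a biological CV of
    roughly 0.2-0.35 at moderate counts rising at low counts — the profile
    bulk RNA-seq fits on donor-derived cell lines typically show.  Fully
    synthetic; fixed seed makes it a stable package-level default.
    """
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(mean=np.log(60.0), sigma=1.4, size=n_genes)
    phi = (0.04 + 1.2 / mu**0.7) * rng.lognormal(0.0, 0.35, size=n_genes)
    return pd.DataFrame(
        {"mu": mu, "phi": phi, "flagged": False},
        index=pd.Index(gene_names(n_genes, "T"), name="gene_id"),
    )


def _drop_extreme_phi(params: pd.DataFrame, fraction: float) -> pd.DataFrame:
    """Discard exactly the top `fraction` of phi values (floor of n*fraction)."""
    n_drop = int(np.floor(len(params) * fraction))
    if n_drop == 0:
        return params
    order = np.argsort(params["phi"].to_numpy(), kind="stable")
    return params.iloc[order[: len(params) - n_drop]]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Elementwise NB(mu, phi) draw; phi == 0 degenerates to Poisson."""
    mu = np.asarray(mu, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    out = np.zeros(mu.shape, dtype=np.int64)
    pois = (phi <= 0) | (mu <= 0)
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        r = 1.0 / phi[~pois]
        p = r / (r + mu[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


def _sample_meta(rng: np.random.Generator, n_cases: int, n_controls: int) -> pd.DataFrame:
    """Covariates for simulated lines: alternating sex within each group and
    donor ages spanning the adult range the study design uses (36-80 years)."""
    ids = [f"case_{i+1}" for i in range(n_cases)] + [f"ctrl_{i+1}" for i in range(n_controls)]
    condition = ["case"] * n_cases + ["control"] * n_controls
    sex = [("M", "F")[i % 2] for i in range(n_cases)] + [
        ("F", "M")[i % 2] for i in range(n_controls)
    ]
    age = rng.uniform(36.0, 80.0, size=n_cases + n_controls).round(1)
    return pd.DataFrame(
        {"condition": condition, "sex": sex, "age": age}, index=pd.Index(ids, name="sample_id")
    )


def resample_joint_params(
    params: pd.DataFrame,
    n_genes: int,
    drop_extreme_dispersion: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint bootstrap of fitted (mu, phi) pairs after dispersion trimming.

    Pairs are resampled with replacement as units (never marginally), so
    the empirical mean-dispersion dependence of the template is preserved.
    """
    if len(params) == 0:
        raise ValueError("empty parameter table")
    kept = _drop_extreme_phi(params, drop_extreme_dispersion)
    if len(kept) == 0:
        raise ValueError("no parameter pairs left after dispersion filtering")
    take = rng.integers(0, len(kept), size=n_genes)
    return kept["mu"].to_numpy()[take], kept["phi"].to_numpy()[take]


def simulate_counts(
    config: SimulationConfig, params: pd.DataFrame | None = None
) -> tuple[CountMatrix, pd.Series]:
    """Simulate a case/control count matrix with known truth labels.

    Returns the counts plus a per-gene label Series taking values
    ``null``, ``up_in_case`` or ``down_in_case``.
    """
    if params is None:
        params = default_nb_params()
    rng = np.random.default_rng(config.seed)
    mu, phi = resample_joint_params(
        params, config.n_genes, config.drop_extreme_dispersion, rng
    )

    genes = gene_names(config.n_genes)
    n_de = int(round(config.p_diff * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    n_up = n_de // 2
    labels = pd.Series("null", index=pd.Index(genes, name="gene_id"), name="label")
    labels.iloc[de_idx[:n_up]] = "up_in_case"
    labels.iloc[de_idx[n_up:]] = "down_in_case"

    n = config.n_cases + config.n_controls
    mu_mat = np.tile(mu[:, None], (1, n))
    case_cols = slice(0, config.n_cases)
    up = (labels == "up_in_case").to_numpy()
    down = (labels == "down_in_case").to_numpy()
    mu_mat[up, case_cols] *= config.fold_diff
    mu_mat[down, case_cols] /= config.fold_diff

    arr = _nb_draw(rng, mu_mat, phi[:, None])

    # "single"-count outliers: one randomly chosen sample of an affected gene
    # has its count inflated by a uniform [2, 10] factor
    hit = rng.random(config.n_genes) < config.p_outlier
    if hit.any():
        cols = rng.integers(0, n, size=int(hit.sum()))
        factors = rng.uniform(2.0, 10.0, size=int(hit.sum()))
        rows = np.flatnonzero(hit)
        arr[rows, cols] = np.round(arr[rows, cols] * factors).astype(np.int64)

    meta = _sample_meta(rng, config.n_cases, config.n_controls)
    counts = pd.DataFrame(arr, index=labels.index, columns=meta.index)
    return CountMatrix(counts, meta), labels


def simulate_matched_null(
    template: CountMatrix,
    n_sets: int,
    group_sizes: tuple[int, int] = (3, 3),
    seed: int = 0,
    k_donors: int = 50,
) -> Iterator[CountMatrix]:
    """Lazily yield null case/control matrices matched to the template means.

    Each emitted matrix has one row per template gene with NB counts whose
    mean equals that gene's mean count across the template samples and no
    condition effect.  The dispersion is drawn from the fitted joint
    (mu, phi) distribution conditional on the nearest means: for each gene,
    a donor is picked among the ``k_donors`` genes closest in log-mean and
    its phi used, so the mean-dispersion trend of the template carries over.
    """
    if n_sets <= 0:
        raise ValueError("n_sets must be positive")
    params = fit_nb_params(template)
    mu = params["mu"].to_numpy()
    phi = params["phi"].to_numpy()
    log_mu = np.log1p(mu)
    order = np.argsort(log_mu, kind="stable")
    rank_of = np.empty_like(order)
    rank_of[order] = np.arange(len(order))
    k = min(k_donors, len(mu))
    # donor pool for gene g: the k genes adjacent in the log-mean ordering
    lo = np.clip(rank_of - k // 2, 0, max(0, len(mu) - k))
    rng = np.random.default_rng(seed)
    n_cases, n_controls = group_sizes
    genes = template.counts.index
    for s in range(n_sets):
        pick = lo + rng.integers(0, k, size=len(mu))
        phi_draw = phi[order[pick]]
        arr = _nb_draw(rng, np.tile(mu[:, None], (1, n_cases + n_controls)), phi_draw[:, None])
        meta = _sample_meta(rng, n_cases, n_controls)
        yield CountMatrix(pd.DataFrame(arr, index=genes, columns=meta.index), meta)


# ---------------------------------------------------------------------------
# Network, annotations, attributes
# ---------------------------------------------------------------------------

def generate_synthetic_network(cfg: SyntheticNetworkConfig) -> nx.Graph:
    """Weighted undirected gene network with planted functional modules.

    Module membership is stored in ``G.graph["modules"]`` (list of gene
    lists); module blocks are disjoint by construction.  Weights are
    log-normal, heavier within modules.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = gene_names(cfg.n_genes)
    G = nx.Graph()
    G.add_nodes_from(genes)
    modules: list[list[str]] = []
    start = 0
    for size in cfg.module_sizes:
        modules.append(genes[start : start + size])
        start += size
    module_of = {}
    for m, members in enumerate(modules):
        for g in members:
            module_of[g] = m

    iu, ju = np.triu_indices(cfg.n_genes, k=1)
    same = np.array(
        [module_of.get(genes[a], -1) == module_of.get(genes[b], -2) for a, b in zip(iu, ju)]
    )
    dens = np.where(same, cfg.within_density, cfg.background_density)
    present = rng.random(len(iu)) < dens
    means = np.where(same, cfg.within_weight_mean, cfg.background_weight_mean)
    weights = rng.lognormal(np.log(means), cfg.weight_sigma)
    for a, b, w in zip(iu[present], ju[present], weights[present]):
        G.add_edge(genes[a], genes[b], weight=float(w))
    G.graph["modules"] = modules
    return G


def generate_annotations(
    genes: Sequence[str],
    modules: Sequence[Sequence[str]],
    n_terms: int = 20,
    overlap_fraction: float = 0.8,
    seed: int = 0,
    term_size_range: tuple[int, int] = (10, 200),
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Phenotype-style annotation terms plus per-gene attributes.

    The first ``len(modules)`` terms are planted: a fraction
    ``overlap_fraction`` of each term's genes come from the corresponding
    module (term size equal to the module size and fraction 1 reproduces the
    module exactly).  Remaining terms are random subsets.  Attributes (CDS
    length in bp and mean FPKM) are log-normal, mimicking their heavy right
    tails in real annotation tables.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    terms: dict[str, set[str]] = {}
    lo, hi = term_size_range
    for t in range(n_terms):
        name = f"TERM:{t:04d}"
        if t < len(modules):
            module = list(modules[t])
            size = min(max(lo, len(module)), hi)
            n_from_module = int(round(overlap_fraction * min(size, len(module))))
            chosen = list(rng.choice(module, size=n_from_module, replace=False))
            pool = [g for g in genes if g not in set(chosen)]
            chosen += list(rng.choice(pool, size=size - n_from_module, replace=False))
        else:
            size = int(rng.integers(lo, hi + 1))
            chosen = list(rng.choice(genes, size=min(size, len(genes)), replace=False))
        terms[name] = set(chosen)
    attributes = pd.DataFrame(
        {
            "cds_length": rng.lognormal(np.log(1500.0), 0.7, size=len(genes)),
            "fpkm": rng.lognormal(np.log(10.0), 1.0, size=len(genes)),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return terms, attributes


# ---------------------------------------------------------------------------
# Drug-perturbation rank matrices
# ---------------------------------------------------------------------------

def generate_rank_matrix(
    n_probes: int,
    perturbagens: Mapping[str, int],
    planted_signature: SignedGeneSet,
    concordance: Mapping[str, float],
    probe_map: Mapping[str, str],
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Probe x instance rank matrix with planted perturbagen signatures.

    Each column is a permutation of 1..n_probes (1 = most up-regulated by
    the perturbation).  For a perturbagen with concordance c > 0, probes of
    the signature's up genes are squeezed toward the top and down-gene
    probes toward the bottom in every instance; c < 0 swaps the directions;
    |c| = 1 places them in solid blocks.  Returns (ranks, instance_meta).
    """
    probes = [f"P{i:05d}" for i in range(n_probes)]
    mapped = set(probe_map)
    gene_probes: dict[str, list[str]] = {}
    for p, g in probe_map.items():
        gene_probes.setdefault(g, []).append(p)
    for g in planted_signature.genes:
        if g not in gene_probes:
            raise ValueError(f"signature gene {g} has no probe in probe_map")
    if not mapped <= set(probes):
        raise ValueError("probe_map refers to probes outside the matrix")

    probe_index = {p: i for i, p in enumerate(probes)}
    up_probes = np.array(
        [probe_index[p] for g in planted_signature.up for p in gene_probes[g]], dtype=int
    )
    down_probes = np.array(
        [probe_index[p] for g in planted_signature.down for p in gene_probes[g]], dtype=int
    )

    rng = np.random.default_rng(seed)
    columns, pert_names = [], []
    ranks = {}
    for pert, n_inst in perturbagens.items():
        c = float(concordance.get(pert, 0.0))
        if not -1.0 <= c <= 1.0:
            raise ValueError("concordance must lie in [-1, 1]")
        for i in range(n_inst):
            col = f"{pert}_{i+1}"
            u = rng.random(n_probes)
            if c > 0:
                u[up_probes] *= 1.0 - c
                u[down_probes] = c + u[down_probes] * (1.0 - c)
            elif c < 0:
                u[down_probes] *= 1.0 + c
                u[up_probes] = -c + u[up_probes] * (1.0 + c)
            order = np.argsort(u, kind="stable")
            r = np.empty(n_probes, dtype=np.int64)
            r[order] = np.arange(1, n_probes + 1)
            assert len(np.unique(r)) == n_probes, "column ranks must be a permutation"
            ranks[col] = r
            columns.append(col)
            pert_names.append(pert)
    rank_df = pd.DataFrame(ranks, index=pd.Index(probes, name="probe_id"))
    meta = pd.DataFrame(
        {"perturbagen": pert_names}, index=pd.Index(columns, name="instance_id")
    )
    return rank_df, meta
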