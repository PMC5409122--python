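"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("case", "control")
SEXES = ("M", "F")


@dataclass
class CountMatrix:
    """Gene x sample integer read counts with per-sample covariates.

    ``counts`` is indexed by gene id with one column per sample;
    ``meta`` is indexed by sample id with columns ``condition``
    ("case"/"control"), ``sex`` ("M"/"F") and ``age`` (years).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.issubdtype(np.asarray(self.counts).dtype, np.integer):
            arr = np.asarray(self.counts)
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if list(self.counts.columns) != list(self.meta.index):
            if set(self.counts.columns) != set(self.meta.index):
                raise ValueError("sample ids in counts and meta disagree")
            self.meta = self.meta.loc[self.counts.columns]
        missing = {"condition", "sex", "age"} - set(self.meta.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        bad = set(self.meta["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, condition: str) -> list[str]:
        return list(self.meta.index[self.meta["condition"] == condition])


@dataclass
class SignedGeneSet:
    """Up- and down-regulated gene lists forming a disease signature."""

    up: list[str]
    down: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValueError(f"up/down sets overlap: {sorted(overlap)[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.up) + list(self.down)

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


@dataclass
class ClusterTestResult:
    """Observed clustering statistic with its permutation null."""

    observed_stat: float
    observed_links: int
    null_stats: np.ndarray
    null_links: np.ndarray
    empirical_p: float
    empirical_p_links: float
    clustered_genes: list[str] = field(default_factory=list)

    @property
    def n_null(self) -> int:
        return len(self.null_stats)

    def summary(self) -> dict:
        qs = np.quantile(self.null_stats, [0.05, 0.25, 0.5, 0.75, 0.95]) if self.n_null else []
        return {
            "observed_stat": float(self.observed_stat),
            "observed_links": int(self.observed_links),
            "n_null": int(self.n_null),
            "empirical_p": float(self.empirical_p),
            "empirical_p_links": float(self.empirical_p_links),
            "n_clustered_genes": len(self.clustered_genes),
            "null_quantiles": [float(q) for q in qs],
        }


def empirical_p_value(null: np.ndarray, observed: float) -> float:
    """Add-one empirical p: (#{null >= observed} + 1) / (n + 1).

    Never returns 0; equals 1/(n+1) when the observed value beats every
    null draw.
    """
    null = np.asarray(null, dtype=float)
    return (float(np.sum(null >= observed)) + 1.0) / (null.size + 1.0)
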