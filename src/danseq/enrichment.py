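"""Matched-background phenotype-term enrichment for a disease signature.

Given a signed DE gene set and gene -> phenotype-term annotations (mouse
orthologue knock-out phenotypes in the motivating analysis), each term's
observed signature overlap is compared with random gene sets drawn from
the annotated universe and matched to the signature on CDS length and
expression (FPKM) quantile bins.  Degree matching is deliberately not used
here — the background is the annotated-orthologue universe, not the
network.  Per-term empirical p-values use the add-one estimator and are
BH-adjusted across the tested term family only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import SignedGeneSet, empirical_p_value
from .de import adjust_bh
from .network import _MatchedSampler

__all__ = ["enrich", "direction_breakdown", "EnrichmentResult", "propagate_hierarchy"]


@dataclass
class EnrichmentResult:
    """Per-term enrichment table plus cached null sets for reuse."""

    table: pd.DataFrame  # term, observed, expected, empirical_p, q_value
    signature_in_universe: list[str]  # genes that entered matching, in draw order
    null_sets: list[list[str]]  # cached; aligned positionally with the signature
    term_sets: dict[str, set[str]] | None = None  # tested terms' gene sets


def propagate_hierarchy(
    annotations: Mapping[str, set[str]], parents: Mapping[str, Sequence[str]]
) -> dict[str, set[str]]:
    """Propagate annotations up a term hierarchy (child gene => ancestor gene)."""
    out = {t: set(g) for t, g in annotations.items()}

    def ancestors(t: str) -> set[str]:
        seen: set[str] = set()
        stack = list(parents.get(t, []))
        while stack:
            p = stack.pop()
            if p not in seen:
                seen.add(p)
                stack.extend(parents.get(p, []))
        return seen

    for t, genes in annotations.items():
        for anc in ancestors(t):
            out.setdefault(anc, set()).update(genes)
    return out


def enrich(
    signature: SignedGeneSet,
    annotations: Mapping[str, set[str]],
    attributes: pd.DataFrame,
    terms_to_test: Sequence[str] | None = None,
    n_null: int = 1000,
    seed: int = 0,
    bins_per_attribute: int = 10,
) -> EnrichmentResult:
    """Matched-null enrichment of the signature in annotation terms.

    The universe is every gene with at least one annotation; the signature
    is restricted to the universe before matching.  ``expected`` is the
    mean overlap count across null sets, ``empirical_p`` the add-one upper
    tail probability, ``q_value`` the BH adjustment over tested terms.
    """
    if n_null < 100:
        raise ValueError("n_null must be at least 100")
    universe = sorted(set().union(*annotations.values())) if annotations else []
    if not universe:
        raise ValueError("empty annotation set")
    sig = [g for g in signature.genes if g in set(universe)]
    if not sig:
        warnings.warn("signature disjoint from the annotated universe", stacklevel=2)
        return EnrichmentResult(
            table=pd.DataFrame(
                columns=["observed", "expected", "empirical_p", "q_value"]
            ),
            signature_in_universe=[],
            null_sets=[],
        )
    attrs_u = attributes.loc[attributes.index.intersection(universe)]
    sampler = _MatchedSampler(sig, attrs_u, attrs=("cds_length", "fpkm"), bins=bins_per_attribute)
    rng = np.random.default_rng(seed)
    null_sets = [sampler.draw(rng) for _ in range(n_null)]

    if terms_to_test is None:
        terms_to_test = sorted(annotations)
    rows = {}
    sig_set = set(sig)
    for term in terms_to_test:
        members = annotations.get(term, set())
        if not members & set(universe):
            warnings.warn(f"term {term!r} has no universe overlap; skipped", stacklevel=2)
            continue
        observed = len(sig_set & members)
        null_counts = np.array([len(members.intersection(ns)) for ns in null_sets])
        rows[term] = {
            "observed": observed,
            "expected": float(null_counts.mean()),
            "empirical_p": empirical_p_value(null_counts, observed),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    if len(table):
        table["q_value"] = adjust_bh(table["empirical_p"].to_numpy())
        table.index.name = "term"
    term_sets = {t: set(annotations[t]) for t in table.index}
    return EnrichmentResult(
        table=table,
        signature_in_universe=sig,
        null_sets=null_sets,
        term_sets=term_sets,
    )


def direction_breakdown(
    result: EnrichmentResult, signature: SignedGeneSet
) -> pd.DataFrame:
    """Split each term's enrichment by signature direction.

    Null replacements are matched per signature position, so the null for
    e.g. the down-regulated subset is the same cached null sets restricted
    to the positions the down genes occupy — no re-sampling needed.
    Returns per-term up/down observed counts (which partition the total)
    and per-direction empirical p-values.
    """
    if result.term_sets is None:
        raise ValueError("result lacks cached term sets; rerun enrich()")
    sig = result.signature_in_universe
    up_set, down_set = set(signature.up), set(signature.down)
    pos_up = [i for i, g in enumerate(sig) if g in up_set]
    pos_down = [i for i, g in enumerate(sig) if g in down_set]
    rows = {}
    for term, members in result.term_sets.items():
        obs_up = sum(1 for i in pos_up if sig[i] in members)
        obs_down = sum(1 for i in pos_down if sig[i] in members)
        null_up = np.array(
            [sum(1 for i in pos_up if ns[i] in members) for ns in result.null_sets]
        )
        null_down = np.array(
            [sum(1 for i in pos_down if ns[i] in members) for ns in result.null_sets]
        )
        rows[term] = {
            "observed_up": obs_up,
            "observed_down": obs_down,
            "p_up": empirical_p_value(null_up, obs_up),
            "p_down": empirical_p_value(null_down, obs_down),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "term"
    return out
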