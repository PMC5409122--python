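"""Readers and writers for the pipeline's plain-text formats.

Everything is TSV (counts, metadata, edge lists, attributes, rank
matrices), GMT for gene sets, Newick for dendrograms and JSON for result
bundles.  Readers validate and report the offending line number on
malformed input; every write/read pair round-trips.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .containers import CountMatrix, SignedGeneSet

RESULTS_SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Malformed input file; message carries the line number."""


def read_counts(path: str | Path) -> pd.DataFrame:
    """Counts TSV: header row of sample ids, one gene per row."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]]
        raise FormatError(f"{path}: non-numeric counts in columns {list(bad)}")
    rows_bad = np.flatnonzero((arr < 0).any(axis=1) | (arr != np.round(arr)).any(axis=1))
    if rows_bad.size:
        # +2: one header line plus 1-based numbering
        raise FormatError(
            f"{path}: line {rows_bad[0] + 2}: counts must be non-negative integers"
        )
    return df.astype(np.int64)


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    missing = {"condition", "sex", "age"} - set(meta.columns)
    if missing:
        raise FormatError(f"{path}: metadata missing columns {sorted(missing)}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t")


def read_count_matrix(counts_path: str | Path, meta_path: str | Path) -> CountMatrix:
    return CountMatrix(read_counts(counts_path), read_metadata(meta_path))


def read_edge_list(path: str | Path) -> nx.Graph:
    """Weighted edge list TSV with header gene_a/gene_b/weight."""
    G = nx.Graph()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["gene_a", "gene_b", "weight"]:
            raise FormatError(f"{path}: line 1: expected header gene_a\tgene_b\tweight")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 columns")
            a, b, w = parts
            try:
                w = float(w)
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: weight not numeric") from None
            if not np.isfinite(w) or w <= 0:
                raise FormatError(f"{path}: line {lineno}: weight must be finite and > 0")
            if a == b:
                raise FormatError(f"{path}: line {lineno}: self-loop {a}")
            G.add_edge(a, b, weight=w)
    return G


def write_edge_list(G: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, data in sorted(G.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('weight', 1.0):.10g}\n")


def read_gmt(path: str | Path) -> dict[str, dict]:
    """GMT: term <tab> description <tab> gene1 <tab> gene2 ..."""
    out: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT rows need term, description and >=1 gene"
                )
            out[parts[0]] = {"description": parts[1], "genes": parts[2:]}
    return out


def write_gmt(terms: Mapping[str, dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, entry in terms.items():
            genes = "\t".join(entry["genes"])
            fh.write(f"{term}\t{entry.get('description', '')}\t{genes}\n")


def signature_to_gmt(sig: SignedGeneSet, path: str | Path) -> None:
    write_gmt(
        {
            "up": {"description": "increased in case lines", "genes": list(sig.up)},
            "down": {"description": "decreased in case lines", "genes": list(sig.down)},
        },
        path,
    )


def signature_from_gmt(path: str | Path) -> SignedGeneSet:
    terms = read_gmt(path)
    return SignedGeneSet(
        up=terms.get("up", {}).get("genes", []),
        down=terms.get("down", {}).get("genes", []),
    )


def read_attributes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "cds_length" in df.columns and (df["cds_length"] <= 0).any():
        bad = int(np.flatnonzero(df["cds_length"] <= 0)[0])
        raise FormatError(f"{path}: line {bad + 2}: cds_length must be positive")
    return df


def write_attributes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_rank_matrix(path: str | Path) -> pd.DataFrame:
    """Rank-matrix TSV: first column probe id, remaining columns instances."""
    df = pd.read_csv(path, sep="\t", index_col=0).astype(np.int64)
    n = len(df)
    expect = np.arange(1, n + 1)
    for col in df.columns:
        if not np.array_equal(np.sort(df[col].to_numpy()), expect):
            raise FormatError(f"{path}: column {col!r} is not a permutation of 1..{n}")
    return df


def write_rank_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_probe_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["probe_id", "gene_id"]:
        raise FormatError(f"{path}: expected columns probe_id, gene_id")
    dup = df["probe_id"].duplicated()
    if dup.any():
        raise FormatError(f"{path}: duplicate probe ids (each probe maps to at most one gene)")
    return dict(zip(df["probe_id"], df["gene_id"]))


def write_probe_map(probe_map: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"probe_id": list(probe_map), "gene_id": list(probe_map.values())}
    ).to_csv(path, sep="\t", index=False)


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick + "\n")


def write_results_json(results: Mapping, path: str | Path) -> None:
    payload = {"schema_version": RESULTS_SCHEMA_VERSION, **results}
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def read_results_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
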