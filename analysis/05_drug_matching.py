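#!/usr/bin/env python
"""Drug-signature connectivity matching.

Scores every perturbagen's instances against the disease signature with
the KS-based combined connectivity score (positive = mimics the disease
profile, negative = opposes it), attaches permutation p-values, and
extracts the genes each perturbagen moves consistently (all probes in the
top/bottom-k ranks of all instances).  Writes results/connectivity.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from danseq import io as dio
from danseq.cmap import consistent_genes, perturbagen_significance
from danseq.pipeline import stage_seed


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--inputs", type=Path, default=Path("results/inputs"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-perm", type=int, default=999)
    ap.add_argument("--top-k", type=int, default=1000)
    args = ap.parse_args()

    sig = dio.signature_from_gmt(args.out / "signature.gmt")
    ranks = dio.read_rank_matrix(args.inputs / "rankmatrix.tsv")
    inst = pd.read_csv(args.inputs / "instances.tsv", sep="\t", index_col=0)
    probe_map = dio.read_probe_map(args.inputs / "probemap.tsv")

    rows = {}
    for pert in sorted(inst["perturbagen"].unique()):
        res = perturbagen_significance(
            sig, ranks, inst, pert, probe_map, n_perm=args.n_perm,
            seed=stage_seed(args.seed, f"cmap-{pert}"),
        )
        moved = consistent_genes(ranks, inst, pert, probe_map, top_k=args.top_k)
        rows[pert] = {
            "mean_combined_score": round(res.observed, 4),
            "p_value": res.p_value,
            "n_instances": len(res.instance_scores),
            "n_consistent_up": len(moved.up),
            "n_consistent_down": len(moved.down),
        }
        direction = ("mimics" if res.observed > 0 else "opposes")
        print(f"{pert}: combined score {res.observed:+.3f} (p = {res.p_value:.4g}) "
              f"- {direction} the signature; consistently moves "
              f"{len(moved.up)} genes up, {len(moved.down)} down")

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "perturbagen"
    table.to_csv(args.out / "connectivity.tsv", sep="\t")


if __name__ == "__main__":
    main()
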