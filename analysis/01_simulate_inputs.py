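#!/usr/bin/env python
"""Generate the synthetic study inputs.

Emulates the study design: counts for 3 mutation-carrier and 3 control
purified-neuron lines (2000 genes, 10% truly differential at fold 3,
1% single-count outliers), a weighted functional network whose two planted
modules sit exactly on the truly up- and down-regulated genes, phenotype
annotation terms overlapping those modules, per-gene CDS-length/FPKM
attributes, and a drug-perturbation rank matrix with one mimicking and one
reversing perturbagen.  Everything lands under results/inputs/.
"""

import argparse
from pathlib import Path

import networkx as nx

from danseq import io as dio
from danseq.containers import SignedGeneSet
from danseq.pipeline import stage_seed
from danseq.synthetic import (
    SimulationConfig,
    SyntheticNetworkConfig,
    generate_annotations,
    generate_rank_matrix,
    generate_synthetic_network,
    simulate_counts,
)

N_GENES = 2000


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/inputs"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    cm, truth = simulate_counts(
        SimulationConfig(n_genes=N_GENES, p_diff=0.1, seed=stage_seed(args.seed, "counts"))
    )
    dio.write_counts(cm.counts, out / "counts.tsv")
    dio.write_metadata(cm.meta, out / "meta.tsv")
    truth.to_frame().to_csv(out / "truth.tsv", sep="\t")

    up = list(truth.index[truth == "up_in_case"])
    down = list(truth.index[truth == "down_in_case"])
    G = generate_synthetic_network(
        SyntheticNetworkConfig(
            n_genes=N_GENES, module_sizes=(len(up), len(down)),
            seed=stage_seed(args.seed, "network"),
        )
    )
    order = up + down + [g for g in truth.index if g not in set(up) | set(down)]
    G = nx.relabel_nodes(G, dict(zip(sorted(G.nodes), order)))
    dio.write_edge_list(G, out / "network.tsv")

    terms, attrs = generate_annotations(
        list(truth.index), [up, down], n_terms=12, overlap_fraction=0.9,
        seed=stage_seed(args.seed, "annotations"),
    )
    dio.write_gmt(
        {t: {"description": "synthetic phenotype term", "genes": sorted(g)}
         for t, g in terms.items()},
        out / "annotations.gmt",
    )
    dio.write_attributes(attrs, out / "attributes.tsv")

    genes = list(truth.index)
    probe_map = {f"P{i:05d}": genes[i % N_GENES] for i in range(3 * N_GENES)}
    planted = SignedGeneSet(up=up[:30], down=down[:20])
    ranks, inst = generate_rank_matrix(
        3 * N_GENES, {"mimic": 4, "reverser": 4, "inert": 4}, planted,
        {"mimic": 0.9, "reverser": -0.9}, probe_map,
        seed=stage_seed(args.seed, "rank-matrix"),
    )
    dio.write_rank_matrix(ranks, out / "rankmatrix.tsv")
    inst.to_csv(out / "instances.tsv", sep="\t")
    dio.write_probe_map(probe_map, out / "probemap.tsv")

    print(f"inputs written to {out}: {N_GENES} genes, "
          f"{len(up)} up / {len(down)} down truly differential, "
          f"{G.number_of_edges()} network edges, {len(terms)} annotation terms")


if __name__ == "__main__":
    main()
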