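#!/usr/bin/env python
"""Phenotype-term enrichment of the signature, matched background.

Compares each annotation term's overlap with the signature against random
gene sets drawn from the annotated universe and matched on CDS length and
FPKM, then splits each enrichment by direction of expression change.
Writes results/enrichment.tsv.
"""

import argparse
from pathlib import Path

from danseq import io as dio
from danseq.enrichment import direction_breakdown, enrich
from danseq.pipeline import stage_seed


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--inputs", type=Path, default=Path("results/inputs"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-null", type=int, default=999)
    args = ap.parse_args()

    sig = dio.signature_from_gmt(args.out / "signature.gmt")
    gmt = dio.read_gmt(args.inputs / "annotations.gmt")
    annotations = {t: set(e["genes"]) for t, e in gmt.items()}
    attrs = dio.read_attributes(args.inputs / "attributes.tsv")

    res = enrich(sig, annotations, attrs, n_null=args.n_null,
                 seed=stage_seed(args.seed, "enrichment"))
    table = res.table.join(direction_breakdown(res, sig))
    table.sort_values("empirical_p").to_csv(args.out / "enrichment.tsv", sep="\t")

    hits = table[table["q_value"] < 0.05].sort_values("empirical_p")
    print(f"{len(table)} terms tested against {args.n_null} matched null sets; "
          f"{len(hits)} enriched at q < 0.05")
    for term, row in hits.iterrows():
        print(f"  {term}: {int(row.observed)} observed vs {row.expected:.2f} expected "
              f"(q = {row.q_value:.3g}; up/down split {int(row.observed_up)}/"
              f"{int(row.observed_down)})")


if __name__ == "__main__":
    main()
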