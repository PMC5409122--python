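"""End-to-end orchestration: DE -> signature -> convergence -> enrichment -> drugs.

All randomness flows from a single master seed; each stage derives its own
seed as SHA-256(master_seed ":" stage_name) mod 2^31, so adding a stage
never perturbs the draws of earlier ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import cmap as cmap_mod
from . import enrichment as enrich_mod
from . import io as dio
from . import network as net_mod
from .de import fit_nb_glm_wald, select_signature

logger = logging.getLogger("danseq")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str) -> None:
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


def stage_seed(master_seed: int, stage_name: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{stage_name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    counts: str
    meta: str
    network: str
    attributes: str
    annotations: str
    rank_matrix: str
    instance_meta: str
    probe_map: str
    nominal_p: float = 0.01
    fdr: float = 0.1
    k: int = 168
    n_null: int = 1000
    n_sim: int = 100
    n_perm: int = 1000
    top_k: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.nominal_p <= 1 or not 0 < self.fdr <= 1:
            raise ValueError("nominal_p and fdr must lie in (0, 1]")
        if min(self.k, self.n_null, self.n_sim, self.n_perm, self.top_k) <= 0:
            raise ValueError("k, n_null, n_sim, n_perm and top_k must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in (
            "counts", "meta", "network", "attributes",
            "annotations", "rank_matrix", "instance_meta", "probe_map",
        ):
            p = getattr(self, name)
            if not Path(p).exists():
                raise StageError("validate", "missing-input", f"{name} path not found: {p}")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full analysis chain and write a result bundle.

    Artifacts written to ``out_dir``: de.tsv, signature.gmt,
    cluster_tests.json, enrichment.tsv, connectivity.tsv, manifest.json.
    Returns the manifest dictionary.
    """
    t0 = time.time()
    config.validate_paths()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn):
        logger.info(json.dumps({"event": "stage-start", "stage": name}))
        try:
            result = fn()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, "stage-failure", str(exc)) from exc
        logger.info(json.dumps({"event": "stage-done", "stage": name}))
        return result

    cm = _stage("load", lambda: dio.read_count_matrix(config.counts, config.meta))
    network = _stage("load-network", lambda: dio.read_edge_list(config.network))
    attributes = net_mod.network_attributes(network, dio.read_attributes(config.attributes))

    de = _stage("de", lambda: fit_nb_glm_wald(cm))
    de_path = out / "de.tsv"
    de.table.to_csv(de_path, sep="\t")

    signature = _stage("signature", lambda: select_signature(de, nominal_p=config.nominal_p))
    sig_path = out / "signature.gmt"
    dio.signature_to_gmt(signature, sig_path)

    def _cluster_stage():
        tests = {}
        for label, genes in (
            ("all", signature.genes),
            ("up", signature.up),
            ("down", signature.down),
        ):
            if not genes:
                continue
            res = net_mod.cluster_test(
                genes, network, attributes,
                n_null=config.n_null,
                seed=stage_seed(config.seed, f"cluster-{label}"),
            )
            tests[label] = res.summary()
        sim = net_mod.simulation_null_test(
            cm,
            k=min(config.k, len(cm.gene_ids)),
            n_sim=config.n_sim,
            network=network,
            observed_stat=tests["all"]["observed_stat"],
            seed=stage_seed(config.seed, "simulation-null"),
        )
        tests["simulation_null"] = {
            "empirical_p": sim["empirical_p"],
            "n_sim": int(len(sim["null_stats"])),
            "n_skipped": sim["n_skipped"],
        }
        return tests

    cluster_tests = _stage("cluster", _cluster_stage)
    dio.write_results_json(cluster_tests, out / "cluster_tests.json")

    def _enrich_stage():
        gmt = dio.read_gmt(config.annotations)
        annotations = {t: set(e["genes"]) for t, e in gmt.items()}
        res = enrich_mod.enrich(
            signature, annotations, dio.read_attributes(config.attributes),
            n_null=config.n_null, seed=stage_seed(config.seed, "enrichment"),
        )
        if len(res.table):
            directions = enrich_mod.direction_breakdown(res, signature)
            return res.table.join(directions)
        return res.table

    enrichment_table = _stage("enrichment", _enrich_stage)
    enrichment_table.to_csv(out / "enrichment.tsv", sep="\t")

    def _cmap_stage():
        ranks = dio.read_rank_matrix(config.rank_matrix)
        inst_meta = pd.read_csv(config.instance_meta, sep="\t", index_col=0)
        probe_map = dio.read_probe_map(config.probe_map)
        rows = {}
        for pert in sorted(inst_meta["perturbagen"].unique()):
            res = cmap_mod.perturbagen_significance(
                signature, ranks, inst_meta, pert, probe_map,
                n_perm=config.n_perm,
                seed=stage_seed(config.seed, f"cmap-{pert}"),
            )
            rows[pert] = {
                "mean_combined_score": res.observed,
                "p_value": res.p_value,
                "n_instances": len(res.instance_scores),
                "mean_es_up": float(res.instance_scores["es_up"].mean()),
                "mean_es_down": float(res.instance_scores["es_down"].mean()),
            }
        table = pd.DataFrame.from_dict(rows, orient="index")
        table.index.name = "perturbagen"
        return table

    connectivity = _stage("cmap", _cmap_stage)
    connectivity.to_csv(out / "connectivity.tsv", sep="\t")

    manifest = {
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "artifacts": {
            "de": "de.tsv",
            "signature": "signature.gmt",
            "cluster_tests": "cluster_tests.json",
            "enrichment": "enrichment.tsv",
            "connectivity": "connectivity.tsv",
        },
        "n_signature": {"up": len(signature.up), "down": len(signature.down)},
        "runtime_seconds": round(time.time() - t0, 2),
    }
    dio.write_results_json(manifest, out / "manifest.json")
    return manifest
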