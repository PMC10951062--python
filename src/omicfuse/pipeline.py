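"""End-to-end pipeline driver: simulate/load, fuse, cluster, characterize.

``run_pipeline`` wires the stages together — complete-case filtering,
standardization, per-modality distances, affinity construction, SNF,
silhouette-guided spectral clustering, the randomization significance
test, per-feature association, endpoint derivation and Cox modelling,
overlap enrichment, ComDim and the network/heatmap reports — and writes
every artifact plus a JSON run manifest (parameters, seeds, input
checksums) into the output directory.  Re-running with an identical
configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import networkx as nx
import pandas as pd

from . import __version__
from .association import (
    EndpointRules,
    cox_ph,
    derive_time_to_insulin,
    logistic_per_feature,
    overlap_enrichment,
)
from .cluster import orient_two_clusters, select_k
from .comdim import comdim, score_separation
from .containers import OmicsBlock
from .preprocess import complete_cases, pairwise_squared_distance, standardize
from .report import betweenness_centrality, group_mean_aggregate, heatmap_feature_order
from .significance import (
    SignificanceParams,
    adjacency_top_quantile,
    cluster_significance,
)
from .snf import SNFParams, affinity_matrix, snf_fuse
from .synthetic import CohortSpec, generate_cohort, generate_longitudinal

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration.

    Either ``simulate`` holds a CohortSpec-compatible dict (synthetic run)
    or ``block_paths``/``clinical_path``/``records_path`` point at CSV/TSV
    inputs.  ``external_labels_path`` optionally provides a second
    clustering for overlap enrichment.
    """

    output_dir: str = "omicfuse_run"
    seed: int = 0
    simulate: dict | None = None
    block_paths: list[str] = field(default_factory=list)
    clinical_path: str | None = None
    records_path: str | None = None
    external_labels_path: str | None = None
    snf: SNFParams = field(default_factory=SNFParams)
    significance: SignificanceParams = field(default_factory=SignificanceParams)
    endpoint: EndpointRules = field(default_factory=EndpointRules)
    k_min: int = 2
    k_max: int = 10
    n_comdim_components: int = 2
    min_group: int = 5
    ties: str = "efron"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "snf" in d and isinstance(d["snf"], dict):
            d["snf"] = SNFParams(**d["snf"])
        if "significance" in d and isinstance(d["significance"], dict):
            d["significance"] = SignificanceParams(**d["significance"])
        if "endpoint" in d and isinstance(d["endpoint"], dict):
            d["endpoint"] = EndpointRules(**d["endpoint"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_blocks(paths: list[str]) -> list[OmicsBlock]:
    blocks = []
    for i, p in enumerate(paths):
        tag = Path(p).stem
        sep = "\t" if str(p).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(p, sep=sep, index_col=0)
        blocks.append(OmicsBlock(data=df, modality=tag or f"block{i + 1}"))
    return blocks


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "omicfuse",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "snf": dataclasses.asdict(config.snf),
            "significance": dataclasses.asdict(config.significance),
            "endpoint": dataclasses.asdict(config.endpoint),
            "k_range": [config.k_min, config.k_max],
            "distance": "squared_euclidean",
            "kernel": "scaled_exponential",
            "fused_diagonal": "row_max",
            "ties": config.ties,
        },
        "stages": {},
        "inputs": {},
    }

    def stage(name: str):
        logger.info("stage: %s", name)
        manifest["stages"][name] = "running"

    def done(name: str, **info):
        manifest["stages"][name] = {"status": "ok", **info}

    try:
        stage("inputs")
        records = None
        if config.simulate is not None:
            spec = CohortSpec.from_dict({**config.simulate, "seed": config.seed})
            blocks, clinical = generate_cohort(spec)
            rng = np.random.default_rng(spec.seed + 1)
            records = generate_longitudinal(spec, clinical, rng)
            spec.to_json(out / "cohort_spec.json")
            manifest["inputs"]["simulated"] = dataclasses.asdict(spec)
        else:
            blocks = _load_blocks(config.block_paths)
            clinical = pd.read_csv(config.clinical_path)
            if config.records_path:
                records = pd.read_csv(config.records_path)
            for p in [*config.block_paths, config.clinical_path, config.records_path]:
                if p:
                    manifest["inputs"][str(p)] = _sha256(Path(p))
        done("inputs", n_patients=blocks[0].n_patients, n_blocks=len(blocks))

        stage("preprocess")
        blocks, clinical = complete_cases(blocks, clinical)
        std_blocks = [standardize(b) for b in blocks]
        distances = [pairwise_squared_distance(b) for b in std_blocks]
        for b, d in zip(std_blocks, distances):
            d.to_tsv(out / f"distance_{b.modality}.tsv")
        done("preprocess", n_complete=blocks[0].n_patients)

        stage("snf")
        affinities = [affinity_matrix(d, config.snf) for d in distances]
        fused = snf_fuse(affinities, config.snf)
        pd.DataFrame(
            fused.W_fused, index=fused.patient_ids, columns=fused.patient_ids
        ).to_csv(out / "fused_network.tsv", sep="\t", index_label="patient_id")
        done("snf", convergence_delta=fused.convergence[-1])

        stage("clustering")
        assignment = select_k(fused, config.k_min, config.k_max, seed=config.seed)
        if assignment.k == 2:
            # orient labels so subgroup 1 is the elevated-feature phenotype
            overall = np.hstack([b.values for b in std_blocks]).mean(axis=1)
            assignment.labels = orient_two_clusters(assignment.labels, overall)
        labels_df = pd.DataFrame(
            {"patient_id": fused.patient_ids, "subgroup": assignment.labels}
        )
        labels_df.to_csv(out / "subgroups.tsv", sep="\t", index=False)
        (out / "silhouette_by_k.json").write_text(
            json.dumps({str(k): v for k, v in assignment.silhouette_by_k.items()}, indent=2)
        )
        done("clustering", k=assignment.k,
             mean_silhouette=assignment.silhouette_by_k[assignment.k])

        stage("significance")
        sig = cluster_significance(
            distances, config.snf, assignment, config.significance, blocks=std_blocks
        )
        (out / "cluster_significance.json").write_text(
            json.dumps(
                {
                    "observed": sig.observed,
                    "p_values": sig.p_values,
                    "raw_frequencies": sig.raw_frequencies,
                    "null_mean": float(sig.null_values.mean()),
                    "null_sd": float(sig.null_values.std(ddof=1)),
                    "null_quantiles": {
                        q: float(np.quantile(sig.null_values, float(q)))
                        for q in ("0.5", "0.95", "0.99")
                    },
                    "n_iter": sig.params.n_iter,
                    "n_skipped": sig.n_skipped,
                },
                indent=2,
            )
        )
        done("significance", p_values=sig.p_values)

        stage("association")
        assoc_info = {}
        if assignment.k == 2:
            tables = []
            for b in std_blocks:
                rows = logistic_per_feature(b, assignment.labels, clinical)
                t = pd.DataFrame([dataclasses.asdict(r) for r in rows])
                t.insert(0, "modality", b.modality)
                tables.append(t)
            assoc = pd.concat(tables, ignore_index=True)
            assoc.to_csv(out / "feature_association.tsv", sep="\t", index=False)
            assoc_info["n_significant_q05"] = int((assoc["q_value"] <= 0.05).sum())

            if records is not None:
                endpoint = derive_time_to_insulin(records, config.endpoint)
                endpoint = endpoint.set_index("patient_id").loc[fused.patient_ids]
                endpoint.reset_index().to_csv(
                    out / "time_to_insulin.tsv", sep="\t", index=False
                )
                clin_aligned = clinical.set_index("patient_id").loc[fused.patient_ids].reset_index()
                cox = cox_ph(
                    endpoint["time"],
                    endpoint["event"],
                    assignment.labels,
                    clin_aligned,
                    ties=config.ties,
                )
                (out / "cox_result.json").write_text(json.dumps(dataclasses.asdict(cox), indent=2))
                assoc_info["hazard_ratio"] = cox.hazard_ratio

            if config.external_labels_path:
                ext = pd.read_csv(config.external_labels_path, sep=None, engine="python")
                ext = ext.set_index("patient_id").loc[fused.patient_ids]
                enr = overlap_enrichment(assignment.labels, ext.iloc[:, 0])
                enr.to_csv(out / "overlap_enrichment.tsv", sep="\t", index=False)
            done("association", **assoc_info)
        else:
            done("association", skipped=f"k={assignment.k} is not binary")

        stage("comdim")
        cd = comdim(std_blocks, n_components=config.n_comdim_components)
        pd.DataFrame(
            cd.global_scores,
            index=fused.patient_ids,
            columns=[f"dim{i + 1}" for i in range(cd.global_scores.shape[1])],
        ).to_csv(out / "comdim_scores.tsv", sep="\t", index_label="patient_id")
        pd.DataFrame(
            cd.saliences,
            index=cd.block_names,
            columns=[f"dim{i + 1}" for i in range(cd.saliences.shape[1])],
        ).to_csv(out / "comdim_saliences.tsv", sep="\t", index_label="block")
        sep_d = score_separation(cd, assignment.labels) if assignment.k == 2 else None
        (out / "comdim_summary.json").write_text(
            json.dumps(
                {
                    "explained": cd.explained.tolist(),
                    "converged": cd.converged,
                    "separation_d": None if sep_d is None else sep_d.tolist(),
                },
                indent=2,
            )
        )
        done("comdim", explained=cd.explained.tolist())

        stage("report")
        A = adjacency_top_quantile(fused.W_fused, config.significance.adjacency_quantile)
        bc = betweenness_centrality(A)
        pd.DataFrame(
            {"patient_id": fused.patient_ids, "betweenness": bc,
             "subgroup": assignment.labels}
        ).to_csv(out / "network_nodes.tsv", sep="\t", index=False)
        G = nx.from_numpy_array(A)
        nx.relabel_nodes(G, dict(enumerate(fused.patient_ids)), copy=False)
        nx.write_graphml(G, out / "network.graphml")
        edges = np.argwhere(np.triu(A, k=1) > 0)
        pd.DataFrame(
            {
                "source": [fused.patient_ids[i] for i, _ in edges],
                "target": [fused.patient_ids[j] for _, j in edges],
            }
        ).to_csv(out / "network_edges.tsv", sep="\t", index=False)
        cluster_sizes = np.bincount(assignment.labels)[1:]
        if cluster_sizes.min() >= config.min_group:
            gm = group_mean_aggregate(std_blocks[0], assignment.labels, config.min_group)
            gm.to_csv(out / "group_means.tsv", sep="\t", index=False)
            order = heatmap_feature_order(gm)
            (out / "heatmap_feature_order.json").write_text(json.dumps(order, indent=2))
        done("report", n_edges=int(A.sum() // 2))
    except Exception as exc:
        failed = [k for k, v in manifest["stages"].items() if v == "running"]
        tag = failed[0] if failed else "unknown"
        raise RuntimeError(f"pipeline stage '{tag}' failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
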