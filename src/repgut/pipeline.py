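"""End-to-end pipeline orchestration with deterministic seeding.

Stages run in a fixed order — simulate? -> merge -> annotate -> qc ->
derep -> clones -> network -> features -> share -> reactivity? — each
writing its artifact plus a JSON report (counts, parameters, wall time).
The manifest lists every data artifact with a content hash; a fixed seed
yields identical hashes. A single global seed fans out to per-stage
child seeds by stable hashing so stages can be rerun in isolation.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import clonal_analysis, compartment_sharing, repertoire_features
from .annotation import annotate
from .read_processing import MergeParams, QCParams, apply_qc, merge_pairs
from .repertoire_io import (
    load_germline_reference,
    read_fasta,
    read_fastq,
    write_rearrangements,
)
from .synthetic_repertoire import (
    SimulationConfig,
    emit_paired_reads,
    simulate_repertoire,
    write_fastq,
    write_truth_table,
)
from .repertoire_io import write_fasta


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All tunables of a pipeline run; every stage reads its thresholds
    from here and nowhere else."""

    seed: int = 0
    outdir: str = "out"
    germline: str = "builtin"
    r1: Optional[str] = None
    r2: Optional[str] = None
    merged_fasta: Optional[str] = None
    mab_table: Optional[str] = None
    microarray_table: Optional[str] = None  # spot table; enables the reactivity stage
    simulate: Optional[dict] = None  # SimulationConfig overrides; None = no simulation
    merge: MergeParams = field(default_factory=MergeParams)
    qc: QCParams = field(default_factory=QCParams)
    derep_identity: float = 0.99
    clonal_identity: float = 0.8
    sharing_identity: float = 0.9
    alpha: float = 0.05
    bh_q: float = 0.05

    def validate(self) -> None:
        errors = []
        for name in ("derep_identity", "clonal_identity", "sharing_identity"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                errors.append(f"{name}={v} outside (0, 1]")
        for name in ("alpha", "bh_q"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                errors.append(f"{name}={v} outside (0, 1)")
        if self.simulate is None and not (self.r1 and self.r2) and not self.merged_fasta:
            errors.append("no input: provide simulate block, r1+r2, or merged_fasta")
        if self.simulate is None and self.germline is None:
            errors.append("germline path required when simulation is disabled")
        if errors:
            raise ConfigError("; ".join(errors))


_KNOWN_KEYS = {
    "seed",
    "outdir",
    "germline",
    "r1",
    "r2",
    "merged_fasta",
    "mab_table",
    "microarray_table",
    "simulate",
    "merge",
    "qc",
    "derep_identity",
    "clonal_identity",
    "sharing_identity",
    "alpha",
    "bh_q",
}


def validate_config(source) -> PipelineConfig:
    """Normalize a YAML/JSON file or dict into a PipelineConfig.

    All defaults filled; unknown keys and every validation error are
    reported together.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    unknown = sorted(set(data) - _KNOWN_KEYS)
    errors = [f"unknown config key: {k}" for k in unknown]
    for k in unknown:
        data.pop(k)
    merge = MergeParams(**data.pop("merge", {}))
    qc = QCParams(**data.pop("qc", {}))
    config = PipelineConfig(merge=merge, qc=qc, **data)
    try:
        config.validate()
    except ConfigError as exc:
        errors.append(str(exc))
    if errors:
        raise ConfigError("; ".join(errors))
    return config


def _jsonable(obj):
    """Make nested report structures JSON-serializable (tuple dict keys
    become '/'-joined strings)."""
    if isinstance(obj, dict):
        return {
            ("/".join(map(str, k)) if isinstance(k, tuple) else str(k)): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (artifact paths + hashes)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    reports: dict[str, dict] = {}

    def finish(stage: str, t0: float, report: dict, **paths):
        report["wall_time_s"] = round(time.time() - t0, 3)
        reports[stage] = report
        with open(outdir / f"{stage}.report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, default=str)
        artifacts.update(paths)

    reference = load_germline_reference(config.germline)

    # --- simulate -----------------------------------------------------------
    truth = None
    if config.simulate is not None:
        t0 = time.time()
        sim_config = SimulationConfig(
            **{"seed": stage_seed(config.seed, "simulate"), **config.simulate}
        )
        repertoire = simulate_repertoire(sim_config, reference)
        truth = repertoire.truth
        truth_path = outdir / "truth.tsv"
        write_truth_table(repertoire, truth_path)
        fasta_paths = {}
        for compartment in ("gut", "blood"):
            p = outdir / f"simulated.{compartment}.fasta"
            write_fasta(repertoire.sequences(compartment), p)
            fasta_paths[f"simulated_{compartment}_fasta"] = p
        r1, r2 = emit_paired_reads(repertoire)
        r1_path, r2_path = outdir / "simulated.R1.fastq", outdir / "simulated.R2.fastq"
        write_fastq(r1, r1_path)
        write_fastq(r2, r2_path)
        finish(
            "simulate",
            t0,
            {"n_clones": len(repertoire.clones), "n_sequences": len(truth),
             "params": asdict(sim_config)},
            truth_tsv=truth_path, r1_fastq=r1_path, r2_fastq=r2_path, **fasta_paths,
        )
        r1_source, r2_source = r1, r2
    else:
        r1_source = list(read_fastq(config.r1)) if config.r1 else None
        r2_source = list(read_fastq(config.r2)) if config.r2 else None

    # --- merge --------------------------------------------------------------
    if r1_source is not None:
        t0 = time.time()
        merged, merge_report = merge_pairs(r1_source, r2_source, config.merge)
        merged_path = outdir / "merged.fasta"
        write_fasta(merged, merged_path)
        finish("merge", t0, {**merge_report, "params": asdict(config.merge)},
               merged_fasta=merged_path)
    else:
        merged = list(read_fasta(config.merged_fasta))

    # --- annotate -----------------------------------------------------------
    t0 = time.time()
    try:
        annotated = annotate(merged, reference)
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("annotate", str(exc)) from exc
    annotated_path = outdir / "rearrangements.tsv"
    write_rearrangements(annotated, annotated_path)
    finish("annotate", t0, {"input": len(merged), "output": len(annotated)},
           rearrangements_tsv=annotated_path)

    # --- qc -----------------------------------------------------------------
    t0 = time.time()
    passing, rejected_records, qc_report = apply_qc(annotated, config.qc)
    qc_path = outdir / "rearrangements.pass.tsv"
    write_rearrangements(passing, qc_path)
    rejected_path = outdir / "rearrangements.reject.tsv"
    write_rearrangements(rejected_records, rejected_path)
    finish("qc", t0, {**qc_report, "params": asdict(config.qc)},
           qc_pass_tsv=qc_path, qc_reject_tsv=rejected_path)

    # --- dereplicate --------------------------------------------------------
    t0 = time.time()
    representatives = clonal_analysis.dereplicate_99(passing, config.derep_identity)
    derep_path = outdir / "dereplicated.tsv"
    write_rearrangements(representatives, derep_path)
    finish(
        "derep",
        t0,
        {"input": len(passing), "output": len(representatives),
         "duplicates_total": sum(r.duplicate_count for r in representatives),
         "identity": config.derep_identity},
        dereplicated_tsv=derep_path,
    )

    # --- clonal families ----------------------------------------------------
    t0 = time.time()
    families = clonal_analysis.infer_clonal_families(representatives, config.clonal_identity)
    families_path = outdir / "clonal_families.tsv"
    clonal_analysis.families_table(families).to_csv(families_path, sep="\t", index=False)
    expansion_path = outdir / "expansion_summary.tsv"
    clonal_analysis.expansion_summary(families).to_csv(expansion_path, sep="\t", index=False)
    finish("clones", t0,
           {"input": len(representatives), "families": len(families),
            "identity": config.clonal_identity},
           clonal_families_tsv=families_path, expansion_tsv=expansion_path)

    # --- network ------------------------------------------------------------
    t0 = time.time()
    graph = clonal_analysis.build_clone_network(representatives)
    graphml_path = outdir / "clone_network.graphml"
    edges_path = outdir / "clone_network.edges.tsv"
    clonal_analysis.export_network(graph, graphml_path, edges_path)
    components_path = outdir / "clone_network.components.tsv"
    clonal_analysis.network_components(graph).to_csv(components_path, sep="\t", index=False)
    finish("network", t0,
           {"vertices": graph.number_of_nodes(), "edges": graph.number_of_edges()},
           network_graphml=graphml_path, network_edges_tsv=edges_path,
           network_components_tsv=components_path)

    # --- features -----------------------------------------------------------
    t0 = time.time()
    by_group = {
        g: [r for r in passing if r.metadata.get("group") == g] for g in ("eART", "lART")
    }
    if all(by_group.values()):
        panel_e = repertoire_features.FeaturePanel.from_rearrangements(by_group["eART"], "eART")
        panel_l = repertoire_features.FeaturePanel.from_rearrangements(by_group["lART"], "lART")
        volcano = repertoire_features.compare_repertoires(
            panel_e, panel_l, alpha=config.alpha, bh_q=config.bh_q
        )
        volcano_path = outdir / "volcano.tsv"
        volcano.to_csv(volcano_path, sep="\t", index=False)
        ratios = {
            g: repertoire_features.iga_igg_ratio(records)
            for g, records in by_group.items()
        }
        finish("features", t0,
               {"parameters": len(volcano), "iga_igg_ratio": ratios,
                "alpha": config.alpha, "bh_q": config.bh_q},
               volcano_tsv=volcano_path)
    else:
        finish("features", t0, {"skipped": "need records from both groups"})

    # --- sharing ------------------------------------------------------------
    t0 = time.time()
    mab_table = None
    if config.mab_table is not None:
        mab_table = pd.read_csv(config.mab_table, sep="\t")
    elif truth is not None:
        mab_table = sample_mabs_from_truth(truth, seed=stage_seed(config.seed, "mabs"))
    if mab_table is not None:
        blood = [r for r in passing if r.metadata.get("compartment") == "blood"]
        shared = compartment_sharing.find_shared(mab_table, blood, config.sharing_identity)
        links_path = outdir / "sharing_links.tsv"
        compartment_sharing.export_sharing_links(shared, links_path)
        summary = {}
        if "group" in mab_table.columns:
            shared_ids = {s.mab_id for s in shared}
            counts = {}
            for g in ("eART", "lART"):
                sub = mab_table[mab_table["group"] == g]
                counts[g] = (
                    int(sub["mab_id"].astype(str).isin(shared_ids).sum()), len(sub)
                )
            if all(n for _, n in counts.values()):
                summary = compartment_sharing.sharing_frequency_test(
                    counts["eART"][0], counts["eART"][1],
                    counts["lART"][0], counts["lART"][1],
                )
                summary = {"eART": counts["eART"], "lART": counts["lART"], **summary}
        finish("share", t0, {"mabs": len(mab_table), "shared": len(shared),
                             "identity": config.sharing_identity, "summary": summary},
               sharing_links_tsv=links_path)
    else:
        finish("share", t0, {"skipped": "no mAb table available"})

    # --- reactivity (optional) ----------------------------------------------
    if config.microarray_table is not None:
        t0 = time.time()
        from .reactivity_metrics import (
            microarray_zscores,
            polyreactivity_index,
            reactivity_summary,
        )

        spots = pd.read_csv(config.microarray_table, sep="\t")
        groups = (
            spots.groupby("antibody_id")
            if "antibody_id" in spots.columns
            else [("test", spots)]
        )
        profiles = [
            polyreactivity_index(microarray_zscores(sub, antibody_id=str(ab)))
            for ab, sub in groups
        ]
        reactivity_path = outdir / "reactivity.tsv"
        reactivity_summary(profiles).to_csv(reactivity_path, sep="\t", index=False)
        finish("reactivity", t0,
               {"antibodies": len(profiles),
                "polyreactive": int(sum(p.polyreactive for p in profiles))},
               reactivity_tsv=reactivity_path)

    manifest = {
        "seed": config.seed,
        "artifacts": {
            name: {"path": str(path), "sha256": _sha256(path)}
            for name, path in sorted(artifacts.items())
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def sample_mabs_from_truth(
    truth: pd.DataFrame, n_per_group: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Build a monoclonal-antibody table by sampling gut clones from a
    simulation truth table (one mAb per sampled clone)."""
    import numpy as np

    rng = np.random.default_rng(seed)
    rows = []
    gut = truth[truth["compartment"] == "gut"]
    for group, sub in gut.groupby("group"):
        clone_ids = sub["clone_id"].unique()
        size = min(n_per_group, len(clone_ids))
        chosen = rng.choice(clone_ids, size=size, replace=False)
        for clone_id in chosen:
            row = sub[sub["clone_id"] == clone_id].iloc[0]
            rows.append(
                {
                    "mab_id": f"mab_{clone_id}",
                    "group": group,
                    "clone_id": clone_id,
                    "v_call": row["v_call"],
                    "j_call": row["j_call"],
                    "cdr3_aa": row["junction_aa"],
                    "isotype": row["isotype"],
                    "polyreactive": bool(row["polyreactive"]),
                }
            )
    return pd.DataFrame(rows)
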