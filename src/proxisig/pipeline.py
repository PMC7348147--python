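"""End-to-end orchestration: normalize -> DEG -> summarize/cluster ->
signatures -> proximity -> enrichment, with a run manifest."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

import proxisig
from proxisig import io as pio
from proxisig.enrichment import (
    DrugAnnotationTable,
    GeneSetCollection,
    drug_feature_enrichment,
    gene_set_enrichment,
    map_orthologs,
    results_frame,
)
from proxisig.errors import ConfigurationError
from proxisig.expression import (
    cluster_profiles,
    detect_degs,
    fpkm_normalize,
    summarize_degs,
)
from proxisig.network import (
    consensus_frame,
    load_network,
    proximity_results_frame,
    run_proximity_screen,
)
from proxisig.signatures import (
    build_signature,
    correlate_signatures,
    polarity_summary,
    prune_redundant,
)

STAGES = ("normalize", "deg", "summarize", "cluster", "signatures", "proximity",
          "enrichment")


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run."""

    counts: str
    annotations: str
    outdir: str
    gene_lengths: str | None = None
    network: str | None = None
    drug_targets: str | None = None
    reference_signatures: str | None = None
    gene_sets_gmt: str | None = None
    drug_annotations: str | None = None
    ortholog_table: str | None = None
    alpha: float = 0.05
    scc_cutoff: float = 0.5
    n_perm: int = 1000
    seed: int = 0
    distance_mode: str = "undirected"
    degree_matched_null: bool = False
    drop_unreachable: bool = False
    correction: str = "bh"
    fdr_alpha: float = 0.05
    skip: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"config: unknown fields {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ConfigurationError("alpha: must be in [0, 1]")
        if self.n_perm < 1:
            raise ConfigurationError("n_perm: must be >= 1")
        if self.distance_mode not in ("directed", "undirected"):
            raise ConfigurationError("distance_mode: directed or undirected")
        unknown = set(self.skip) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"skip: unknown stages {sorted(unknown)}")
        for name in (
            "counts",
            "annotations",
            "gene_lengths",
            "network",
            "drug_targets",
            "reference_signatures",
            "gene_sets_gmt",
            "drug_annotations",
            "ortholog_table",
        ):
            val = getattr(self, name)
            if val is not None and not Path(val).exists():
                raise ConfigurationError(f"{name}: missing input file {val}")

    def snapshot(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    input_checksums: dict[str, str]
    version: str
    stages: dict[str, dict] = field(default_factory=dict)
    failed_stage: str | None = None

    def record(self, stage: str, t0: float, **counts: Any) -> None:
        self.stages[stage] = {
            "wall_time_s": round(time.time() - t0, 3),
            **counts,
        }

    def write(self, path: str | Path) -> None:
        pio.write_json(
            {
                "config": self.config,
                "input_checksums": self.input_checksums,
                "version": self.version,
                "stages": self.stages,
                "failed_stage": self.failed_stage,
            },
            path,
        )


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Run all configured stages; partial outputs survive a stage failure."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for name in ("counts", "annotations", "gene_lengths", "network",
                 "drug_targets", "reference_signatures", "gene_sets_gmt",
                 "drug_annotations", "ortholog_table"):
        val = getattr(cfg, name)
        if val is not None:
            checksums[name] = _sha256(val)
    manifest = RunManifest(
        config=cfg.snapshot(),
        input_checksums=checksums,
        version=proxisig.__version__,
    )

    try:
        cm = pio.read_count_matrix(cfg.counts, cfg.annotations, cfg.gene_lengths)
        tissues = cm.tissues()

        fm = None
        if "normalize" not in cfg.skip and cm.gene_lengths is not None:
            t0 = time.time()
            fm = fpkm_normalize(cm)
            pio.write_fpkm(fm, outdir / "fpkm.tsv")
            manifest.record("normalize", t0, n_genes=len(fm.genes),
                            n_samples=len(fm.samples))

        deg_tables = []
        if "deg" not in cfg.skip:
            t0 = time.time()
            for tissue in tissues:
                table = detect_degs(cm, tissue, alpha=cfg.alpha)
                pio.write_deg_table(table, outdir / f"deg_{tissue}.tsv")
                deg_tables.append(table)
            manifest.record(
                "deg", t0, n_tissues=len(deg_tables),
                n_degs={t.tissue: len(t.gene_sets()["both"]) for t in deg_tables},
            )

        if deg_tables and "summarize" not in cfg.skip:
            t0 = time.time()
            summary = summarize_degs(deg_tables)
            pio.write_json(summary.to_dict(), outdir / "deg_summary.json")
            manifest.record("summarize", t0, union_size=summary.union_size)

        if fm is not None and deg_tables and "cluster" not in cfg.skip:
            t0 = time.time()
            union = sorted(set().union(*(t.gene_sets()["both"] for t in deg_tables)))
            if union:
                clustered = cluster_profiles(fm, union)
                (outdir / "dendrogram.newick").write_text(clustered.newick + "\n")
                clustered.pca_scores.to_csv(
                    outdir / "pca_scores.tsv", sep="\t", index_label="sample"
                )
                manifest.record("cluster", t0, n_genes=len(union))
            else:
                manifest.record("cluster", t0, n_genes=0, skipped="no DEGs")

        treatment_sigs = {}
        if fm is not None and "signatures" not in cfg.skip:
            t0 = time.time()
            for tissue in tissues:
                ann = cm.annotations
                case = [s for s in cm.samples
                        if ann.at[s, "tissue"] == tissue
                        and ann.at[s, "group"] == "treated"]
                ctrl = [s for s in cm.samples
                        if ann.at[s, "tissue"] == tissue
                        and ann.at[s, "group"] == "control"]
                treatment_sigs[tissue] = build_signature(
                    fm.values, "rnaseq", case, ctrl,
                    sig_id=f"treatment_{tissue}", tissue=tissue,
                )
            pio.write_signatures(
                list(treatment_sigs.values()), outdir / "treatment_signatures.tsv"
            )
            n_corr = 0
            if cfg.reference_signatures is not None:
                refs = pio.read_signatures(cfg.reference_signatures)
                refs = prune_redundant(refs, scc_cutoff=cfg.scc_cutoff)
                rows = []
                pol = {}
                for tissue, sig in treatment_sigs.items():
                    cors = correlate_signatures(sig, refs, alpha=cfg.alpha)
                    pol[tissue] = polarity_summary(cors, refs, alpha=cfg.alpha)
                    rows += [
                        {
                            "query": c.query_id,
                            "reference": c.reference_id,
                            "scc": c.scc,
                            "n_shared": c.n_shared,
                            "p": c.p_value,
                            "p_bonferroni": c.p_adjusted,
                            "significant": c.significant,
                        }
                        for c in cors
                    ]
                pd.DataFrame(rows).to_csv(
                    outdir / "signature_correlations.tsv", sep="\t", index=False
                )
                pio.write_json(pol, outdir / "polarity_summary.json")
                n_corr = len(rows)
            manifest.record("signatures", t0, n_tissue_signatures=len(treatment_sigs),
                            n_correlations=n_corr)

        if (
            deg_tables
            and cfg.network is not None
            and cfg.drug_targets is not None
            and "proximity" not in cfg.skip
        ):
            t0 = time.time()
            net = load_network(cfg.network)
            targets = pio.read_drug_targets(cfg.drug_targets)
            deg_sets = {t.tissue: t for t in deg_tables}
            any_degs = any(
                t.gene_sets()["both"] & set(net.nodes) for t in deg_tables
            )
            if any_degs:
                results, calls = run_proximity_screen(
                    net,
                    deg_sets,
                    targets,
                    n_perm=cfg.n_perm,
                    seed=cfg.seed,
                    fdr_alpha=cfg.fdr_alpha,
                    mode=cfg.distance_mode,
                    degree_matched_null=cfg.degree_matched_null,
                    drop_unreachable=cfg.drop_unreachable,
                )
            else:  # zero DEGs: emit empty-but-valid outputs
                results, calls = [], []
            prox = proximity_results_frame(results)
            if prox.empty:
                prox = pd.DataFrame(
                    columns=["drug", "tissue", "deg_kind", "source",
                             "observed_dist", "p", "fdr", "n_deg_in_net",
                             "n_targets_in_net"]
                )
            prox.to_csv(outdir / "proximity.tsv", sep="\t", index=False)
            cons = consensus_frame(calls)
            if cons.empty:
                cons = pd.DataFrame(columns=["drug", "tissue", "retained"])
            cons.to_csv(outdir / "consensus.tsv", sep="\t", index=False)
            manifest.record(
                "proximity", t0, n_tests=len(results),
                n_retained=sum(c.retained for c in calls),
            )

        if deg_tables and "enrichment" not in cfg.skip:
            t0 = time.time()
            wrote = {}
            union = set().union(*(t.gene_sets()["both"] for t in deg_tables))
            if cfg.ortholog_table is not None and union:
                union, report = map_orthologs(union, cfg.ortholog_table)
                pio.write_json(
                    {"n_input": report.n_input, "n_output": report.n_output,
                     "unmapped": report.unmapped},
                    outdir / "ortholog_report.json",
                )
                wrote["orthologs"] = report.n_output
            if cfg.gene_sets_gmt is not None and union:
                universe = set(cm.genes)
                coll = GeneSetCollection.from_gmt(cfg.gene_sets_gmt)
                coll = GeneSetCollection(
                    sets=coll.sets,
                    universe=frozenset(universe & set(coll.universe)) or coll.universe,
                )
                query = union & set(coll.universe)
                if query:
                    res = gene_set_enrichment(query, coll, correction=cfg.correction)
                    results_frame(res).to_csv(
                        outdir / "gene_set_enrichment.tsv", sep="\t", index=False
                    )
                    wrote["gene_sets"] = len(res)
            consensus_path = outdir / "consensus.tsv"
            if cfg.drug_annotations is not None and consensus_path.exists():
                cons = pd.read_csv(consensus_path, sep="\t")
                hits = sorted(set(cons.loc[cons["retained"], "drug"]))
                alld = sorted(set(cons["drug"]))
                if hits:
                    ann = DrugAnnotationTable.from_tsv(cfg.drug_annotations)
                    for kind in ("class", "side_effect", "interaction"):
                        res = drug_feature_enrichment(
                            hits, alld, ann, feature_kind=kind,
                            correction=cfg.correction,
                        )
                        results_frame(res).to_csv(
                            outdir / f"drug_enrichment_{kind}.tsv",
                            sep="\t", index=False,
                        )
                    wrote["drug_features"] = True
            manifest.record("enrichment", t0, **wrote)
    except Exception as exc:
        import traceback

        manifest.failed_stage = f"{type(exc).__name__}: {exc}"
        manifest.write(outdir / "manifest.json")
        (outdir / "failure.log").write_text(traceback.format_exc())
        raise
    manifest.write(outdir / "manifest.json")
    return manifest
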