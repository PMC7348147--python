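"""Plain-text readers and writers for every pipeline artefact.

Formats: counts as TSV (genes x samples) and MTX with index sidecars; sample
annotations, gene lengths, networks, drug targets, signatures and DEG tables
as TSV; ground truth and summaries as JSON; dendrograms as Newick.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from proxisig.errors import ParseError
from proxisig.expression import CountMatrix, DEGTable, FPKMMatrix
from proxisig.network import DrugTargetSet, SignalingNetwork
from proxisig.signatures import Signature


# -- count matrices ---------------------------------------------------------


def write_count_matrix(cm: CountMatrix, outdir: str | Path, stem: str = "counts"):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm.counts.to_csv(outdir / f"{stem}.tsv", sep="\t", index_label="gene")
    scipy.io.mmwrite(
        outdir / f"{stem}.mtx", scipy.sparse.csr_matrix(cm.counts.values)
    )
    (outdir / f"{stem}.genes.txt").write_text("\n".join(cm.genes) + "\n")
    (outdir / f"{stem}.samples.txt").write_text("\n".join(cm.samples) + "\n")
    cm.annotations.to_csv(outdir / "sample_annotations.tsv", sep="\t",
                          index_label="sample")
    if cm.gene_lengths is not None:
        cm.gene_lengths.to_frame("length").to_csv(
            outdir / "gene_lengths.tsv", sep="\t", index_label="gene"
        )


def read_count_matrix(
    counts_path: str | Path,
    annotations_path: str | Path,
    gene_lengths_path: str | Path | None = None,
) -> CountMatrix:
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        genes = counts_path.with_suffix(".genes.txt").read_text().split()
        samples = counts_path.with_suffix(".samples.txt").read_text().split()
        mat = scipy.io.mmread(counts_path).toarray().astype(int)
        counts = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    annotations = pd.read_csv(annotations_path, sep="\t", index_col=0)
    lengths = None
    if gene_lengths_path is not None:
        lengths = pd.read_csv(gene_lengths_path, sep="\t", index_col=0)["length"]
    return CountMatrix(counts=counts, annotations=annotations, gene_lengths=lengths)


def write_fpkm(fm: FPKMMatrix, path: str | Path):
    fm.values.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


# -- networks and drug targets ---------------------------------------------


def write_network(net: SignalingNetwork, outdir: str | Path, stem: str = "network"):
    import networkx as nx

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [
        {"source": u, "target": v, "directed": True}
        for u, v in sorted(net.graph.edges())
    ]
    pd.DataFrame(rows).to_csv(outdir / f"{stem}.tsv", sep="\t", index=False)
    nx.write_graphml(net.graph, outdir / f"{stem}.graphml")


def write_drug_targets(sets: Sequence[DrugTargetSet], path: str | Path):
    rows = [
        {"drug": ts.drug, "target": t, "source_db": ts.source_db}
        for ts in sets
        for t in sorted(ts.targets)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_drug_targets(path: str | Path) -> list[DrugTargetSet]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"drug", "target", "source_db"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: need columns {sorted(required)}")
    out = []
    for (drug, src), grp in df.groupby(["drug", "source_db"], sort=True):
        out.append(
            DrugTargetSet(drug=drug, targets=frozenset(grp["target"]), source_db=src)
        )
    return out


# -- signatures -------------------------------------------------------------


def write_signatures(sigs: Sequence[Signature], path: str | Path):
    rows = []
    for s in sigs:
        for gene, lfc in s.values.items():
            rows.append(
                {
                    "signature_id": s.id,
                    "tissue": s.tissue,
                    "topic": s.topic,
                    "polarity": s.polarity,
                    "platform": s.platform,
                    "gene": gene,
                    "log2fc": lfc,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_signatures(path: str | Path) -> list[Signature]:
    df = pd.read_csv(path, sep="\t")
    required = {"signature_id", "gene", "log2fc"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: need columns {sorted(required)}")
    out = []
    for sid, grp in df.groupby("signature_id", sort=True):
        first = grp.iloc[0]
        out.append(
            Signature(
                id=str(sid),
                values=pd.Series(
                    grp["log2fc"].values, index=pd.Index(grp["gene"].astype(str))
                ),
                tissue=str(first.get("tissue", "") or ""),
                topic=str(first.get("topic", "") or ""),
                polarity=str(first.get("polarity", "neutral") or "neutral"),
                platform=str(first.get("platform", "rnaseq") or "rnaseq"),
            )
        )
    return out


# -- DEG tables -------------------------------------------------------------


def write_deg_table(table: DEGTable, path: str | Path):
    df = table.rows.rename(
        columns={"log2fc": "log2FC", "p_value": "PValue"}
    )
    df.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


def read_deg_table(path: str | Path, tissue: str, alpha: float = 0.05) -> DEGTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.rename(columns={"log2FC": "log2fc", "PValue": "p_value"})
    return DEGTable(tissue=tissue, rows=df, alpha=alpha)


# -- misc -------------------------------------------------------------------


def write_json(obj, path: str | Path):
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    return [g for g in Path(path).read_text().split() if g]


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path):
    with open(path, "w") as fh:
        for sid, genes in sets.items():
            fh.write("\t".join([sid, "na", *sorted(set(genes))]) + "\n")
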