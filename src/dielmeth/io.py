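"""Readers and writers for the study's on-disk formats.

Conventions: FASTA via Biopython; GFF3 1-based closed (gene / exon /
transposable_element features, parsed back with gffutils); CX-report
TSV per sample, headerless, columns chrom, pos (1-based), strand,
context, count_methylated, count_unmethylated; BED and bedGraph 0-based
half-open. All writers emit deterministic byte-stable text.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CALL_COLUMNS
from .genome import GenomeModel
from .simulate import GroundTruth


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_gff3(genome: GenomeModel, path) -> None:
    """Genes with exon children plus TEs, 1-based closed coordinates."""
    lines = ["##gff-version 3"]
    for chrom, size in genome.chrom_sizes.items():
        lines.append(f"##sequence-region {chrom} 1 {size}")
    exons_by_gene = dict(tuple(genome.exons.groupby("gene_id", sort=False)))
    for g in genome.genes.itertuples():
        lines.append(
            "\t".join(
                [
                    g.chrom,
                    "dielmeth",
                    "gene",
                    str(g.start + 1),
                    str(g.end),
                    ".",
                    g.strand,
                    ".",
                    f"ID={g.gene_id}",
                ]
            )
        )
        sub = exons_by_gene.get(g.gene_id)
        if sub is None:
            continue
        for i, e in enumerate(sub.sort_values("start").itertuples(), start=1):
            lines.append(
                "\t".join(
                    [
                        e.chrom,
                        "dielmeth",
                        "exon",
                        str(e.start + 1),
                        str(e.end),
                        ".",
                        e.strand,
                        ".",
                        f"ID={g.gene_id}.exon{i};Parent={g.gene_id}",
                    ]
                )
            )
    for t in genome.tes.itertuples():
        lines.append(
            "\t".join(
                [
                    t.chrom,
                    "dielmeth",
                    "transposable_element",
                    str(t.start + 1),
                    str(t.end),
                    ".",
                    ".",
                    ".",
                    f"ID={t.te_id}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path, seqs: Mapping[str, str] | None = None, control_contig: str | None = None) -> GenomeModel:
    """Rebuild a :class:`GenomeModel` from GFF3 (sequences optional)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    gene_rows, exon_rows, te_rows = [], [], []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_rows.append((g.id, g.seqid, g.start - 1, g.end, g.strand))
    for e in db.features_of_type("exon", order_by=("seqid", "start")):
        parent = e.attributes["Parent"][0]
        exon_rows.append((parent, e.seqid, e.start - 1, e.end, e.strand))
    for t in db.features_of_type("transposable_element", order_by=("seqid", "start")):
        te_rows.append((t.id, t.seqid, t.start - 1, t.end))
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    )
    exons = pd.DataFrame(
        exon_rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    )
    tes = pd.DataFrame(te_rows, columns=["te_id", "chrom", "start", "end"])
    return GenomeModel(
        seqs=dict(seqs) if seqs else {},
        genes=genes,
        exons=exons,
        tes=tes,
        control_contig=control_contig,
    )


def write_cx_report(calls: pd.DataFrame, path) -> None:
    """Headerless CX-style TSV: chrom, pos(1-based), strand, context,
    count_methylated, count_unmethylated."""
    out = pd.DataFrame(
        {
            "chrom": calls["chrom"],
            "pos": calls["pos"],
            "strand": calls["strand"],
            "context": calls["context"],
            "n_meth": calls["n_meth"],
            "n_unmeth": calls["n_total"] - calls["n_meth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_cx_report(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"],
        dtype={"chrom": str, "pos": np.int64, "strand": str, "context": str},
    )
    df["n_total"] = df["n_meth"] + df["n_unmeth"]
    return df[CALL_COLUMNS]


def write_windows_tsv(windows: pd.DataFrame, path) -> None:
    windows.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_bedgraph(windows: pd.DataFrame, context: str, path) -> None:
    """Per-context window levels as bedGraph (defined windows only)."""
    sub = windows[(windows["context"] == context) & windows["level"].notna()]
    lines = [
        f"{r.chrom}\t{r.start}\t{r.end}\t{r.level:.6g}" for r in sub.itertuples()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    """DMRs as BED6: name = context:direction, score = -10*log10(q)
    (clipped to [0, 1000]), strand '.'. """
    lines = []
    for r in dmrs.itertuples():
        q = max(float(r.q_value), 1e-100)
        score = int(np.clip(-10.0 * np.log10(q), 0, 1000))
        lines.append(
            f"{r.chrom}\t{r.start}\t{r.end}\t{r.context}:{r.direction}\t{score}\t."
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed(path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=True, index_label="gene_id")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_lengths_tsv(lengths: pd.Series, path) -> None:
    lengths.rename("length").to_csv(path, sep="\t", index_label="gene_id")


def read_lengths_tsv(path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col="gene_id")["length"]


def write_go_map_tsv(go_map: pd.DataFrame, path) -> None:
    go_map.to_csv(path, sep="\t", index=False)


def read_go_map_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True) + "\n")


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# whole-study directory layout


def write_study(study: dict, outdir) -> None:
    """Write a simulated study (see ``simulate_study``) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome: GenomeModel = study["genome"]
    write_fasta(genome.seqs, outdir / "genome.fa")
    write_gff3(genome, outdir / "annotation.gff3")
    cx = outdir / "cx"
    cx.mkdir(exist_ok=True)
    for sample, calls in study["calls"].items():
        write_cx_report(calls, cx / f"{sample}.cx.tsv")
    write_counts_tsv(study["counts"], outdir / "rna_counts.tsv")
    write_lengths_tsv(study["lengths"], outdir / "gene_lengths.tsv")
    write_go_map_tsv(study["go_map"], outdir / "go_map.tsv")
    write_ground_truth(study["truth"], outdir / "ground_truth.json")


def read_study(outdir) -> dict:
    outdir = Path(outdir)
    seqs = read_fasta(outdir / "genome.fa")
    truth = read_ground_truth(outdir / "ground_truth.json")
    genome = read_gff3(
        outdir / "annotation.gff3", seqs=seqs, control_contig=truth.control_contig
    )
    calls = {
        p.name.removesuffix(".cx.tsv"): read_cx_report(p)
        for p in sorted((outdir / "cx").glob("*.cx.tsv"))
    }
    return {
        "genome": genome,
        "truth": truth,
        "calls": calls,
        "counts": read_counts_tsv(outdir / "rna_counts.tsv"),
        "lengths": read_lengths_tsv(outdir / "gene_lengths.tsv"),
        "go_map": read_go_map_tsv(outdir / "go_map.tsv"),
    }
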