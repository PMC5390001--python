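"""Shared format readers and writers.

Everything the pipeline reads or writes is plain text: FASTA/FASTQ through
Biopython, GFF3/BED12 annotation, GMT gene sets, JASPAR-style PFM motif
files, and headered TSV tables for counts, sample sheets, voxel matrices
and probe maps.  Every writer round-trips bit-identically through its
reader.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from deeptag.enrich import GeneSet
from deeptag.spatial import VoxelMatrix
from deeptag.tagproc import ExonAnnotation
from deeptag.tfbs import MotifModel, Promoter, PromoterSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """(read_id, sequence) pairs; Phred qualities are ignored."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality: int = 40) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{chr(quality + 33) * len(seq)}\n")


# ---------------------------------------------------------------------------
# Annotation (GFF3 / BED12)
# ---------------------------------------------------------------------------

def _gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[ExonAnnotation]:
    """Exon features grouped per gene; 1-based inclusive -> 0-based half-open.

    The gene identifier is taken from the ``gene_id`` attribute, falling
    back to ``Parent`` then ``ID``.
    """
    exons: dict[str, list[tuple[int, int]]] = defaultdict(list)
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2].lower() != "exon":
                continue
            chrom, _, _, start, end, _, strand, _, attrs = fields[:9]
            a = _gff_attributes(attrs)
            gene = a.get("gene_id") or a.get("Parent") or a.get("ID")
            if gene is None:
                raise ValueError(f"exon feature without gene_id/Parent/ID in {path}")
            exons[gene].append((int(start) - 1, int(end)))
            meta[gene] = (chrom, strand)
    return [
        ExonAnnotation(gene, meta[gene][0], meta[gene][1], sorted(iv))
        for gene, iv in exons.items()
    ]


def write_gff3(annotation: Sequence[ExonAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotation:
            for i, (start, end) in enumerate(ann.exons, 1):
                fh.write(
                    f"{ann.chromosome}\tdeeptag\texon\t{start + 1}\t{end}\t.\t"
                    f"{ann.strand}\t.\tgene_id={ann.gene_id};ID={ann.gene_id}.exon{i}\n"
                )


def read_bed12(path: str | Path) -> list[ExonAnnotation]:
    """One gene per BED12 line; block starts/sizes give the exon intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + s, start + s + size) for s, size in zip(starts, sizes)]
            out.append(ExonAnnotation(name, chrom, strand, exons))
    return out


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return df.astype(int)


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index.name = "sample"
    return df


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample")


def read_gene_annotation_tsv(path: str | Path) -> pd.Series:
    """Per-gene chromosome labels from a two-column (gene, chromosome) TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return df["chromosome"]


def write_table(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# Voxel matrix and probe map
# ---------------------------------------------------------------------------

def read_voxel_matrix(matrix_path: str | Path, probe_map_path: str | Path) -> VoxelMatrix:
    """Probe x voxel TSV (empty cells = missing) plus a probe -> gene TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index.name = "probe"
    pm = pd.read_csv(probe_map_path, sep="\t", index_col=0)
    return VoxelMatrix(values.astype(float), pm["gene"].astype(str))


def write_voxel_matrix(matrix: VoxelMatrix, matrix_path: str | Path, probe_map_path: str | Path) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="probe")
    matrix.probe_map.to_frame("gene").to_csv(probe_map_path, sep="\t", index_label="probe")


# ---------------------------------------------------------------------------
# Gene sets (GMT) and motifs (PFM)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """GMT: one set per line, ``name <tab> description <tab> gene1 ...``."""
    sets = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line in {path}: {line[:60]!r}")
            sets.append(GeneSet(fields[0], [g for g in fields[2:] if g], source=fields[1]))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\t{gs.source or '.'}\t{members}\n")


def read_pfms(path: str | Path) -> list[MotifModel]:
    """JASPAR-style PFM text: ``>name`` then four A/C/G/T count rows.

    Rows may be bare whitespace-separated numbers or the bracketed
    ``A [ 1 2 3 ]`` form; row order is A, C, G, T either way.
    """
    motifs = []
    name, rows = None, []

    def flush() -> None:
        if name is None:
            return
        if len(rows) != 4:
            raise ValueError(f"motif {name!r} needs 4 rows, got {len(rows)}")
        motifs.append(MotifModel(name, np.array(rows, dtype=float)))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name, rows = line[1:].split()[0], []
            else:
                body = line
                if body[0] in "ACGT" and (len(body) == 1 or not body[1].isdigit()):
                    body = body[1:]
                body = body.replace("[", " ").replace("]", " ")
                rows.append([float(x) for x in body.split()])
    flush()
    return motifs


def write_pfms(motifs: Sequence[MotifModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.name}\n")
            for base, row in zip("ACGT", m.pfm):
                fh.write(base + " [ " + " ".join(f"{v:g}" for v in row) + " ]\n")


def read_promoters_fasta(path: str | Path) -> PromoterSet:
    return PromoterSet([Promoter(name, seq) for name, seq in read_fasta(path).items()])


def write_promoters_fasta(promoters: PromoterSet, path: str | Path) -> None:
    write_fasta({p.gene_id: p.sequence for p in promoters}, path)
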