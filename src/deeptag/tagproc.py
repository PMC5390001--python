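"""Raw tag reads -> gene-level counts.

Implements the tag-seq quantification contract: reads are trimmed to 17 bp,
the NlaIII recognition site (CATG) is prepended to give a 21-bp tag, tags are
placed on the reference by a best-stratum unique matcher (exact placements
beat 1-mismatch placements; a tag is used only if the winning stratum holds
exactly one placement), and placements falling within sense-strand exons are
summed per gene.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from deeptag.containers import CountMatrix

logger = logging.getLogger(__name__)

TAG_LENGTH = 21
READ_PORTION = 17
ANCHOR = "CATG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ProcessedTag:
    """A 21-bp tag: CATG anchor + the first 17 bases of the read."""

    sequence: str
    read_id: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != TAG_LENGTH or not self.sequence.startswith(ANCHOR):
            raise ValueError("tag must be 21 bp and start with CATG")


@dataclass(frozen=True)
class Placement:
    """A unique tag placement on the reference."""

    reference_id: str
    offset: int  # 0-based start of the 21-mer on the forward strand
    strand: str  # '+' or '-'
    mismatches: int = 0

    @property
    def interval(self) -> tuple[int, int]:
        return self.offset, self.offset + TAG_LENGTH


@dataclass
class ExonAnnotation:
    """Exon structure of one gene; internal coordinates 0-based half-open."""

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        for start, end in self.exons:
            if start < 0 or start >= end:
                raise ValueError(f"invalid exon interval ({start}, {end}) for {self.gene_id}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def contains(self, start: int, end: int) -> bool:
        """Interval lies entirely within one exon."""
        return any(s <= start and end <= e for s, e in self.exons)


def process_raw_read(read: str, read_id: str = "") -> ProcessedTag | None:
    """Trim a raw read to 17 bp and prepend the CATG anchor.

    Returns ``None`` for reads shorter than 17 bases (caller tallies these
    as QC discards).
    """
    read = read.upper()
    if len(read) < READ_PORTION:
        return None
    return ProcessedTag(ANCHOR + read[:READ_PORTION], read_id)


def filter_samples(read_tallies: Mapping[str, int], min_reads: int) -> list[str]:
    """Samples with at least ``min_reads`` raw reads, in input order."""
    if any(v < 0 for v in read_tallies.values()):
        raise ValueError("read tallies must be nonnegative")
    kept = [s for s, n in read_tallies.items() if n >= min_reads]
    if not kept:
        warnings.warn("no sample passed the read-depth filter", stacklevel=2)
    return kept


class TagIndex:
    """Exact-lookup index of every 21-mer on both strands of the reference.

    Reverse-strand placements are keyed by the reverse complement of the
    forward-strand window, so a lookup with a tag sequence finds every
    position where the tag would align (sense to either strand).
    """

    def __init__(self, reference: Mapping[str, str]):
        self.reference = {rid: seq.upper() for rid, seq in reference.items()}
        self._index: dict[str, list[Placement]] = defaultdict(list)
        for rid, seq in self.reference.items():
            for off in range(len(seq) - TAG_LENGTH + 1):
                window = seq[off : off + TAG_LENGTH]
                self._index[window].append(Placement(rid, off, "+"))
                self._index[revcomp(window)].append(Placement(rid, off, "-"))

    def lookup(self, kmer: str) -> list[Placement]:
        return self._index.get(kmer, [])

    def __len__(self) -> int:
        return len(self._index)


def _one_mismatch_variants(tag: str) -> Iterator[str]:
    for i, base in enumerate(tag):
        for sub in "ACGT":
            if sub != base:
                yield tag[:i] + sub + tag[i + 1 :]


def place_tag(tag: ProcessedTag, index: TagIndex, max_mismatch: int = 1) -> Placement | str:
    """Best-stratum unique placement of a tag.

    Exact placements are searched first; only if there are none is the
    1-mismatch stratum searched.  The tag is accepted iff the winning
    stratum contains exactly one placement; otherwise the verdict string
    ``"ambiguous"`` (>1) or ``"unplaced"`` (0) is returned.  N bases never
    match (an N in the tag consumes the mismatch allowance).
    """
    exact = index.lookup(tag.sequence)
    if len(exact) == 1:
        return exact[0]
    if len(exact) > 1:
        return "ambiguous"
    if max_mismatch >= 1:
        hits: list[Placement] = []
        for variant in _one_mismatch_variants(tag.sequence):
            for pl in index.lookup(variant):
                hits.append(Placement(pl.reference_id, pl.offset, pl.strand, mismatches=1))
        if len(hits) == 1:
            return hits[0]
        if len(hits) > 1:
            return "ambiguous"
    return "unplaced"


@dataclass
class QCReport:
    """Per-sample tallies of the processing funnel."""

    reads_in: Counter = field(default_factory=Counter)
    too_short: Counter = field(default_factory=Counter)
    placed: Counter = field(default_factory=Counter)
    ambiguous: Counter = field(default_factory=Counter)
    unplaced: Counter = field(default_factory=Counter)
    counted: Counter = field(default_factory=Counter)

    def to_frame(self) -> pd.DataFrame:
        samples = sorted(self.reads_in)
        rows = {
            name: [getattr(self, name).get(s, 0) for s in samples]
            for name in ("reads_in", "too_short", "placed", "ambiguous", "unplaced", "counted")
        }
        return pd.DataFrame(rows, index=pd.Index(samples, name="sample"))


def count_per_gene(
    placements: Iterable[tuple[str, Placement]],
    annotation: Sequence[ExonAnnotation],
    samples: pd.DataFrame,
    *,
    multi_gene: str = "count_all",
    qc: QCReport | None = None,
) -> CountMatrix:
    """Sum sense-exonic placements per gene into a count matrix.

    A placement contributes to gene *g* iff its 21-bp interval lies within an
    exon of *g* on *g*'s chromosome and its strand equals *g*'s strand.
    Contributions are summed over all positions within a gene.  When a
    placement falls in sense exons of several genes, ``multi_gene`` selects
    between crediting each gene (``"count_all"``, default) and discarding the
    placement (``"discard"``).

    Parameters
    ----------
    placements
        Iterable of ``(sample_id, Placement)``.
    annotation
        Exon annotations; the row universe of the output is the union of all
        annotated genes (genes without placements keep zero rows).
    samples
        Sample sheet; every sample id seen in ``placements`` must be present.
    """
    if multi_gene not in ("count_all", "discard"):
        raise ValueError("multi_gene must be 'count_all' or 'discard'")
    by_chrom: dict[str, list[ExonAnnotation]] = defaultdict(list)
    for ann in annotation:
        by_chrom[ann.chromosome].append(ann)
    genes = [ann.gene_id for ann in annotation]
    counts: dict[str, Counter] = defaultdict(Counter)
    known_samples = set(samples.index)
    for sample_id, pl in placements:
        if sample_id not in known_samples:
            raise KeyError(f"sample {sample_id!r} missing from the sample sheet")
        start, end = pl.interval
        hits = [
            ann.gene_id
            for ann in by_chrom.get(pl.reference_id, ())
            if ann.strand == pl.strand and ann.contains(start, end)
        ]
        if multi_gene == "discard" and len(hits) > 1:
            continue
        for gid in hits:
            counts[sample_id][gid] += 1
        if hits and qc is not None:
            qc.counted[sample_id] += 1
    mat = pd.DataFrame(
        {s: [counts[s].get(g, 0) for g in genes] for s in samples.index},
        index=pd.Index(genes, name="gene"),
        dtype=int,
    )
    chroms = pd.Series({ann.gene_id: ann.chromosome for ann in annotation}, name="chromosome")
    return CountMatrix(mat, samples, chroms)


def process_sample_reads(
    reads: Iterable[tuple[str, str]],
    index: TagIndex,
    sample_id: str,
    qc: QCReport,
    max_mismatch: int = 1,
) -> Iterator[tuple[str, Placement]]:
    """Full read -> placement funnel for one sample, updating QC tallies."""
    for read_id, seq in reads:
        qc.reads_in[sample_id] += 1
        tag = process_raw_read(seq, read_id)
        if tag is None:
            qc.too_short[sample_id] += 1
            continue
        verdict = place_tag(tag, index, max_mismatch=max_mismatch)
        if isinstance(verdict, Placement):
            qc.placed[sample_id] += 1
            yield sample_id, verdict
        elif verdict == "ambiguous":
            qc.ambiguous[sample_id] += 1
        else:
            qc.unplaced[sample_id] += 1
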