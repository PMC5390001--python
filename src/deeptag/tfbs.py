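"""Promoter extraction and motif over-representation.

Promoters are the 1000 bp immediately upstream of a gene's first exon.
Motif occurrence is judged by a position-weight-matrix log-odds scan of both
strands, a promoter counting as a hit when any window reaches a configurable
fraction of the motif's maximal score.  Over-representation of a motif in a
study promoter set is assessed against a GC-matched random-promoter
background (default 3000 promoters), keeping only motifs whose background
hit frequency is at least 10 %.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from deeptag.enrich import hypergeom_pvalue
from deeptag.tagproc import ExonAnnotation, revcomp

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class Promoter:
    gene_id: str
    sequence: str
    clipped: bool = False

    @property
    def gc_fraction(self) -> float:
        seq = self.sequence
        if not seq:
            return 0.0
        return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass
class PromoterSet:
    promoters: list[Promoter]

    def __len__(self) -> int:
        return len(self.promoters)

    def __iter__(self):
        return iter(self.promoters)

    @property
    def gc_fractions(self) -> np.ndarray:
        return np.array([p.gc_fraction for p in self.promoters])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [p.gene_id for p in self.promoters],
                "gc": self.gc_fractions,
                "clipped": [p.clipped for p in self.promoters],
                "sequence": [p.sequence for p in self.promoters],
            }
        )


@dataclass
class MotifModel:
    """Position frequency matrix with log-odds scoring.

    ``pfm`` has shape (4, L) in A, C, G, T row order; columns are normalized
    to sum to 1 after adding ``pseudocount``.  A window scores
    ``sum_l log2(p[base_l, l] / background[base_l])`` and the promoter-level
    hit threshold is ``threshold_fraction`` of the maximal achievable score.
    """

    name: str
    pfm: np.ndarray
    pseudocount: float = 0.01
    threshold_fraction: float = 0.8
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.pfm = np.asarray(self.pfm, dtype=float)
        if self.pfm.shape[0] != 4 or self.pfm.shape[1] < 4:
            raise ValueError("PFM must be 4 x L with L >= 4")
        if (self.pfm < 0).any():
            raise ValueError("PFM entries must be nonnegative")
        probs = self.pfm + self.pseudocount
        self.probabilities = probs / probs.sum(axis=0, keepdims=True)

    @property
    def length(self) -> int:
        return self.pfm.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probabilities / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probabilities.argmax(axis=0))


def encode_sequence(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX.get(c, 4) for c in seq.upper()), dtype=np.int8, count=len(seq))


def _window_scores(encoded: np.ndarray, scores5: np.ndarray, L: int) -> np.ndarray:
    if len(encoded) < L:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
    return scores5[windows, np.arange(L)].sum(axis=1)


def scan_motif(sequence: str, motif: MotifModel) -> bool:
    """True iff any window on either strand reaches the score threshold.

    Windows containing N never hit.
    """
    L = motif.length
    if len(sequence) < L:
        return False
    threshold = motif.threshold_fraction * motif.max_score
    # row 4 = N: large negative so any N-containing window scores below threshold
    scores5 = np.vstack([motif.log_odds, np.full((1, L), -1e9)])
    enc = encode_sequence(sequence)
    for strand_enc in (enc, encode_sequence(revcomp(sequence))):
        if (_window_scores(strand_enc, scores5, L) >= threshold).any():
            return True
    return False


def extract_promoters(
    annotation: Sequence[ExonAnnotation],
    reference: Mapping[str, str],
    length: int = 1000,
) -> PromoterSet:
    """The ``length`` bases immediately 5' of each gene's first exon.

    For minus-strand genes the first exon is the one with the largest
    genomic coordinate and the promoter is the reverse complement of the
    ``length`` bases 3' of it.  Promoters clipped at a reference edge are
    flagged; genes on absent references are skipped with a warning.
    """
    out: list[Promoter] = []
    for ann in annotation:
        if ann.chromosome not in reference:
            warnings.warn(f"gene {ann.gene_id}: reference {ann.chromosome!r} absent, skipped", stacklevel=2)
            continue
        chrom = reference[ann.chromosome].upper()
        if ann.strand == "+":
            tss = min(start for start, _ in ann.exons)
            lo = max(0, tss - length)
            seq = chrom[lo:tss]
            clipped = tss - length < 0
        else:
            tss = max(end for _, end in ann.exons)
            hi = min(len(chrom), tss + length)
            seq = revcomp(chrom[tss:hi])
            clipped = tss + length > len(chrom)
        out.append(Promoter(ann.gene_id, seq, clipped))
    return PromoterSet(out)


def sample_gc_matched_background(
    pool: PromoterSet,
    study: PromoterSet,
    n_background: int = 3000,
    gc_bin_width: float = 0.05,
    seed: int | None = 0,
) -> PromoterSet:
    """Background promoters matching the study set's GC histogram.

    ``n_background`` promoters are drawn without replacement from ``pool`` so
    that the GC-bin histogram of the background is proportional to the study
    set's (largest-remainder rounding to hit ``n_background`` exactly).
    """
    if len(pool) < n_background:
        raise ValueError(
            f"pool of {len(pool)} promoters cannot supply {n_background} background promoters"
        )
    rng = np.random.default_rng(seed)
    bins = np.floor(study.gc_fractions / gc_bin_width).astype(int)
    pool_bins = np.floor(pool.gc_fractions / gc_bin_width).astype(int)
    uniq, study_counts = np.unique(bins, return_counts=True)
    # largest-remainder apportionment of n_background across occupied bins
    quota = n_background * study_counts / study_counts.sum()
    base = np.floor(quota).astype(int)
    rem = n_background - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:rem]] += 1
    chosen: list[Promoter] = []
    for b, need in zip(uniq, base):
        if need == 0:
            continue
        candidates = np.flatnonzero(pool_bins == b)
        if len(candidates) < need:
            raise ValueError(
                f"GC bin [{b * gc_bin_width:.2f}, {(b + 1) * gc_bin_width:.2f}) "
                f"needs {need} promoters but the pool holds {len(candidates)}"
            )
        for i in rng.choice(candidates, size=need, replace=False):
            chosen.append(pool.promoters[int(i)])
    return PromoterSet(chosen)


def motif_hit_frequencies(
    promoters: PromoterSet, motifs: Sequence[MotifModel]
) -> pd.DataFrame:
    """Per-motif hit indicator matrix summarised as counts and frequencies."""
    rows = []
    for motif in motifs:
        hits = sum(scan_motif(p.sequence, motif) for p in promoters)
        rows.append({"motif": motif.name, "hits": hits, "n": len(promoters)})
    df = pd.DataFrame(rows).set_index("motif")
    df["frequency"] = df["hits"] / df["n"]
    return df


def tfbs_overrepresentation(
    study: PromoterSet,
    background: PromoterSet,
    motifs: Sequence[MotifModel],
    min_random_freq: float = 0.10,
    test: str = "fisher",
) -> pd.DataFrame:
    """Motif over-representation in study vs background promoters.

    Per motif, the hit frequency (fraction of promoters with >= 1 scoring
    window) is computed in both sets; motifs whose background frequency is
    below ``min_random_freq`` are dropped; the p-value is a one-sided exact
    test on the 2x2 hit/no-hit table (``test="fisher"``) or a one-sided
    two-proportion z-test (``test="ztest"``).  Rows are sorted by p.
    """
    if not len(study) or not len(background):
        raise ValueError("study and background promoter sets must be nonempty")
    if test not in ("fisher", "ztest"):
        raise ValueError("test must be 'fisher' or 'ztest'")
    study_freq = motif_hit_frequencies(study, motifs)
    bg_freq = motif_hit_frequencies(background, motifs)
    rows = []
    for motif in motifs:
        fs = study_freq.loc[motif.name]
        fb = bg_freq.loc[motif.name]
        if fb["frequency"] < min_random_freq:
            continue
        a, n1 = int(fs["hits"]), int(fs["n"])
        c, n2 = int(fb["hits"]), int(fb["n"])
        if test == "fisher":
            # one-sided: study hits at least as extreme as observed, margins fixed
            p = hypergeom_pvalue(N=n1 + n2, K=a + c, n=n1, a=a, alternative="greater")
        else:
            pool = (a + c) / (n1 + n2)
            se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
            z = 0.0 if se == 0 else (a / n1 - c / n2) / se
            p = float(stats.norm.sf(z))
        rows.append(
            {
                "motif": motif.name,
                "study_freq": fs["frequency"],
                "random_freq": fb["frequency"],
                "study_hits": a,
                "n_study": n1,
                "random_hits": c,
                "n_random": n2,
                "p_value": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "motif",
            "study_freq",
            "random_freq",
            "study_hits",
            "n_study",
            "random_hits",
            "n_random",
            "p_value",
        ],
    )
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)
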