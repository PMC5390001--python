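"""Gene-set over-representation statistics.

Exact hypergeometric (Fisher) tests of the overlap between a study gene list
and annotation sets against a stated gene universe, with the filters used
for annotation-term screening (minimum overlap, nominal alpha) and the
cross-set deduplication rule for cell-type marker lists.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Above this universe size the exact integer enumeration switches to
#: floating-point log-pmf enumeration (tie tolerance 1e-9 relative).
_EXACT_N_LIMIT = 2000


@dataclass
class GeneSet:
    """A named gene list; members are held as a set (duplicates collapse)."""

    name: str
    members: frozenset[str]
    source: str = ""

    def __init__(self, name: str, members: Iterable[str], source: str = ""):
        self.name = name
        self.members = frozenset(members)
        self.source = source

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class EnrichmentRow:
    """One 2x2 overlap test: study list vs one annotation set."""

    name: str
    universe_size: int  # N
    set_size: int  # K (annotation genes inside the universe)
    study_size: int  # n
    overlap: int  # a
    p_value: float
    odds_ratio: float  # cross-product (a*d)/(b*c); may be 0, inf or nan
    odds_ratio_corrected: float  # Haldane-Anscombe +0.5 applied iff any cell is 0

    def table(self) -> np.ndarray:
        a = self.overlap
        b = self.study_size - a
        c = self.set_size - a
        d = self.universe_size - self.set_size - self.study_size + a
        return np.array([[a, b], [c, d]])


def hypergeom_pvalue(N: int, K: int, n: int, a: int, alternative: str = "two-sided") -> float:
    """Exact hypergeometric p-value for an overlap of ``a``.

    ``two-sided`` sums the probabilities of all overlap values whose
    probability does not exceed the observed table's; ``greater``/``less``
    are the upper/lower tails including the observed value.  For universes
    up to a few thousand genes the computation is exact integer arithmetic;
    beyond that a log-pmf enumeration with a 1e-9 relative tie tolerance
    is used.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K <= N and 0 <= n <= N")
    lo, hi = max(0, n - (N - K)), min(n, K)
    if not (lo <= a <= hi):
        raise ValueError(f"overlap {a} outside the feasible range [{lo}, {hi}]")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError("alternative must be 'two-sided', 'greater' or 'less'")
    if alternative == "greater":
        return float(stats.hypergeom.sf(a - 1, N, K, n))
    if alternative == "less":
        return float(stats.hypergeom.cdf(a, N, K, n))
    support = range(lo, hi + 1)
    if N <= _EXACT_N_LIMIT:
        nums = [comb(K, j) * comb(N - K, n - j) for j in support]
        obs = nums[a - lo]
        selected = sum(v for v in nums if v <= obs)
        return float(Fraction(selected, comb(N, n)))
    js = np.arange(lo, hi + 1)
    logpmf = stats.hypergeom.logpmf(js, N, K, n)
    obs = logpmf[a - lo]
    return float(min(1.0, np.exp(logpmf[logpmf <= obs + 1e-9]).sum()))


def _odds_ratios(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.float64(a) * d / (np.float64(b) * c)
    if min(a, b, c, d) == 0:
        corrected = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        corrected = float(raw)
    return float(raw), float(corrected)


def fisher_enrichment(
    study: GeneSet,
    annot: GeneSet,
    universe: GeneSet,
    alternative: str = "two-sided",
    or_estimator: str = "cross-product",
) -> EnrichmentRow:
    """Exact test of the overlap between a study list and an annotation set.

    The 2x2 table is (a = |study ∩ annot|, b = n − a, c = K − a,
    d = N − K − n + a) with K the annotation members inside the universe.
    The odds ratio defaults to the unconditional cross-product estimate
    (Haldane–Anscombe +0.5 on all cells iff any cell is zero, reported in a
    separate field); ``or_estimator="conditional"`` reports the conditional
    MLE in ``odds_ratio_corrected`` instead.
    """
    outside = study.members - universe.members
    if outside:
        raise ValueError(f"study genes outside the universe: {sorted(outside)[:10]}")
    N = len(universe)
    K = len(annot.members & universe.members)
    n = len(study)
    a = len(study.members & annot.members & universe.members)
    b, c, d = n - a, K - a, N - K - n + a
    p = hypergeom_pvalue(N, K, n, a, alternative=alternative)
    raw, corrected = _odds_ratios(a, b, c, d)
    if or_estimator == "conditional":
        corrected = float(stats.contingency.odds_ratio([[a, b], [c, d]], kind="conditional").statistic)
    elif or_estimator != "cross-product":
        raise ValueError("or_estimator must be 'cross-product' or 'conditional'")
    return EnrichmentRow(annot.name, N, K, n, a, p, raw, corrected)


def dedup_celltype_lists(lists: Sequence[GeneSet]) -> list[GeneSet]:
    """Remove genes occurring in two or more of the input lists from all of them.

    Within-list duplicates collapse by set semantics and do not trigger the
    rule; only cross-list repetition does.
    """
    seen: dict[str, int] = {}
    for gs in lists:
        for g in gs.members:
            seen[g] = seen.get(g, 0) + 1
    shared = {g for g, k in seen.items() if k >= 2}
    return [GeneSet(gs.name, gs.members - shared, gs.source) for gs in lists]


def term_overrepresentation(
    study: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    universe: GeneSet,
    min_genes: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen annotation terms for one-sided enrichment in a study list.

    A term is retained iff its overlap with the study list is at least
    ``min_genes`` AND its one-sided enrichment p is below ``alpha``.
    Rows are sorted by p.
    """
    if not term_map:
        raise ValueError("term map is empty")
    study_set = GeneSet("study", study)
    if not len(study_set):
        warnings.warn("empty study list: no term can be enriched", stacklevel=2)
    rows = []
    for term, members in term_map.items():
        row = fisher_enrichment(
            study_set, GeneSet(term, members), universe, alternative="greater"
        )
        if row.overlap >= min_genes and row.p_value < alpha:
            rows.append(row)
    df = pd.DataFrame(
        [
            {
                "term": r.name,
                "N": r.universe_size,
                "K": r.set_size,
                "n": r.study_size,
                "overlap": r.overlap,
                "p_value": r.p_value,
                "odds_ratio": r.odds_ratio,
                "odds_ratio_corrected": r.odds_ratio_corrected,
            }
            for r in rows
        ],
        columns=["term", "N", "K", "n", "overlap", "p_value", "odds_ratio", "odds_ratio_corrected"],
    )
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)
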