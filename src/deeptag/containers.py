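"""Shared in-memory containers for the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPE_LEVELS = ("WT", "MUT")
TREATMENT_LEVELS = ("SHAM", "CSD")

#: Canonical ordering of the four experimental groups.
GROUP_ORDER = ("WT.SHAM", "WT.CSD", "MUT.SHAM", "MUT.CSD")


def group_labels(samples: pd.DataFrame) -> pd.Series:
    """Per-sample group label ``<genotype>.<treatment>``."""
    return samples["genotype"].astype(str) + "." + samples["treatment"].astype(str)


@dataclass
class CountMatrix:
    """Gene-level integer tag counts with the factorial sample layout.

    Parameters
    ----------
    counts
        genes x samples DataFrame of nonnegative integers.
    samples
        Per-sample metadata indexed by sample id, with ``genotype`` in
        {WT, MUT} and ``treatment`` in {SHAM, CSD}.
    chromosomes
        Optional per-gene chromosome label (needed for effect-list assembly).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    chromosomes: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            self.samples = self.samples.loc[self.counts.columns]
        self.validate()

    def validate(self) -> None:
        vals = self.counts.to_numpy()
        if vals.size and ((vals < 0).any() or not np.allclose(vals, np.round(vals))):
            raise ValueError("counts must be nonnegative integers")
        for col, levels in (("genotype", GENOTYPE_LEVELS), ("treatment", TREATMENT_LEVELS)):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet lacks required column {col!r}")
            bad = set(self.samples[col].astype(str)) - set(levels)
            if bad:
                raise ValueError(f"unknown {col} levels: {sorted(bad)}")
        if self.chromosomes is not None:
            self.chromosomes = self.chromosomes.reindex(self.counts.index)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        """Column sums (total placed tags per sample)."""
        return self.counts.sum(axis=0)

    @property
    def groups(self) -> pd.Series:
        return group_labels(self.samples)

    def has_complete_design(self) -> bool:
        """All four genotype x treatment groups present."""
        return set(self.groups) == set(GROUP_ORDER)

    def drop_all_zero_genes(self) -> tuple["CountMatrix", pd.Index]:
        """Split off genes with zero counts in every sample."""
        zero = self.counts.sum(axis=1) == 0
        kept = CountMatrix(
            self.counts.loc[~zero],
            self.samples,
            None if self.chromosomes is None else self.chromosomes.loc[~zero],
        )
        return kept, self.counts.index[zero]
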