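"""Voxel-atlas spatial co-expression network and gene-set permutation test.

A probes x voxels expression matrix (with missing entries) is reduced to a
gene-gene cosine co-expression network: voxels with too much missingness are
dropped, cosine similarity is computed between all probe pairs over their
jointly observed voxels, and probe-pair similarities are averaged per gene
pair.  The spatial coherence of a gene set is then scored as the mean
within-set similarity and compared against a permutation null of random
same-size gene sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class VoxelMatrix:
    """Probes x voxels real-valued expression with missing entries (NaN).

    ``probe_map`` assigns every probe (row) to exactly one gene.
    """

    values: pd.DataFrame
    probe_map: pd.Series

    def __post_init__(self) -> None:
        missing = set(self.values.index) - set(self.probe_map.index)
        if missing:
            raise ValueError(f"probes without a gene assignment: {sorted(missing)[:5]}")
        self.probe_map = self.probe_map.loc[self.values.index]

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass
class CoexprNetwork:
    """Symmetric gene-gene mean cosine similarity matrix.

    ``similarity`` is NaN for pairs with no defined probe pair;
    ``n_probe_pairs`` counts the probe pairs that contributed to each entry.
    """

    similarity: pd.DataFrame
    n_probe_pairs: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.similarity.index

    def edge_list(self) -> pd.DataFrame:
        genes = self.genes
        iu, ju = np.triu_indices(len(genes), k=1)
        sim = self.similarity.to_numpy()
        npp = self.n_probe_pairs.to_numpy()
        return pd.DataFrame(
            {
                "gene_a": genes[iu],
                "gene_b": genes[ju],
                "similarity": sim[iu, ju],
                "n_probe_pairs": npp[iu, ju].astype(int),
            }
        )


@dataclass
class CoexprPermResult:
    """Observed mean within-set similarity against a permutation null."""

    observed: float
    null_means: np.ndarray
    p_value: float
    tail: str
    set_size: int
    seed: int | None

    @property
    def n_permutations(self) -> int:
        return len(self.null_means)


def filter_matrix(
    matrix: VoxelMatrix, max_missing: float = 0.75, *, filter_probes: bool = False
) -> tuple[VoxelMatrix, dict[str, int]]:
    """Drop voxels (and optionally probes) with missingness above ``max_missing``.

    The rule is strictly greater-than: a voxel with exactly 75 % missing
    entries is retained at the default threshold.
    """
    vals = matrix.values
    voxel_missing = vals.isna().mean(axis=0)
    keep_vox = voxel_missing <= max_missing
    removed = {"voxels_removed": int((~keep_vox).sum()), "probes_removed": 0}
    vals = vals.loc[:, keep_vox]
    if vals.shape[1] == 0:
        raise ValueError("all voxels removed by the missingness filter")
    if filter_probes:
        probe_missing = vals.isna().mean(axis=1)
        keep_probe = probe_missing <= max_missing
        removed["probes_removed"] = int((~keep_probe).sum())
        vals = vals.loc[keep_probe]
    logger.info(
        "missingness filter: removed %d voxels, %d probes",
        removed["voxels_removed"],
        removed["probes_removed"],
    )
    return VoxelMatrix(vals, matrix.probe_map.loc[vals.index]), removed


def probe_cosine(matrix: VoxelMatrix, min_overlap: int = 10) -> pd.DataFrame:
    """Pairwise-complete cosine similarity between all probe rows.

    The cosine of probes *i*, *j* is computed over voxels where both are
    observed.  Pairs with fewer than ``min_overlap`` shared voxels, or with a
    zero-norm vector on the overlap, are undefined (NaN).
    """
    X = matrix.values.to_numpy(dtype=float)
    observed = ~np.isnan(X)
    Xz = np.where(observed, X, 0.0)
    obs = observed.astype(float)
    dot = Xz @ Xz.T
    # sum of x_i^2 over voxels where probe j is also observed
    sq_on_other = (Xz**2) @ obs.T
    overlap = obs @ obs.T
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(sq_on_other) * np.sqrt(sq_on_other.T)
        sim = dot / denom
    sim[(overlap < min_overlap) | (denom == 0)] = np.nan
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=matrix.values.index, columns=matrix.values.index)


def gene_network(probe_similarity: pd.DataFrame, probe_map: pd.Series) -> CoexprNetwork:
    """Average probe-pair similarities per gene pair.

    The value for genes (A, B) is the mean over all defined probe pairs with
    one probe of A and one of B.  Genes with no defined probe pair to any
    other gene are excluded with a warning.
    """
    probes = probe_similarity.index
    gene_of = probe_map.loc[probes].astype(str)
    genes = pd.Index(sorted(gene_of.unique()), name="gene")
    gene_idx = {g: i for i, g in enumerate(genes)}
    member = np.zeros((len(genes), len(probes)))
    for p_i, g in enumerate(gene_of):
        member[gene_idx[g], p_i] = 1.0
    S = probe_similarity.to_numpy(dtype=float).copy()
    np.fill_diagonal(S, np.nan)  # within-gene self pairs never contribute
    defined = ~np.isnan(S)
    Sz = np.where(defined, S, 0.0)
    sums = member @ Sz @ member.T
    counts = member @ defined.astype(float) @ member.T
    # same-gene pairs between distinct probes of one gene stay on the diagonal
    with np.errstate(invalid="ignore"):
        mean_sim = sums / counts
    np.fill_diagonal(mean_sim, 1.0)
    np.fill_diagonal(counts, 0)
    sim_df = pd.DataFrame(mean_sim, index=genes, columns=genes)
    cnt_df = pd.DataFrame(counts, index=genes, columns=genes)
    off_diag_defined = cnt_df.to_numpy().sum(axis=1) > 0
    dropped = genes[~off_diag_defined]
    if len(dropped):
        warnings.warn(
            f"{len(dropped)} gene(s) have no defined probe pair and were excluded",
            stacklevel=2,
        )
        keep = genes[off_diag_defined]
        sim_df = sim_df.loc[keep, keep]
        cnt_df = cnt_df.loc[keep, keep]
    return CoexprNetwork(sim_df, cnt_df)


def _mean_within(sim: np.ndarray, idx: np.ndarray) -> float:
    sub = sim[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    vals = sub[iu]
    return float(np.nanmean(vals))


def geneset_perm_test(
    network: CoexprNetwork,
    gene_set: list[str],
    B: int = 10_000,
    tail: str = "lower",
    seed: int | None = 0,
) -> CoexprPermResult:
    """Permutation test of a gene set's mean spatial co-expression.

    The observed statistic is the mean similarity over all unordered
    within-set gene pairs; the null is built from ``B`` uniformly drawn
    same-size gene sets from the network's gene universe.  The empirical p
    is ``(1 + exceedances) / (B + 1)``, so it is never 0; ``tail`` selects
    which direction counts as extreme ("lower", "upper" or "two-sided").
    """
    if tail not in ("lower", "upper", "two-sided"):
        raise ValueError("tail must be 'lower', 'upper' or 'two-sided'")
    genes = network.genes
    missing = sorted(set(gene_set) - set(genes))
    if missing:
        raise KeyError(f"gene set members missing from the network: {missing}")
    uniq = sorted(set(gene_set))
    if len(uniq) < 2:
        raise ValueError("gene set must contain at least 2 network genes")
    pos = {g: i for i, g in enumerate(genes)}
    sim = network.similarity.to_numpy(dtype=float)
    obs_idx = np.array([pos[g] for g in uniq])
    observed = _mean_within(sim, obs_idx)
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        null[b] = _mean_within(sim, rng.choice(len(genes), size=len(uniq), replace=False))
    lower = (1 + np.sum(null <= observed)) / (B + 1)
    upper = (1 + np.sum(null >= observed)) / (B + 1)
    if tail == "lower":
        p = lower
    elif tail == "upper":
        p = upper
    else:
        p = min(1.0, 2 * min(lower, upper))
    return CoexprPermResult(observed, null, float(p), tail, len(uniq), seed)


def coexpression_ecdf_data(
    network: CoexprNetwork, gene_set: list[str], null_result: CoexprPermResult
) -> pd.DataFrame:
    """Long-format data for ECDF plots of within-set vs null mean similarities."""
    genes = network.genes
    pos = {g: i for i, g in enumerate(genes)}
    sim = network.similarity.to_numpy(dtype=float)
    idx = np.array([pos[g] for g in sorted(set(gene_set))])
    iu = np.triu_indices(len(idx), k=1)
    within = sim[np.ix_(idx, idx)][iu]
    within = within[~np.isnan(within)]
    rows = [pd.DataFrame({"value": within, "which": "gene_set_pairs"})]
    rows.append(pd.DataFrame({"value": null_result.null_means, "which": "null_set_means"}))
    return pd.concat(rows, ignore_index=True)
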