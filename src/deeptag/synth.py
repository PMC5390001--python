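"""Synthetic data generators with ground truth.

Everything the analysis consumes can be generated here with the statistical
structure the pipeline assumes: NB tag counts under the 2x2 factorial design
with planted main and interaction effects, CATG-anchored 17-bp tag reads
from a synthetic transcript reference, promoter sets with planted motif
occurrences for the GC-matched over-representation test, and voxel atlases
with planted spatially co-expressed gene modules and missing entries.
All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from deeptag.containers import CountMatrix
from deeptag.spatial import VoxelMatrix
from deeptag.tagproc import ANCHOR, READ_PORTION, TAG_LENGTH, ExonAnnotation, revcomp
from deeptag.tfbs import MotifModel, Promoter, PromoterSet

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Scenario for the NB count generator.

    Counts for gene g in sample k are NB with mean
    ``base_mean_g * (L_k / mean(L)) * 2^(x_k . beta_g)`` and dispersion
    ``phi_g``, where x_k holds intercept, genotype, treatment and
    interaction indicators.  Effect genes are disjoint; fractions must sum
    to at most 1.  Interaction genes are planted with the rising-with-
    treatment, stronger-in-mutant shape by default (``beta_treatment`` =
    half the interaction effect, both positive).
    """

    n_genes: int = 2000
    n_per_group: int = 6
    library_size_range: tuple[float, float] = (5e4, 1e5)
    frac_genotype: float = 0.0
    frac_treatment: float = 0.0
    frac_interaction: float = 0.0
    effect_size_genotype: float = 1.5
    effect_size_treatment: float = 1.5
    effect_size_interaction: float = 1.5
    signed_main_effects: bool = True
    base_mean_range: tuple[float, float] = (20.0, 500.0)
    dispersion: float = 0.1
    dispersion_spread: float = 0.0
    chromosomes: tuple[str, ...] = tuple(str(c) for c in range(1, 20))
    rng_seed: int = 0

    def validate(self) -> None:
        fracs = (self.frac_genotype, self.frac_treatment, self.frac_interaction)
        if any(f < 0 for f in fracs) or sum(fracs) > 1:
            raise ValueError("effect fractions must be nonnegative and sum to <= 1")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library_size_range must be positive and ordered")
        lo, hi = self.base_mean_range
        if lo <= 0 or hi < lo:
            raise ValueError("base_mean_range must be positive and ordered")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")


def _sample_sheet(n_per_group: int) -> pd.DataFrame:
    rows = []
    for genotype in ("WT", "MUT"):
        for treatment in ("SHAM", "CSD"):
            for r in range(n_per_group):
                rows.append((f"{genotype}.{treatment}.{r + 1}", genotype, treatment))
    return pd.DataFrame(
        [(g, t) for _, g, t in rows],
        index=pd.Index([s for s, _, _ in rows], name="sample"),
        columns=["genotype", "treatment"],
    )


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """NB counts under the factorial model, plus the ground-truth table.

    The truth table records per gene the planted log2 effects (0 for null
    genes), the base mean, the dispersion and the chromosome label.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    G = config.n_genes
    samples = _sample_sheet(config.n_per_group)
    n = len(samples)

    genes = pd.Index([f"gene{str(i + 1).zfill(5)}" for i in range(G)], name="gene")
    base_mean = np.exp(rng.uniform(*np.log(config.base_mean_range), size=G))
    if config.dispersion_spread > 0:
        phi = config.dispersion * np.exp(rng.normal(0.0, config.dispersion_spread, size=G))
    else:
        phi = np.full(G, config.dispersion)
    chrom = rng.choice(np.array(config.chromosomes), size=G)

    beta = np.zeros((G, 3))  # log2: genotype, treatment, interaction
    n_g = int(round(config.frac_genotype * G))
    n_t = int(round(config.frac_treatment * G))
    n_i = int(round(config.frac_interaction * G))
    chosen = rng.choice(G, size=n_g + n_t + n_i, replace=False)
    idx_g, idx_t, idx_i = chosen[:n_g], chosen[n_g : n_g + n_t], chosen[n_g + n_t :]

    def signs(size: int) -> np.ndarray:
        return rng.choice([-1.0, 1.0], size=size) if config.signed_main_effects else np.ones(size)

    beta[idx_g, 0] = config.effect_size_genotype * signs(n_g)
    beta[idx_t, 1] = config.effect_size_treatment * signs(n_t)
    # "cluster 1" shape: up with treatment, more strongly in the mutant
    beta[idx_i, 1] = 0.5 * config.effect_size_interaction
    beta[idx_i, 2] = config.effect_size_interaction

    lib = np.exp(rng.uniform(*np.log(config.library_size_range), size=n))
    g_ind = (samples["genotype"] == "MUT").to_numpy(float)
    t_ind = (samples["treatment"] == "CSD").to_numpy(float)
    X = np.column_stack([g_ind, t_ind, g_ind * t_ind])  # (n, 3), no intercept column

    log2_mu = np.log2(base_mean)[:, None] + beta @ X.T + np.log2(lib / lib.mean())[None, :]
    mu = 2.0**log2_mu
    counts = np.empty((G, n), dtype=np.int64)
    poisson = phi <= 0
    if poisson.any():
        counts[poisson] = rng.poisson(mu[poisson])
    if (~poisson).any():
        r = 1.0 / phi[~poisson]
        p = r[:, None] / (r[:, None] + mu[~poisson])
        counts[~poisson] = rng.negative_binomial(r[:, None], p)

    truth = pd.DataFrame(
        {
            "beta_genotype": beta[:, 0],
            "beta_treatment": beta[:, 1],
            "beta_interaction": beta[:, 2],
            "base_mean": base_mean,
            "dispersion": phi,
            "chromosome": chrom,
        },
        index=genes,
    )
    cm = CountMatrix(
        pd.DataFrame(counts, index=genes, columns=samples.index),
        samples,
        truth["chromosome"],
    )
    return cm, truth


# ---------------------------------------------------------------------------
# Transcript reference and tag reads
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _tag_site(seq: str, anchor: str = "threeprime") -> list[int]:
    """CATG positions with a full 17-mer downstream; 3'-most first if requested."""
    sites = []
    pos = seq.find(ANCHOR)
    while pos != -1:
        if pos + TAG_LENGTH <= len(seq):
            sites.append(pos)
        pos = seq.find(ANCHOR, pos + 1)
    if anchor == "threeprime":
        return sites[-1:]
    return sites


def generate_transcripts(
    n_genes: int,
    length: int = 500,
    seed: int | None = 0,
    ensure_unique_tags: bool = True,
    max_attempts: int = 200,
) -> tuple[dict[str, str], list[ExonAnnotation]]:
    """Random one-exon transcripts, each with a usable 3'-most CATG site.

    With ``ensure_unique_tags`` every transcript's 3'-most tag 21-mer occurs
    exactly once across both strands of the whole reference, so error-free
    reads place uniquely (needed for exact round-trip checks).
    """
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    tags: set[str] = set()
    for i in range(n_genes):
        gid = f"gene{str(i + 1).zfill(5)}"
        for _ in range(max_attempts):
            seq = _random_seq(rng, length)
            # plant an anchor near the 3' end and make sure it stays 3'-most
            plant = length - TAG_LENGTH - 4
            seq = seq[:plant] + ANCHOR + seq[plant + 4 :]
            tail = seq[plant + 1 :]
            j = tail.find(ANCHOR)
            while j != -1:
                tail = tail[:j] + "T" + tail[j + 1 :]
                j = tail.find(ANCHOR)
            seq = seq[: plant + 1] + tail
            site = _tag_site(seq)[-1]
            tag = seq[site : site + TAG_LENGTH]
            if not ensure_unique_tags:
                seqs[gid] = seq
                break
            if tag in tags or revcomp(tag) in tags or tag == revcomp(tag):
                continue
            candidate = dict(seqs, **{gid: seq})
            occurrences = sum(s.count(tag) + s.count(revcomp(tag)) for s in candidate.values())
            if occurrences == 1:
                seqs[gid] = seq
                tags.add(tag)
                break
        else:
            raise RuntimeError(f"could not generate a unique tag for {gid}")
    annotation = [ExonAnnotation(gid, gid, "+", [(0, len(seq))]) for gid, seq in seqs.items()]
    return seqs, annotation


def simulate_tag_reads(
    reference: dict[str, str],
    counts_per_gene: pd.Series | dict[str, int],
    error_rate: float = 0.0,
    anchor: str = "threeprime",
    seed: int | None = 0,
    read_prefix: str = "read",
) -> tuple[list[tuple[str, str]], pd.Series]:
    """Emit 17-bp reads from the bases 3' of CATG sites, sense strand.

    Each gene emits exactly ``counts_per_gene[gene]`` reads.  With
    ``anchor="threeprime"`` all reads come from the 3'-most usable CATG
    site; ``anchor="all"`` spreads them uniformly over usable sites.
    Per-base substitution errors are applied at ``error_rate``.  Genes whose
    transcript has no usable CATG site are skipped with a warning.  Returns
    the reads as ``(read_id, sequence)`` pairs plus the per-gene tally of
    reads actually emitted.
    """
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    counts = pd.Series(counts_per_gene).astype(int)
    reads: list[tuple[str, str]] = []
    tally: dict[str, int] = {}
    serial = 0
    for gene, n_reads in counts.items():
        if n_reads <= 0:
            continue
        seq = reference.get(gene)
        if seq is None:
            warnings.warn(f"gene {gene!r} absent from the reference, skipped", stacklevel=2)
            continue
        sites = _tag_site(seq, anchor=anchor)
        if not sites:
            warnings.warn(f"gene {gene!r} has no usable CATG site, skipped", stacklevel=2)
            continue
        site_choice = (
            np.full(n_reads, sites[0])
            if len(sites) == 1
            else rng.choice(np.array(sites), size=n_reads)
        )
        for site in site_choice:
            read = seq[site + 4 : site + 4 + READ_PORTION]
            if error_rate > 0:
                arr = np.array(list(read))
                hit = rng.random(READ_PORTION) < error_rate
                if hit.any():
                    subs = rng.integers(1, 4, size=int(hit.sum()))
                    base_idx = np.searchsorted(_BASES, arr[hit])
                    arr[hit] = _BASES[(base_idx + subs) % 4]
                    read = "".join(arr)
            serial += 1
            reads.append((f"{read_prefix}{serial}", read))
            tally[gene] = tally.get(gene, 0) + 1
    return reads, pd.Series(tally, dtype=int).reindex(counts.index, fill_value=0)


# ---------------------------------------------------------------------------
# Voxel atlas
# ---------------------------------------------------------------------------

@dataclass
class AtlasConfig:
    """Scenario for the synthetic voxel atlas.

    Module genes share one smooth nonnegative spatial profile plus
    independent noise; background genes get independent profiles.  Missing
    entries are injected completely at random.  A fraction of genes carry
    two probes.
    """

    n_genes: int = 200
    n_voxels: int = 400
    module_size: int = 20
    noise_sd: float = 0.3
    missing_rate: float = 0.2
    multi_probe_fraction: float = 0.2
    n_harmonics: int = 6
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("the voxel grid must contain at least one voxel")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.module_size > self.n_genes:
            raise ValueError("module_size cannot exceed n_genes")


def _smooth_profile(rng: np.random.Generator, n_voxels: int, n_harmonics: int) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi, n_voxels)
    z = np.zeros(n_voxels)
    for h in range(1, n_harmonics + 1):
        z += rng.normal(0, 1.0 / h) * np.sin(h * t) + rng.normal(0, 1.0 / h) * np.cos(h * t)
    return z


def simulate_voxel_atlas(config: AtlasConfig) -> tuple[VoxelMatrix, list[str]]:
    """Synthetic probes x voxels atlas with one planted co-expressed module."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    genes = [f"gene{str(i + 1).zfill(5)}" for i in range(config.n_genes)]
    module = genes[: config.module_size]
    module_profile = _smooth_profile(rng, config.n_voxels, config.n_harmonics)
    probe_rows: list[np.ndarray] = []
    probe_ids: list[str] = []
    probe_genes: list[str] = []
    for gi, gene in enumerate(genes):
        n_probes = 2 if rng.random() < config.multi_probe_fraction else 1
        base = (
            module_profile
            if gene in module
            else _smooth_profile(rng, config.n_voxels, config.n_harmonics)
        )
        for p in range(n_probes):
            z = base + (
                rng.normal(0.0, config.noise_sd, size=config.n_voxels)
                if config.noise_sd > 0
                else 0.0
            )
            probe_rows.append(np.exp(z))  # nonnegative expression-like values
            probe_ids.append(f"probe{gi + 1}_{p + 1}")
            probe_genes.append(gene)
    values = np.array(probe_rows)
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = np.where(mask, np.nan, values)
    df = pd.DataFrame(
        values,
        index=pd.Index(probe_ids, name="probe"),
        columns=[f"voxel{v + 1}" for v in range(config.n_voxels)],
    )
    probe_map = pd.Series(probe_genes, index=df.index, name="gene")
    return VoxelMatrix(df, probe_map), module


# ---------------------------------------------------------------------------
# Promoters with planted motifs
# ---------------------------------------------------------------------------

@dataclass
class PromoterConfig:
    """Scenario for the promoter/motif generator.

    Background sequences are i.i.d. with a per-promoter GC fraction drawn
    uniformly from ``gc_range``; the motif consensus is inserted at a random
    position in a configured fraction of study (and optionally pool)
    promoters.
    """

    n_study: int = 95
    pool_size: int = 12000
    length: int = 1000
    gc_range: tuple[float, float] = (0.35, 0.65)
    plant_fraction_study: float = 0.0
    plant_fraction_pool: float = 0.0
    n_background: int = 3000
    motif_consensus: str = "TGACGTCAGC"
    rng_seed: int = 0

    def validate(self) -> None:
        if len(self.motif_consensus) >= self.length:
            raise ValueError("motif must be shorter than the promoter length")
        if self.pool_size < self.n_background:
            raise ValueError("pool must be at least as large as the requested background")
        for f in (self.plant_fraction_study, self.plant_fraction_pool):
            if not 0 <= f <= 1:
                raise ValueError("plant fractions must lie in [0, 1]")


def motif_from_consensus(consensus: str, name: str = "planted", weight: float = 0.85) -> MotifModel:
    """A PFM concentrated on a consensus string (``weight`` on the consensus base)."""
    L = len(consensus)
    pfm = np.full((4, L), (1 - weight) / 3)
    for j, base in enumerate(consensus.upper()):
        pfm["ACGT".index(base), j] = weight
    return MotifModel(name, pfm)


def _gc_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=probs))


def simulate_promoters(
    config: PromoterConfig,
) -> tuple[PromoterSet, PromoterSet, MotifModel]:
    """Study promoters, a background pool, and the planted motif model."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    motif = motif_from_consensus(config.motif_consensus)
    cons = config.motif_consensus.upper()

    def make(n: int, prefix: str, plant_fraction: float) -> PromoterSet:
        proms = []
        planted = rng.random(n) < plant_fraction
        gcs = rng.uniform(*config.gc_range, size=n)
        for i in range(n):
            seq = _gc_sequence(rng, config.length, gcs[i])
            if planted[i]:
                pos = int(rng.integers(0, config.length - len(cons) + 1))
                seq = seq[:pos] + cons + seq[pos + len(cons) :]
            proms.append(Promoter(f"{prefix}{i + 1}", seq))
        return PromoterSet(proms)

    study = make(config.n_study, "study_gene", config.plant_fraction_study)
    pool = make(config.pool_size, "pool_gene", config.plant_fraction_pool)
    return study, pool, motif
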