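"""End-to-end pipeline driver.

Runs the analysis stages in dependency order on synthetic or user data:
``simulate`` (all synthetic inputs + ground truth), ``de`` (TMM + NB GLM
effect tables and lists), ``cluster`` (interaction-pattern k-means),
``enrich`` (gene-set over-representation), ``tfbs`` (promoter motif
over-representation) and ``spatial`` (voxel co-expression permutation
test).  Every stage writes plain-text TSV outputs before dependents start,
and a run manifest (config snapshot, version, per-output checksums,
wall-clock per stage) is always written, even on failure.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from deeptag import __version__, clustering, enrich, io, spatial, synth, tfbs
from deeptag.containers import CountMatrix
from deeptag.model import TagCountModel

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "de", "cluster", "enrich", "tfbs", "spatial")


@dataclass
class PipelineConfig:
    """Flat key-value configuration; CLI flags override file values."""

    outdir: str = "deeptag_run"
    stages: tuple[str, ...] = STAGE_ORDER
    seed: int = 0
    # simulate
    n_genes: int = 2000
    n_per_group: int = 6
    frac_genotype: float = 0.02
    frac_treatment: float = 0.03
    frac_interaction: float = 0.05
    effect_size: float = 1.5
    dispersion: float = 0.1
    # de
    alpha: float = 0.005
    prior_n: float = 10.0
    exclude_chromosomes: tuple[str, ...] = ("8",)
    interaction_exclusion: bool = True
    # cluster
    k: int = 4
    restarts: int = 50
    # tfbs
    n_background: int = 3000
    min_random_freq: float = 0.10
    gc_bin_width: float = 0.05
    plant_fraction_study: float = 0.4
    plant_fraction_pool: float = 0.1
    n_study_promoters: int = 95
    promoter_pool_size: int = 12000
    # spatial
    B: int = 1000
    tail: str = "lower"
    max_missing: float = 0.75
    min_overlap: int = 10
    atlas_genes: int = 200
    atlas_voxels: int = 400
    atlas_module_size: int = 20
    atlas_missing_rate: float = 0.2
    # optional external inputs (defaults: outputs of the simulate stage)
    counts_path: str | None = None
    samples_path: str | None = None
    gene_annotation_path: str | None = None
    gmt_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        if isinstance(cfg.exclude_chromosomes, list):
            cfg.exclude_chromosomes = tuple(str(c) for c in cfg.exclude_chromosomes)
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")


@dataclass
class RunManifest:
    """Record of one pipeline run, sufficient to re-run deterministic stages."""

    config: dict
    version: str = __version__
    stages_run: list[str] = field(default_factory=list)
    outputs: dict[str, dict[str, str]] = field(default_factory=dict)  # stage -> file -> sha256
    wall_clock: dict[str, float] = field(default_factory=dict)
    error: str | None = None

    def write(self, path: str | Path) -> None:
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")
        tmp.replace(path)  # atomic on POSIX


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _record(manifest: RunManifest, stage: str, outdir: Path, files: list[Path], t0: float) -> None:
    manifest.stages_run.append(stage)
    manifest.outputs[stage] = {str(f.relative_to(outdir)): _sha256(f) for f in files}
    manifest.wall_clock[stage] = round(time.perf_counter() - t0, 3)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage_simulate(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    sim_dir = outdir / "synthetic"
    sim_dir.mkdir(parents=True, exist_ok=True)
    sim_cfg = synth.SimConfig(
        n_genes=cfg.n_genes,
        n_per_group=cfg.n_per_group,
        frac_genotype=cfg.frac_genotype,
        frac_treatment=cfg.frac_treatment,
        frac_interaction=cfg.frac_interaction,
        effect_size_genotype=cfg.effect_size,
        effect_size_treatment=cfg.effect_size,
        effect_size_interaction=cfg.effect_size,
        dispersion=cfg.dispersion,
        rng_seed=cfg.seed,
    )
    counts, truth = synth.simulate_counts(sim_cfg)
    io.write_counts_tsv(counts.counts, sim_dir / "counts.tsv")
    io.write_sample_sheet(counts.samples, sim_dir / "samples.tsv")
    io.write_table(truth, sim_dir / "truth.tsv", index_label="gene")
    truth[["chromosome"]].to_csv(sim_dir / "gene_annotation.tsv", sep="\t", index_label="gene")

    atlas_cfg = synth.AtlasConfig(
        n_genes=cfg.atlas_genes,
        n_voxels=cfg.atlas_voxels,
        module_size=cfg.atlas_module_size,
        missing_rate=cfg.atlas_missing_rate,
        rng_seed=cfg.seed + 1,
    )
    atlas, module = synth.simulate_voxel_atlas(atlas_cfg)
    io.write_voxel_matrix(atlas, sim_dir / "atlas.tsv", sim_dir / "probe_map.tsv")
    io.write_gene_list(module, sim_dir / "atlas_module.txt")

    prom_cfg = synth.PromoterConfig(
        n_study=cfg.n_study_promoters,
        pool_size=cfg.promoter_pool_size,
        plant_fraction_study=cfg.plant_fraction_study,
        plant_fraction_pool=cfg.plant_fraction_pool,
        n_background=cfg.n_background,
        rng_seed=cfg.seed + 2,
    )
    study, pool, motif = synth.simulate_promoters(prom_cfg)
    io.write_promoters_fasta(study, sim_dir / "promoters_study.fasta")
    io.write_promoters_fasta(pool, sim_dir / "promoters_pool.fasta")
    io.write_pfms([motif], sim_dir / "motifs.pfm")

    # gene sets for the enrichment stage: the planted interaction genes plus
    # random sets from the simulated universe
    rng = np.random.default_rng(cfg.seed + 3)
    planted = truth.index[truth["beta_interaction"] != 0].tolist()
    sets = [enrich.GeneSet("planted_interaction_module", planted, "truth")]
    for i in range(5):
        members = rng.choice(truth.index.to_numpy(), size=50, replace=False)
        sets.append(enrich.GeneSet(f"random_set_{i + 1}", members, "random"))
    io.write_gmt(sets, sim_dir / "gene_sets.gmt")
    return sorted(sim_dir.iterdir())


def _load_counts(cfg: PipelineConfig, outdir: Path) -> CountMatrix:
    sim_dir = outdir / "synthetic"
    counts_path = Path(cfg.counts_path or sim_dir / "counts.tsv")
    samples_path = Path(cfg.samples_path or sim_dir / "samples.tsv")
    ann_path = Path(cfg.gene_annotation_path or sim_dir / "gene_annotation.tsv")
    counts = io.read_counts_tsv(counts_path)
    samples = io.read_sample_sheet(samples_path)
    chroms = io.read_gene_annotation_tsv(ann_path) if ann_path.exists() else None
    return CountMatrix(counts, samples, chroms)


def _stage_de(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    de_dir = outdir / "de"
    de_dir.mkdir(parents=True, exist_ok=True)
    data = _load_counts(cfg, outdir)
    results = TagCountModel(data).fit(
        alpha=cfg.alpha,
        prior_n=cfg.prior_n,
        exclude_chromosomes=cfg.exclude_chromosomes,
        interaction_exclusion=cfg.interaction_exclusion,
    )
    for effect, table in results.tests.items():
        out = table.copy()
        out["fdr_bh"] = _bh_fdr(out["p_value"].to_numpy())
        io.write_table(out, de_dir / f"de_{effect}.tsv", index_label="gene")
    io.write_table(
        results.norm_factors.to_frame(), de_dir / "norm_factors.tsv", index_label="sample"
    )
    io.write_table(results.log_cpm(), de_dir / "log_cpm.tsv", index_label="gene")
    if results.effect_lists is not None:
        el = results.effect_lists
        for name, genes in (
            ("genotype", el.genotype),
            ("csd", el.csd),
            ("interaction", el.interaction),
        ):
            io.write_gene_list(sorted(genes), de_dir / f"list_{name}.txt")
    (de_dir / "summary.txt").write_text(results.summary() + "\n")
    return sorted(de_dir.iterdir())


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reported, never used for lists)."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _stage_cluster(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    cl_dir = outdir / "cluster"
    cl_dir.mkdir(parents=True, exist_ok=True)
    de_dir = outdir / "de"
    log_cpm = pd.read_csv(de_dir / "log_cpm.tsv", sep="\t", index_col=0)
    samples = io.read_sample_sheet(
        Path(cfg.samples_path or outdir / "synthetic" / "samples.tsv")
    )
    genes = io.read_gene_list(de_dir / "list_interaction.txt")
    patterns = clustering.standardize_patterns(log_cpm, samples, genes)
    assignment = clustering.kmeans_patterns(
        patterns, k=cfg.k, restarts=cfg.restarts, seed=cfg.seed
    )
    out = patterns.copy()
    out.insert(0, "cluster", assignment.labels)
    io.write_table(out, cl_dir / "clusters.tsv", index_label="gene")
    io.write_table(assignment.centroids, cl_dir / "centroids.tsv", index_label="cluster")
    biggest = assignment.labels.index[assignment.labels == 1]
    io.write_gene_list(sorted(biggest), cl_dir / "cluster1_genes.txt")
    return sorted(cl_dir.iterdir())


def _stage_enrich(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    en_dir = outdir / "enrich"
    en_dir.mkdir(parents=True, exist_ok=True)
    gmt_path = Path(cfg.gmt_path or outdir / "synthetic" / "gene_sets.gmt")
    sets = io.read_gmt(gmt_path)
    universe = enrich.GeneSet("universe", io.read_counts_tsv(
        Path(cfg.counts_path or outdir / "synthetic" / "counts.tsv")
    ).index)
    study_genes = io.read_gene_list(outdir / "de" / "list_interaction.txt")
    table = enrich.term_overrepresentation(
        study_genes, {gs.name: gs.members for gs in sets}, universe, min_genes=5, alpha=0.05
    )
    io.write_table(table, en_dir / "term_enrichment.tsv")
    rows = []
    for gs in sets:
        r = enrich.fisher_enrichment(enrich.GeneSet("study", study_genes), gs, universe)
        rows.append(
            {
                "set": r.name, "N": r.universe_size, "K": r.set_size, "n": r.study_size,
                "overlap": r.overlap, "p_value": r.p_value, "odds_ratio": r.odds_ratio,
                "odds_ratio_corrected": r.odds_ratio_corrected,
            }
        )
    io.write_table(pd.DataFrame(rows), en_dir / "fisher_tests.tsv")
    return sorted(en_dir.iterdir())


def _stage_tfbs(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    tf_dir = outdir / "tfbs"
    tf_dir.mkdir(parents=True, exist_ok=True)
    sim_dir = outdir / "synthetic"
    study = io.read_promoters_fasta(sim_dir / "promoters_study.fasta")
    pool = io.read_promoters_fasta(sim_dir / "promoters_pool.fasta")
    motifs = io.read_pfms(sim_dir / "motifs.pfm")
    background = tfbs.sample_gc_matched_background(
        pool, study, n_background=cfg.n_background,
        gc_bin_width=cfg.gc_bin_width, seed=cfg.seed,
    )
    table = tfbs.tfbs_overrepresentation(
        study, background, motifs, min_random_freq=cfg.min_random_freq
    )
    io.write_table(table, tf_dir / "tfbs_overrepresentation.tsv")
    return sorted(tf_dir.iterdir())


def _stage_spatial(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    sp_dir = outdir / "spatial"
    sp_dir.mkdir(parents=True, exist_ok=True)
    sim_dir = outdir / "synthetic"
    atlas = io.read_voxel_matrix(sim_dir / "atlas.tsv", sim_dir / "probe_map.tsv")
    gene_set = io.read_gene_list(sim_dir / "atlas_module.txt")
    filtered, removed = spatial.filter_matrix(atlas, max_missing=cfg.max_missing)
    sims = spatial.probe_cosine(filtered, min_overlap=cfg.min_overlap)
    network = spatial.gene_network(sims, filtered.probe_map)
    io.write_table(network.edge_list(), sp_dir / "network_edges.tsv")
    result = spatial.geneset_perm_test(
        network, gene_set, B=cfg.B, tail=cfg.tail, seed=cfg.seed
    )
    summary = pd.DataFrame(
        [
            {
                "set_size": result.set_size, "observed_mean_similarity": result.observed,
                "tail": result.tail, "B": result.n_permutations, "p_value": result.p_value,
                "voxels_removed": removed["voxels_removed"],
            }
        ]
    )
    io.write_table(summary, sp_dir / "permutation_summary.tsv")
    io.write_table(
        spatial.coexpression_ecdf_data(network, gene_set, result), sp_dir / "ecdf_data.tsv"
    )
    return sorted(sp_dir.iterdir())


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "de": _stage_de,
    "cluster": _stage_cluster,
    "enrich": _stage_enrich,
    "tfbs": _stage_tfbs,
    "spatial": _stage_spatial,
}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in dependency order; manifest always written."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config))
    try:
        for stage in STAGE_ORDER:
            if stage not in config.stages:
                continue
            logger.info("[%s] starting", stage)
            t0 = time.perf_counter()
            try:
                files = _STAGE_FUNCS[stage](config, outdir)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage label
                manifest.error = f"{stage}: {exc}"
                raise StageError(stage, exc) from exc
            _record(manifest, stage, outdir, files, t0)
            logger.info("[%s] done in %.1fs", stage, manifest.wall_clock[stage])
    finally:
        manifest.write(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

def validate_inputs(
    counts_path: str | Path | None = None,
    samples_path: str | Path | None = None,
    gmt_path: str | Path | None = None,
    voxel_path: str | Path | None = None,
) -> list[str]:
    """Schema checks for user-supplied inputs; returns every violation found."""
    violations: list[str] = []
    samples = None
    if samples_path is not None:
        samples = io.read_sample_sheet(samples_path)
        for col in ("genotype", "treatment"):
            if col not in samples.columns:
                violations.append(f"sample sheet: missing column {col!r}")
        if not violations and samples is not None:
            groups = set(samples["genotype"] + "." + samples["treatment"])
            missing = {"WT.SHAM", "WT.CSD", "MUT.SHAM", "MUT.CSD"} - groups
            for g in sorted(missing):
                violations.append(f"sample sheet: experimental group {g} absent")
    if counts_path is not None:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        vals = counts.to_numpy()
        if (vals < 0).any():
            violations.append("count matrix: negative counts present")
        if not np.allclose(vals, np.round(vals)):
            violations.append("count matrix: non-integer counts present")
        if samples is not None and list(counts.columns) != list(samples.index):
            violations.append("count matrix: columns do not match the sample sheet")
    if gmt_path is not None:
        try:
            io.read_gmt(gmt_path)
        except ValueError as exc:
            violations.append(f"GMT: {exc}")
    if voxel_path is not None:
        with open(voxel_path) as fh:
            widths = {len(line.rstrip("\n").split("\t")) for line in fh if line.strip()}
        if len(widths) > 1:
            violations.append("voxel matrix: rows have inconsistent column counts")
    return violations
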