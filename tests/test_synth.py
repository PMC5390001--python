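"""Generator contracts: distributions, planted structure, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from deeptag import spatial, synth, tfbs


class TestSimulateCounts:
    def test_null_config_has_zero_truth(self):
        cm, truth = synth.simulate_counts(synth.SimConfig(n_genes=50, rng_seed=0))
        assert (truth[["beta_genotype", "beta_treatment", "beta_interaction"]] == 0).all().all()

    def test_seed_reproducibility(self):
        cfg = synth.SimConfig(n_genes=100, frac_interaction=0.1, rng_seed=7)
        a, ta = synth.simulate_counts(cfg)
        b, tb = synth.simulate_counts(cfg)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(ta, tb)

    def test_poisson_limit_variance_equals_mean(self):
        # dispersion 0: per-gene sample variance tracks the sample mean
        cfg = synth.SimConfig(
            n_genes=500, n_per_group=100, dispersion=0.0,
            base_mean_range=(100.0, 100.0), library_size_range=(1e5, 1e5), rng_seed=1,
        )
        cm, _ = synth.simulate_counts(cfg)
        ratio = cm.counts.var(axis=1, ddof=1) / cm.counts.mean(axis=1)
        assert abs(ratio.mean() - 1.0) < 0.02

    def test_null_gene_mean_recovers_base_mean(self):
        # Monte-Carlo check of the generative model: base_mean 100, equal
        # library sizes -> empirical mean within 3 SE of 100
        phi = 0.1
        cfg = synth.SimConfig(
            n_genes=2000, dispersion=phi, base_mean_range=(100.0, 100.0),
            library_size_range=(1e5, 1e5), rng_seed=3,
        )
        cm, truth = synth.simulate_counts(cfg)
        vals = cm.counts.to_numpy().ravel()
        se = np.sqrt((100 + phi * 100**2) / vals.size)
        assert abs(vals.mean() - 100.0) < 3 * se

    def test_nb_variance_mean_relationship(self):
        # across null genes the empirical variance follows Var = mu + phi mu^2
        phi = 0.2
        cfg = synth.SimConfig(
            n_genes=10_000, n_per_group=6, dispersion=phi,
            base_mean_range=(50.0, 500.0), library_size_range=(1e5, 1e5), rng_seed=4,
        )
        cm, truth = synth.simulate_counts(cfg)
        mu = truth["base_mean"].to_numpy()
        s2 = cm.counts.var(axis=1, ddof=1).to_numpy()
        expected = mu + phi * mu**2
        assert abs(s2.mean() / expected.mean() - 1.0) < 0.05

    def test_invalid_fractions_raise(self):
        with pytest.raises(ValueError):
            synth.simulate_counts(synth.SimConfig(frac_genotype=0.7, frac_treatment=0.5))
        with pytest.raises(ValueError):
            synth.simulate_counts(synth.SimConfig(n_per_group=1))
        with pytest.raises(ValueError):
            synth.simulate_counts(synth.SimConfig(library_size_range=(0, 10)))


class TestTagReads:
    def test_read_is_17mer_after_threeprime_anchor(self):
        ref = {"g1": "AAACATGTTTTTTTTTTTTTTTTTGGG"}
        reads, tally = synth.simulate_tag_reads(ref, {"g1": 5}, seed=0)
        expected = "TTTTTTTTTTTTTTTTTGGG"[:17]
        assert all(seq == expected for _, seq in reads)
        assert tally["g1"] == 5

    def test_error_free_reads_identical(self):
        ref, _ = synth.generate_transcripts(1, seed=2)
        reads, _ = synth.simulate_tag_reads(ref, {g: 100 for g in ref}, seed=1)
        assert len({seq for _, seq in reads}) == 1

    def test_error_rate_matches_binomial(self):
        # fraction of reads with >= 1 substitution ~ 1 - (1-e)^17
        ref, _ = synth.generate_transcripts(1, seed=5)
        gene = next(iter(ref))
        clean, _ = synth.simulate_tag_reads(ref, {gene: 1}, error_rate=0.0, seed=0)
        true_read = clean[0][1]
        n = 10_000
        reads, _ = synth.simulate_tag_reads(ref, {gene: n}, error_rate=0.01, seed=6)
        frac = np.mean([seq != true_read for _, seq in reads])
        p = 1 - 0.99**17
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * se

    def test_gene_without_catg_skipped_with_warning(self):
        ref = {"g1": "A" * 50}
        with pytest.warns(UserWarning, match="no usable CATG"):
            reads, tally = synth.simulate_tag_reads(ref, {"g1": 10}, seed=0)
        assert not reads and tally["g1"] == 0

    def test_unique_tags_place_uniquely(self):
        from deeptag.tagproc import TagIndex, place_tag, process_raw_read

        ref, _ = synth.generate_transcripts(30, seed=9)
        index = TagIndex(ref)
        reads, _ = synth.simulate_tag_reads(ref, {g: 1 for g in ref}, seed=10)
        for rid, seq in reads:
            verdict = place_tag(process_raw_read(seq, rid), index)
            assert not isinstance(verdict, str)


class TestVoxelAtlas:
    def test_noise_free_module_has_cosine_one(self):
        cfg = synth.AtlasConfig(n_genes=20, module_size=5, noise_sd=0.0,
                                missing_rate=0.0, multi_probe_fraction=0.0, rng_seed=0)
        atlas, module = synth.simulate_voxel_atlas(cfg)
        sims = spatial.probe_cosine(atlas, min_overlap=1)
        probes = atlas.probe_map.index[atlas.probe_map.isin(module)]
        block = sims.loc[probes, probes].to_numpy()
        assert np.allclose(block, 1.0, atol=1e-12)

    def test_high_missingness_voxels_removed_downstream(self):
        cfg = synth.AtlasConfig(n_genes=30, module_size=5, missing_rate=0.2, rng_seed=1)
        atlas, _ = synth.simulate_voxel_atlas(cfg)
        # push a handful of voxels to ~90% missingness
        rng = np.random.default_rng(2)
        bad = atlas.values.columns[:5]
        for col in bad:
            hit = rng.random(len(atlas.values)) < 0.9
            atlas.values.loc[hit, col] = np.nan
        filtered, removed = spatial.filter_matrix(atlas, max_missing=0.75)
        assert removed["voxels_removed"] >= len(bad)
        assert not set(bad) & set(filtered.values.columns)
        assert (filtered.values.isna().mean(axis=0) <= 0.75).all()

    def test_background_cosine_matches_direct_monte_carlo(self):
        # with no module, the mean pairwise gene cosine equals a direct MC
        # estimate for independent nonnegative smooth profiles
        cfg = synth.AtlasConfig(n_genes=200, module_size=0, missing_rate=0.0,
                                multi_probe_fraction=0.0, noise_sd=0.0, rng_seed=2)
        atlas, _ = synth.simulate_voxel_atlas(cfg)
        sims = spatial.probe_cosine(atlas, min_overlap=1).to_numpy()
        iu = np.triu_indices_from(sims, k=1)
        observed_mean = sims[iu].mean()
        # independent oracle: fresh profile pairs, cosine computed directly
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(2000):
            a = np.exp(synth._smooth_profile(rng, cfg.n_voxels, cfg.n_harmonics))
            b = np.exp(synth._smooth_profile(rng, cfg.n_voxels, cfg.n_harmonics))
            vals.append(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
        mc = np.array(vals)
        se = mc.std(ddof=1) * np.sqrt(1 / len(mc) + 1 / len(iu[0]))
        assert abs(observed_mean - mc.mean()) < 5 * se

    def test_zero_voxel_grid_rejected(self):
        with pytest.raises(ValueError, match="voxel"):
            synth.simulate_voxel_atlas(synth.AtlasConfig(n_voxels=0))

    def test_module_size_bounded(self):
        with pytest.raises(ValueError):
            synth.simulate_voxel_atlas(synth.AtlasConfig(n_genes=5, module_size=6))


class TestPromoters:
    def test_full_planting_puts_motif_everywhere(self):
        cfg = synth.PromoterConfig(n_study=20, pool_size=30, n_background=25,
                                   plant_fraction_study=1.0, rng_seed=0)
        study, _, motif = synth.simulate_promoters(cfg)
        for p in study:
            assert motif.consensus in p.sequence

    def test_gc_parameter_controls_gc_content(self):
        cfg = synth.PromoterConfig(n_study=200, pool_size=200, n_background=100,
                                   gc_range=(0.5, 0.5), rng_seed=1)
        study, _, _ = synth.simulate_promoters(cfg)
        gc = study.gc_fractions
        se = np.sqrt(0.25 / 1000 / len(gc))
        assert abs(gc.mean() - 0.5) < 3 * se

    def test_pool_smaller_than_background_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            synth.simulate_promoters(
                synth.PromoterConfig(pool_size=100, n_background=3000)
            ).__repr__()

    def test_unplanted_sets_are_exchangeable(self):
        # plant fraction 0 in both sets: downstream p uniform over repeats
        from scipy import stats

        ps = []
        for rep in range(60):
            # equal plant fractions keep both sets exchangeable while giving
            # a mid-range hit frequency (less p-value discreteness)
            cfg = synth.PromoterConfig(n_study=120, pool_size=120, length=300,
                                       plant_fraction_study=0.35, plant_fraction_pool=0.35,
                                       n_background=100, rng_seed=200 + rep)
            study, pool, motif = synth.simulate_promoters(cfg)
            tab = tfbs.tfbs_overrepresentation(study, pool, [motif], min_random_freq=0.0)
            ps.append(tab["p_value"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 1e-3
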