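import hashlib
from pathlib import Path

import numpy as np
import pytest

from loophub.core import io as cio
from loophub.core.intervals import GenomicInterval, overlaps
from loophub.core.loops import loop_distance
from loophub.simulate import (
    SimulationConfig,
    TruthTables,
    apply_condition_gain,
    simulate_dataset,
    simulate_speckle_track,
    write_dataset,
)

from conftest import small_sim_config


def _hash_dir(path):
    out = {}
    for f in sorted(Path(path).rglob("*")):
        if f.is_file():
            out[str(f.relative_to(path))] = hashlib.sha256(f.read_bytes()).hexdigest()
    return out


class TestConfig:
    def test_round_trip_file(self, tmp_path):
        cfg = small_sim_config(seed=3, delta_logfc=1.0)
        path = tmp_path / "cfg.txt"
        cfg.to_file(path)
        assert SimulationConfig.from_file(path) == cfg

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.txt"
        path.write_text("bogus = 1\n")
        with pytest.raises(ValueError, match="bogus"):
            SimulationConfig.from_file(path)

    def test_invalid_values(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_chrom=0)
        with pytest.raises(ValueError):
            SimulationConfig(hub_partner_range=(10, 2))
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=10, archetype_sizes=(5, 5, 5, 5))


class TestDeterminism:
    def test_fixed_seed_byte_identical_outputs(self, tmp_path):
        cfg = small_sim_config(
            seed=5, chrom_length=2_000_000, n_genes=40,
            n_constitutive_peaks=60, n_condition_specific_peaks=10, n_hubs=6,
            archetype_sizes=(3, 5, 2, 6), n_decoy_loops=5,
            loop_distance_range=(50_000, 1_000_000),
        )
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        write_dataset(simulate_dataset(cfg, with_matrix=True), d1)
        write_dataset(simulate_dataset(cfg, with_matrix=True), d2)
        h1, h2 = _hash_dir(d1), _hash_dir(d2)
        # gzip embeds mtime; compare decompressed content for .gz members
        for name in list(h1):
            if name.endswith(".gz"):
                import gzip

                a = gzip.open(d1 / name).read()
                b = gzip.open(d2 / name).read()
                assert a == b, name
                del h1[name], h2[name]
        assert h1 == h2

    def test_different_seeds_differ(self):
        a = simulate_dataset(small_sim_config(seed=1), with_matrix=False)
        b = simulate_dataset(small_sim_config(seed=2), with_matrix=False)
        assert not a.peaks.equals(b.peaks)


class TestSpeckleTrack:
    def test_gain_one_tracks_equal(self, small_ds):
        cfg = small_sim_config(speckle_gain=1.0)
        track = simulate_speckle_track(
            cfg, small_ds.genome, small_ds.truth.speckle_center_bins
        )
        spec = [
            GenomicInterval(r.chrom, r.start, r.end)
            for r in small_ds.peaks[
                small_ds.peaks.id.isin(small_ds.truth.specific_ids)
            ].itertuples()
        ]
        gained = apply_condition_gain(cfg, track, spec)
        for chrom in track.values:
            np.testing.assert_array_equal(track.values[chrom], gained.values[chrom])

    def test_zero_amplitude_matches_lognormal_moments(self):
        cfg = small_sim_config(seed=13, chrom_length=20_000_000)
        from loophub.core.intervals import Genome

        genome = Genome({"chr1": cfg.chrom_length})
        track = simulate_speckle_track(cfg, genome, [], bump_amplitude=0.0)
        logs = np.log(track.genome_values())
        n = logs.size
        sigma = cfg.speckle_baseline_sigma
        # mean of logs ~ N(0, sigma/sqrt(n)); var of logs ~ sigma^2 within 3 SE
        assert abs(logs.mean()) < 3 * sigma / np.sqrt(n)
        se_var = sigma**2 * np.sqrt(2.0 / (n - 1))
        assert abs(logs.var(ddof=1) - sigma**2) < 3 * se_var

    def test_center_bins_exceed_genome_median(self, small_ds):
        track = small_ds.tracks["A"]
        med = np.median(track.genome_values())
        for chrom, b in small_ds.truth.speckle_center_bins:
            assert track.values[chrom][b] > med


class TestPeaksAndLoops:
    def test_specific_only_in_condition_b(self, small_ds):
        spec = small_ds.peaks[small_ds.peaks.id.isin(small_ds.truth.specific_ids)]
        assert (~spec.called_A).all()
        assert spec.called_B.all()

    def test_all_features_within_bounds(self, small_ds):
        g = small_ds.genome
        for r in small_ds.peaks.itertuples():
            assert 0 <= r.start < r.end <= g.length(r.chrom)
        for lp in small_ds.loops:
            assert g.contains_interval(lp.anchor1)
            assert g.contains_interval(lp.anchor2)

    def test_loops_intra_chromosomal_within_distance_range(self, small_ds):
        lo, hi = small_ds.config.loop_distance_range
        for lp in small_ds.loops:
            assert lp.anchor1.chrom == lp.anchor2.chrom
            assert lo <= loop_distance(lp) <= hi

    def test_planted_partner_counts_match_bedpe_recount(self, small_ds, tmp_path):
        # brute-force recount from the emitted BEDPE against truth structure
        path = tmp_path / "loops.bedpe"
        cio.write_bedpe(path, small_ds.loops)
        back = cio.read_bedpe(path)
        true_loops = [
            lp for lp in back if lp.id not in set(small_ds.truth.decoy_loop_ids)
        ]
        ivs = small_ds.peak_intervals("B")
        counts = {}
        for iv in ivs:
            n = sum(
                1
                for lp in true_loops
                if overlaps(iv, lp.anchor1) or overlaps(iv, lp.anchor2)
            )
            counts[iv.name] = n
        nonhub_max = small_ds.config.nonhub_partner_range[1]
        hubs = set(small_ds.truth.hub_ids)
        spec = set(small_ds.truth.specific_ids)
        for pid, n in counts.items():
            if pid in hubs:
                assert n >= small_ds.config.hub_partner_range[0]
            elif pid in spec:
                assert n <= 1
            else:
                # small overflow above the quota is allowed when hub wiring
                # exhausts nearby capacity; the classes must stay separated
                assert n <= nonhub_max + 2
                assert n < small_ds.config.hub_partner_range[0]

    def test_no_hubs_means_no_heavy_tail(self):
        cfg = small_sim_config(
            seed=9, n_hubs=0, n_condition_specific_peaks=0, n_decoy_loops=0
        )
        ds = simulate_dataset(cfg, with_matrix=False)
        from loophub.topology import count_distinct_loops

        stats = count_distinct_loops(ds.peak_intervals("B"), ds.loops)
        assert stats.n_distinct_loops.max() <= cfg.nonhub_partner_range[1]

    def test_zero_delta_means_no_strengthened_loops(self):
        cfg = small_sim_config(seed=9, delta_logfc=0.0)
        ds = simulate_dataset(cfg, with_matrix=False)
        assert ds.truth.strengthened_loop_ids == []

    def test_decoys_have_high_fdr(self, small_ds):
        decoys = set(small_ds.truth.decoy_loop_ids)
        for lp in small_ds.loops:
            if lp.id in decoys:
                assert lp.fdr >= 0.05
            else:
                assert lp.fdr < 0.01


class TestContactMatrix:
    def test_symmetric(self, tiny_matrix_ds):
        for mat in tiny_matrix_ds.matrices.values():
            finite = np.isfinite(mat.data)
            assert np.array_equal(finite, finite.T)
            np.testing.assert_allclose(mat.data[finite], mat.data.T[finite])

    def test_diagonal_missing(self, tiny_matrix_ds):
        for mat in tiny_matrix_ds.matrices.values():
            assert np.all(np.isnan(np.diag(mat.data)))

    def test_no_noise_no_enrichment_is_pure_decay(self):
        cfg = small_sim_config(
            seed=15, chrom_length=500_000, n_genes=8, n_constitutive_peaks=20,
            n_condition_specific_peaks=0, n_hubs=4, archetype_sizes=(2, 2, 1, 3),
            n_decoy_loops=0, matrix_noise_sd=0.0, loop_pixel_enrichment=1.0,
            loop_distance_range=(50_000, 400_000),
        )
        ds = simulate_dataset(cfg, with_matrix=True)
        mat = ds.matrices["chr1"]
        n = mat.n_bins
        s = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        expected = 1.0 / (1.0 + s)
        off = ~np.eye(n, dtype=bool)
        np.testing.assert_allclose(mat.data[off], expected[off])

    def test_planted_pixel_enrichment_recovered(self):
        cfg = small_sim_config(
            seed=16, chrom_length=2_000_000, n_genes=40, n_constitutive_peaks=80,
            n_condition_specific_peaks=16, n_hubs=8, archetype_sizes=(4, 6, 2, 8),
            n_decoy_loops=0, matrix_noise_sd=0.05,
            loop_distance_range=(50_000, 1_000_000),
        )
        ds = simulate_dataset(cfg, with_matrix=True)
        ratios = []
        for lp in ds.loops:
            mat = ds.matrices[lp.chrom]
            i = lp.anchor1.center // cfg.matrix_bin
            j = lp.anchor2.center // cfg.matrix_bin
            decay = 1.0 / (1.0 + abs(i - j))
            ratios.append(mat.data[i, j] / decay)
        assert np.mean(ratios) == pytest.approx(cfg.loop_pixel_enrichment, rel=0.1)


class TestExpression:
    def test_zero_noise_makes_archetype_rows_identical(self):
        cfg = small_sim_config(seed=17, archetype_noise_sd=0.0)
        ds = simulate_dataset(cfg, with_matrix=False)
        from loophub.clusters import zscore_rows
        from loophub.simulate import expression_samples

        samples = expression_samples(cfg)
        mat = ds.expression.set_index("gene_id")[samples]
        z, valid = zscore_rows(mat.to_numpy())
        for arch in (1, 2, 3, 4):
            gids = [g for g, a in ds.truth.archetypes.items() if a == arch]
            rows = z[[list(mat.index).index(g) for g in gids]]
            assert np.allclose(rows - rows[0], 0.0)

    def test_archetype_sizes_as_configured(self, small_ds):
        sizes = small_ds.config.archetype_sizes
        for arch, size in zip((1, 2, 3, 4), sizes):
            n = sum(1 for a in small_ds.truth.archetypes.values() if a == arch)
            assert n == size

    def test_flat_genes_fail_selection_thresholds(self, small_ds):
        expr = small_ds.expression
        flat = [g for g, a in small_ds.truth.archetypes.items() if a == 0]
        sub = expr[expr.gene_id.isin(flat)]
        assert (sub.padj_B_vs_A >= 0.05).all()


class TestTruthTables:
    def test_json_round_trip(self, small_ds, tmp_path):
        path = tmp_path / "truth.json"
        small_ds.truth.to_json(path)
        back = TruthTables.from_json(path)
        assert back == small_ds.truth

    def test_every_truth_id_exists(self, small_ds):
        peak_ids = set(small_ds.peaks.id)
        loop_ids = {lp.id for lp in small_ds.loops}
        assert set(small_ds.truth.hub_ids) <= peak_ids
        assert set(small_ds.truth.specific_ids) <= peak_ids
        assert set(small_ds.truth.strengthened_loop_ids) <= loop_ids
        assert set(small_ds.truth.decoy_loop_ids) <= loop_ids
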