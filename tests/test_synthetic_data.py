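"""Generator correctness: analytic moments, confinement, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from condensate_kit import synthetic_data as sd


class TestTrajectories:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            sd.TrajectorySimConfig(state_fractions=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            sd.TrajectorySimConfig(diffusion_coeffs=(2.0, 0.3, 0.05), state_fractions=(0, 0, 1))
        with pytest.raises(ValueError):
            sd.TrajectorySimConfig(frame_interval=0.0, state_fractions=(0, 0, 1))
        with pytest.raises(ValueError):
            sd.TrajectorySimConfig(field_size=(0.0, 5.0), state_fractions=(0, 0, 1))
        with pytest.raises(ValueError):
            sd.TrajectorySimConfig(
                state_fractions=(1, 0, 0), focus_centers=((1.0, 1.0),), focus_radius=0.0
            )

    def test_zero_tracks_gives_empty_set(self):
        cfg = sd.TrajectorySimConfig(n_tracks=0, state_fractions=(0, 0, 1))
        tracks, truth = sd.simulate_trajectories(cfg)
        assert len(tracks) == 0 and len(truth) == 0

    def test_condensate_only_tracks_confined_to_focus(self):
        cfg = sd.TrajectorySimConfig(
            n_tracks=60, state_fractions=(1, 0, 0), focus_centers=((5.0, 5.0),),
            focus_radius=0.25, localization_sigma=0.03, seed=2,
        )
        tracks, truth = sd.simulate_trajectories(cfg)
        assert (truth["state"] == "condensate").all()
        r = np.hypot(tracks["x_um"] - 5.0, tracks["y_um"] - 5.0)
        assert (r <= cfg.focus_radius + 3 * cfg.localization_sigma).all()

    def test_free_mean_squared_step_matches_brownian_moment(self):
        # E[r^2] for one frame = 4*D*tau; Monte-Carlo check without noise
        D, tau = 2.0, 0.02
        cfg = sd.TrajectorySimConfig(
            n_tracks=2000, state_fractions=(0, 0, 1), diffusion_coeffs=(0.05, 0.3, D),
            localization_sigma=0.0, frame_interval=tau, seed=3,
        )
        tracks, _ = sd.simulate_trajectories(cfg)
        r2 = []
        for _, g in tracks.groupby("track_id"):
            r2.append(np.diff(g["x_um"]) ** 2 + np.diff(g["y_um"]) ** 2)
        r2 = np.concatenate(r2)
        assert len(r2) >= 10_000
        expected = 4 * D * tau
        se = r2.std() / np.sqrt(len(r2))
        assert abs(r2.mean() - expected) < 3 * se

    @pytest.mark.parametrize("state,D", [(1, 0.3), (2, 2.0)])
    def test_step_lengths_follow_rayleigh_law(self, state, D):
        # single-frame step length ~ Rayleigh(sqrt(2 D tau)) for unconfined states
        frac = [0.0, 0.0, 0.0]
        frac[state] = 1.0
        cfg = sd.TrajectorySimConfig(
            n_tracks=2000, state_fractions=tuple(frac), localization_sigma=0.0, seed=4,
        )
        tracks, _ = sd.simulate_trajectories(cfg)
        steps = []
        for _, g in tracks.groupby("track_id"):
            steps.append(np.hypot(np.diff(g["x_um"]), np.diff(g["y_um"])))
        steps = np.concatenate(steps)[:10_000]
        scale = np.sqrt(2 * D * cfg.frame_interval)
        assert stats.kstest(steps, "rayleigh", args=(0, scale)).pvalue > 0.01

    def test_seeded_runs_identical(self):
        cfg = sd.TrajectorySimConfig(n_tracks=50, state_fractions=(0, 0.5, 0.5), seed=9)
        t1, _ = sd.simulate_trajectories(cfg)
        t2, _ = sd.simulate_trajectories(cfg)
        pd.testing.assert_frame_equal(t1, t2)


class TestCellImages:
    def test_no_foci_no_noise_is_constant(self):
        masks = sd.make_cell_masks((64, 64), n_cells=2, seed=0)
        truth = sd.SyntheticImageTruth(masks, [], background_level=50.0, noise_sigma=0.0)
        img = sd.render_cell_image(truth, seed=0)
        assert np.allclose(img[0], 50.0)

    def test_bright_spot_is_global_maximum(self):
        masks = sd.make_cell_masks((128, 128), n_cells=4, seed=1)
        rr, cc = np.nonzero(masks > 0)
        p = (float(rr[10]), float(cc[10]))
        truth = sd.SyntheticImageTruth(masks, [(p, 2.0, 40.0)], noise_sigma=5.0)
        img = sd.render_cell_image(truth, seed=2)
        peak = np.unravel_index(np.argmax(img[0]), img[0].shape)
        assert abs(peak[0] - p[0]) <= 1 and abs(peak[1] - p[1]) <= 1

    def test_focus_outside_cell_rejected(self):
        masks = sd.make_cell_masks((64, 64), n_cells=1, seed=0)
        bg = np.argwhere(masks == 0)[0]
        with pytest.raises(ValueError):
            sd.SyntheticImageTruth(masks, [((float(bg[0]), float(bg[1])), 2.0, 10.0)])

    def test_seeded_renders_identical(self):
        masks = sd.make_cell_masks((64, 64), n_cells=2, seed=0)
        truth = sd.SyntheticImageTruth(masks, [], noise_sigma=3.0)
        a = sd.render_cell_image(truth, seed=5)
        b = sd.render_cell_image(truth, seed=5)
        assert a.tobytes() == b.tobytes()


class TestDropletFields:
    def test_empty_shape_list_is_pure_noise(self):
        img, truth = sd.render_droplet_field([], shape=(64, 64), seed=0)
        assert len(truth) == 0
        assert img.std() < 0.1

    def test_disk_truth_area_matches_rasterization(self):
        img, truth = sd.render_droplet_field(
            [sd.ShapeSpec("disk", (50, 50), (10, 10))], shape=(128, 128), seed=0
        )
        assert abs(truth.loc[0, "area_px"] - np.pi * 100) / (np.pi * 100) < 0.05

    def test_ellipse_axis_ratio(self):
        _, truth = sd.render_droplet_field(
            [sd.ShapeSpec("ellipse", (60, 60), (20, 10))], shape=(128, 128), seed=0
        )
        assert truth.loc[0, "axis_ratio"] == 2.0

    def test_overlapping_shapes_rejected(self):
        shapes = [sd.ShapeSpec("disk", (50, 50), (10, 10)), sd.ShapeSpec("disk", (55, 55), (10, 10))]
        with pytest.raises(ValueError):
            sd.render_droplet_field(shapes, shape=(128, 128))
        img, truth = sd.render_droplet_field(shapes, shape=(128, 128), allow_overlap=True)
        assert len(truth) == 2


class TestDecayCounts:
    def test_no_decay_flag_gives_flat_expectations(self):
        cfg = sd.DecaySimConfig(
            n_genes=300, no_decay=True, a_range=(500, 500.01), n_replicates=2,
            library_size_factors=(1.0,) * 8, seed=1,
        )
        counts, samples, _ = sd.simulate_decay_counts(cfg)
        gene_rows = counts.loc[~counts.index.str.startswith("ERCC-")]
        means = gene_rows.T.groupby(samples["timepoint_min"]).mean().mean(axis=1)
        # all timepoints share the same Poisson mean of 500
        assert np.allclose(means, 500.0, rtol=0.02)

    def test_seeded_matrix_identical(self):
        cfg = sd.DecaySimConfig(n_genes=20, seed=6)
        c1, _, _ = sd.simulate_decay_counts(cfg)
        c2, _, _ = sd.simulate_decay_counts(cfg)
        pd.testing.assert_frame_equal(c1, c2)

    def test_poisson_mean_at_one_time_constant(self):
        # b = 30 -> expectation at t=30 is a/e; check with 200 replicate samples
        a, b = 800.0, 30.0
        cfg = sd.DecaySimConfig(
            n_genes=1, a_range=(a, a + 1e-9), b_range=(b, b + 1e-9),
            timepoints=(0.0, 30.0), n_replicates=200,
            library_size_factors=(1.0,) * 400, seed=2,
        )
        counts, samples, _ = sd.simulate_decay_counts(cfg)
        at30 = counts.iloc[0][samples["timepoint_min"] == 30.0].to_numpy(float)
        expected = a * np.exp(-1.0)
        se = np.sqrt(expected / len(at30))
        assert abs(at30.mean() - expected) < 3 * se

    def test_library_normalized_totals_decrease_in_time(self):
        cfg = sd.DecaySimConfig(n_genes=100, seed=3)
        counts, samples, _ = sd.simulate_decay_counts(cfg)
        genes = counts.loc[~counts.index.str.startswith("ERCC-")]
        scaled = genes.sum(axis=0) / samples["lib_factor"]
        by_t = scaled.groupby(samples["timepoint_min"]).mean()
        assert (np.diff(by_t.to_numpy()) < 0).all()

    def test_empty_timepoints_rejected(self):
        with pytest.raises(ValueError):
            sd.DecaySimConfig(timepoints=())


class TestPolyAReads:
    def test_full_zero_inflation_gives_zero_runs(self):
        cfg = sd.PolyASimConfig(n_genes=3, zero_inflation=1.0, reads_per_gene=20, seed=0)
        reads, _, _ = sd.simulate_polya_reads(cfg)
        assert (reads["true_tail"] == 0).all()
        assert not reads["sequence"].str.startswith("T").any()

    def test_reads_confined_to_three_prime_window(self):
        cfg = sd.PolyASimConfig(n_genes=6, reads_per_gene=40, seed=1)
        reads, ann, _ = sd.simulate_polya_reads(cfg)
        ann = ann.set_index("gene_id")
        for r in reads.itertuples(index=False):
            g = ann.loc[r.gene_true]
            end3 = g.end if g.strand == "+" else g.start
            lo = end3 - 50 if g.strand == "+" else end3 - 250
            hi = end3 + 250 if g.strand == "+" else end3 + 50
            assert lo <= r.start + 1 and r.end <= hi

    def test_mean_run_length_matches_zinb_mean(self):
        pi, mu = 0.3, 6.0
        cfg = sd.PolyASimConfig(
            n_genes=1, condition_means=np.full((1, 4), mu), zero_inflation=pi,
            reads_per_gene=2500, seed=2,
        )
        reads, _, _ = sd.simulate_polya_reads(cfg)
        tails = reads["true_tail"].to_numpy(float)
        assert len(tails) == 10_000
        expected = (1 - pi) * mu
        se = tails.std() / np.sqrt(len(tails))
        assert abs(tails.mean() - expected) < 3 * se

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            sd.PolyASimConfig(zero_inflation=1.5)
        with pytest.raises(ValueError):
            sd.PolyASimConfig(overdispersion=0.0)
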