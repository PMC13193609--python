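"""Diffusion-state analysis: MSD fits, focus detection, CDF mixture fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from condensate_kit import synthetic_data as sd
from condensate_kit import trajectory_dynamics as td


def _brownian_track(rng, D, tau, n, sigma=0.0, start=(0.0, 0.0)):
    steps = rng.normal(0, np.sqrt(2 * D * tau), size=(n - 1, 2))
    pos = np.vstack([start, np.cumsum(steps, axis=0) + start])
    pos = pos + rng.normal(0, sigma, pos.shape)
    return pd.DataFrame({"track_id": 0, "frame": np.arange(n), "x_um": pos[:, 0], "y_um": pos[:, 1]})


class TestMsdFit:
    def test_short_track_rejected(self):
        rng = np.random.default_rng(0)
        track = _brownian_track(rng, 0.5, 0.02, 6)
        with pytest.raises(ValueError, match="at least 7"):
            td.fit_msd(track, 0.02)

    def test_mean_fitted_D_recovers_truth(self):
        rng = np.random.default_rng(1)
        Ds = [td.fit_msd(_brownian_track(rng, 0.5, 0.02, 30, sigma=0.03), 0.02).D for _ in range(100)]
        assert abs(np.mean(Ds) - 0.5) / 0.5 < 0.20

    def test_negative_slope_clamped_and_flagged(self):
        # pure localization noise around a fixed point: MSD flat, slope ~ 0 or negative
        rng = np.random.default_rng(5)
        for _ in range(20):
            track = _brownian_track(rng, 0.0, 0.02, 20, sigma=0.05)
            fit = td.fit_msd(track, 0.02)
            assert fit.D >= 0.0
            if fit.clamped:
                assert fit.D == 0.0
                break
        else:
            pytest.fail("no clamped fit observed in 20 stationary tracks")


class TestStableFocusDetection:
    @staticmethod
    def _clustered_tracks(n_tracks, n_frames, center_px=(30.0, 30.0), pixel_size=0.05, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for tid in range(n_tracks):
            x = (center_px[1] + rng.uniform(-2, 2, n_frames)) * pixel_size
            y = (center_px[0] + rng.uniform(-2, 2, n_frames)) * pixel_size
            rows.append(pd.DataFrame({"track_id": tid, "frame": np.arange(n_frames), "x_um": x, "y_um": y}))
        return pd.concat(rows, ignore_index=True)

    def test_twelve_clustered_tracks_give_one_region(self):
        tracks = self._clustered_tracks(12, 15)
        foci = td.detect_stable_foci(tracks, (64, 64), 0.05)
        assert len(foci.regions) == 1
        mask = foci.membership_mask()
        assert mask[30, 30]

    def test_five_tracks_fail_the_count_filter(self):
        tracks = self._clustered_tracks(5, 15)
        foci = td.detect_stable_foci(tracks, (64, 64), 0.05)
        assert len(foci.regions) == 0

    def test_empty_trajectory_set(self):
        empty = pd.DataFrame({"track_id": [], "frame": [], "x_um": [], "y_um": []})
        assert len(td.detect_stable_foci(empty, (64, 64), 0.05).regions) == 0


class TestOverlapClassification:
    @staticmethod
    def _region_set():
        pix = np.argwhere(np.ones((5, 5), bool)) + 10  # region covering [10,15) x [10,15)
        reg = td.FocusRegion((12.0, 12.0), 3.0, pix)
        return td.FocusRegionSet([reg], (64, 64), 0.05)

    def _track_at(self, cols_px, rows_px):
        n = len(cols_px)
        return pd.DataFrame({
            "track_id": 0, "frame": np.arange(n),
            "x_um": np.asarray(cols_px) * 0.05, "y_um": np.asarray(rows_px) * 0.05,
        })

    def test_fully_inside_is_in(self):
        oc = td.classify_trajectory(self._track_at([11, 12, 13], [11, 12, 13]), self._region_set())
        assert oc.label == "In" and oc.overlap_fraction == 1.0

    def test_half_inside_is_inout(self):
        oc = td.classify_trajectory(self._track_at([11, 12, 40, 41], [11, 12, 40, 41]), self._region_set())
        assert oc.label == "InOut" and oc.overlap_fraction == 0.5

    def test_none_inside_is_out(self):
        oc = td.classify_trajectory(self._track_at([40, 41], [40, 41]), self._region_set())
        assert oc.label == "Out" and oc.overlap_fraction == 0.0

    def test_no_regions_is_out(self):
        empty = td.FocusRegionSet([], (64, 64), 0.05)
        assert td.classify_trajectory(self._track_at([1], [1]), empty).label == "Out"

    def test_agrees_with_brute_force_membership(self, four_focus_tracks):
        cfg, tracks, _ = four_focus_tracks
        shape = (260, 260)
        foci = td.detect_stable_foci(tracks, shape, 0.05)
        mask = foci.membership_mask()
        classes = td.classify_all(tracks, foci)
        for tid, g in list(tracks.groupby("track_id"))[:200]:
            inside = 0
            for _, row in g.iterrows():
                r = min(int(row.y_um / 0.05), shape[0] - 1)
                c = min(int(row.x_um / 0.05), shape[1] - 1)
                inside += bool(mask[r, c])
            frac = inside / len(g)
            got = classes.set_index("track_id").loc[tid]
            assert got["overlap_fraction"] == pytest.approx(frac)


class TestDisplacementPool:
    def test_four_frame_track_gives_three_values(self):
        rng = np.random.default_rng(0)
        track = _brownian_track(rng, 0.5, 0.02, 4)
        assert len(td.pooled_squared_displacements(track)) == 3

    def test_short_tracks_excluded(self):
        rng = np.random.default_rng(0)
        track = _brownian_track(rng, 0.5, 0.02, 3)
        assert len(td.pooled_squared_displacements(track)) == 0

    def test_matches_brute_force_enumeration(self, four_focus_tracks):
        _, tracks, _ = four_focus_tracks
        pool = td.pooled_squared_displacements(tracks)
        brute = []
        for _, g in tracks.groupby("track_id"):
            g = g.sort_values("frame")
            if len(g) < 4:
                continue
            f = g["frame"].to_numpy()
            x = g["x_um"].to_numpy()
            y = g["y_um"].to_numpy()
            for i in range(len(f) - 1):
                if f[i + 1] - f[i] == 1:
                    brute.append((x[i + 1] - x[i]) ** 2 + (y[i + 1] - y[i]) ** 2)
        assert np.allclose(np.sort(pool), np.sort(brute))


class TestEmpiricalCdf:
    def test_single_value_step(self):
        cdf = td.empirical_cdf(np.array([2.0]))
        assert cdf(1.9) == 0.0 and cdf(2.0) == 1.0

    def test_value_one_at_maximum(self):
        pool = np.random.default_rng(0).exponential(1.0, 500)
        assert td.empirical_cdf(pool)(pool.max()) == 1.0

    def test_agrees_with_direct_counting(self):
        rng = np.random.default_rng(1)
        pool = rng.exponential(0.1, 400)
        cdf = td.empirical_cdf(pool)
        for q in rng.uniform(0, 0.5, 50):
            assert cdf(q) == pytest.approx(np.mean(pool <= q))

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            td.empirical_cdf(np.array([]))


def _quantile_pool(D, alphas, tau, n=4000, standard_factor=False):
    """Noise-free pool whose ECDF reproduces the mixture CDF (inverse-CDF grid)."""
    probs = (np.arange(n) + 0.5) / n
    out = np.empty(n)
    hi = 80 * max(D) * tau  # CDF within ~3e-13 of 1 at the bracket end
    for i, p in enumerate(probs):
        out[i] = optimize.brentq(
            lambda r2: td.model_cdf(np.array([r2]), D, alphas, tau, standard_factor)[0] - p,
            0.0, hi,
        )
    return out


class TestMixtureFits:
    TAU = 0.02

    def test_three_state_recovery_from_model_cdf(self):
        pool = _quantile_pool([0.05, 0.3, 2.0], [0.3, 0.3, 0.4], self.TAU)
        fit = td.fit_three_state(pool, self.TAU, seed=0)
        assert fit.D1 == pytest.approx(0.05, rel=0.05)
        assert fit.D2 == pytest.approx(0.3, rel=0.05)
        assert fit.D3 == pytest.approx(2.0, rel=0.05)
        assert fit.alpha1 == pytest.approx(0.3, abs=0.02)
        assert fit.alpha2 == pytest.approx(0.3, abs=0.02)

    def test_single_state_input_collapses_alphas(self):
        pool = _quantile_pool([2.0], [1.0], self.TAU)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = td.fit_three_state(pool, self.TAU, seed=1)
        # the true state may be split across near-identical components
        # (flagged degenerate); weight on any D off the truth must vanish
        weight_near_truth = sum(
            a for D, a in [(fit.D1, fit.alpha1), (fit.D2, fit.alpha2), (fit.D3, fit.alpha3)]
            if abs(D - 2.0) / 2.0 < 0.05
        )
        assert weight_near_truth >= 0.98

    def test_two_state_recovery_and_limit(self):
        pool = _quantile_pool([0.05, 0.3], [0.6, 0.4], self.TAU)
        fit = td.fit_two_state(pool, self.TAU, seed=0)
        assert fit.D1 == pytest.approx(0.05, rel=0.05)
        assert fit.D2 == pytest.approx(0.3, rel=0.05)
        assert fit.alpha == pytest.approx(0.6, abs=0.02)

        single = _quantile_pool([0.3], [1.0], self.TAU)
        lim = td.fit_two_state(single, self.TAU, seed=0)
        big = max(lim.alpha, 1 - lim.alpha)
        assert big >= 0.95 or lim.degenerate

    def test_two_state_data_yields_small_third_weight(self):
        rng = np.random.default_rng(3)
        comp = rng.choice(2, size=4000, p=[0.5, 0.5])
        D = np.array([0.05, 2.0])
        r2 = rng.exponential((8 / 3) * D[comp] * self.TAU)
        fit = td.fit_three_state(r2, self.TAU, seed=0)
        assert min(fit.alpha1, fit.alpha2, fit.alpha3) <= 0.05

    def test_standard_factor_flag_changes_scale(self):
        pool = _quantile_pool([1.0], [1.0], self.TAU, standard_factor=True)
        fit = td.fit_three_state(pool, self.TAU, standard_factor=True, seed=0)
        assert fit.D3 == pytest.approx(1.0, rel=0.1)


class TestStateFractions:
    def _fit(self, a1, a2, D=(0.05, 0.3, 2.0)):
        return td.ThreeStateFit(D[0], D[1], D[2], a1, a2, 0.0)

    def test_forced_arithmetic(self):
        fr = td.compute_state_fractions(self._fit(0.4, 0.3), self._fit(0.5, 0.3), 300, 300, 1000)
        # F_cond = 0.6 * 0.8 = 0.48; F_free = 1-0.4-0.3 = 0.30; F_nuc = 0.22
        assert fr.F_condensate == pytest.approx(0.48)
        assert fr.F_free == pytest.approx(0.30)
        assert fr.F_nucleoid == pytest.approx(0.22)
        assert sum(fr.as_tuple()) == pytest.approx(1.0, abs=1e-9)

    def test_no_focus_steps(self):
        fr = td.compute_state_fractions(self._fit(0.4, 0.3), self._fit(0.5, 0.5), 0, 0, 1000)
        assert fr.F_condensate == 0.0
        assert fr.F_nucleoid == pytest.approx(1 - 0.3)

    def test_all_in_limit(self):
        fr = td.compute_state_fractions(self._fit(0.5, 0.5), self._fit(0.5, 0.5), 1000, 0, 1000)
        assert fr.F_condensate == pytest.approx(1.0)
        assert fr.F_free == pytest.approx(0.0)
        assert fr.F_nucleoid == pytest.approx(0.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            td.compute_state_fractions(self._fit(0.3, 0.3), self._fit(0.5, 0.5), 0, 0, 0)
        with pytest.raises(ValueError):
            # F_free 0.9 + F_cond 1.0 > 1 -> inconsistent
            td.compute_state_fractions(self._fit(0.05, 0.05), self._fit(0.5, 0.5), 1000, 0, 1000)

    def test_slow_d3_warns(self):
        slow = td.ThreeStateFit(0.01, 0.05, 0.5, 0.3, 0.3, 0.0)
        with pytest.warns(UserWarning, match="D3"):
            td.compute_state_fractions(slow, self._fit(0.5, 0.3), 100, 100, 1000)
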