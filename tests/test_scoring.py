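import numpy as np
import pytest

from meshmx.detector import DetectorGeometry, make_shells, resolution_map
from meshmx.frames import Frame, FrameRecipe, render_frame
from meshmx.scoring import (
    diffraction_score,
    estimate_background,
    find_spots,
    fit_wilson,
    flag_sharp_rings,
    mean_spot_intensity,
    score_frame,
)
from meshmx.wilson import standard_wilson_curve


@pytest.fixture(scope="module")
def geom():
    return DetectorGeometry(60.0, 0.3, (63.5, 63.5), 1.0, 128, 128)


@pytest.fixture(scope="module")
def shells(geom):
    return make_shells(geom, 10, 3.0)


class TestBackground:
    def test_constant_frame_recovered_exactly(self, geom, shells):
        frame = Frame(np.full((128, 128), 7.0), geom)
        curve = estimate_background(frame, shells)
        assert np.allclose(curve.b_of_h[curve.usable], 7.0)
        assert not flag_sharp_rings(curve).flagged.any()

    def test_hot_pixels_rejected(self, geom, shells):
        data = np.full((128, 128), 10.0)
        rng = np.random.default_rng(1)
        ys, xs = rng.integers(5, 123, (2, 10))
        data[ys, xs] = 1000.0
        curve = estimate_background(Frame(data, geom), shells)
        assert np.allclose(curve.b_of_h[curve.usable], 10.0)
        # oracle: the median is immune to 10 isolated outliers
        assert np.allclose(curve.b_of_h[curve.usable], np.median(data))

    def test_poisson_background_within_standard_errors(self, geom, shells):
        rng = np.random.default_rng(2)
        frame = Frame(rng.poisson(20.0, (128, 128)).astype(float), geom)
        curve = estimate_background(frame, shells)
        hmap = resolution_map(geom)
        idx = shells.shell_index(hmap)
        for i in np.nonzero(curve.usable)[0]:
            n = (idx == i).sum()
            se = np.sqrt(20.0 / n)
            # sigma-clipping trims the upper tail, so allow a small offset
            assert curve.b_of_h[i] == pytest.approx(20.0, abs=3 * se + 0.3)


class TestRingFlagging:
    def test_smooth_curve_unflagged(self, geom, shells):
        frame = render_frame(FrameRecipe(background_level=40, seed=3), geom)
        curve = flag_sharp_rings(estimate_background(frame, shells))
        assert not curve.flagged.any()

    def test_ice_ring_shell_flagged_and_idempotent(self, geom, shells):
        frame = render_frame(
            FrameRecipe(background_level=40, ice_rings=(3.44,), ice_strength=120,
                        seed=3),
            geom,
        )
        curve = flag_sharp_rings(estimate_background(frame, shells))
        ring_shell = int(shells.shell_index(1.0 / 3.44))
        assert curve.flagged[ring_shell]
        again = flag_sharp_rings(curve)
        assert np.array_equal(again.flagged, curve.flagged)


class TestFindSpots:
    def test_pure_background_gives_empty_list(self, geom, shells):
        frame = render_frame(FrameRecipe(background_level=30, seed=4), geom)
        curve = flag_sharp_rings(estimate_background(frame, shells))
        assert find_spots(frame, curve) == []

    def test_single_spot_found_at_planted_position(self, geom, shells):
        data = np.full((128, 128), 10.0)
        x0, y0 = 90.3, 40.7
        gx, gy = np.meshgrid(np.arange(128), np.arange(128))
        data += 3000.0 * np.exp(-((gx - x0) ** 2 + (gy - y0) ** 2) / (2 * 1.5**2)) / (
            2 * np.pi * 1.5**2
        )
        frame = Frame(data, geom)
        curve = flag_sharp_rings(estimate_background(frame, shells))
        spots = find_spots(frame, curve)
        assert len(spots) == 1
        assert spots[0].centroid[0] == pytest.approx(x0, abs=1.0)
        assert spots[0].centroid[1] == pytest.approx(y0, abs=1.0)

    def test_elongated_streak_rejected(self, geom, shells):
        data = np.full((128, 128), 10.0)
        data[60:62, 50:70] = 500.0  # 2 x 20 px streak
        frame = Frame(data, geom)
        curve = flag_sharp_rings(estimate_background(frame, shells))
        assert find_spots(frame, curve) == []


class TestMeanSpotIntensity:
    def test_agrees_with_brute_force_resummation(self, geom, shells):
        frame = render_frame(
            FrameRecipe(background_level=15, n_spots=60, spot_scale=4e4,
                        spot_sigma_px=1.0, seed=5),
            geom,
        )
        curve = flag_sharp_rings(estimate_background(frame, shells))
        spots = find_spots(frame, curve)
        assert spots
        ibar, _ = mean_spot_intensity(frame, spots, curve, dilate_px=2)

        # oracle: naive dilation by rolled unions, then plain per-shell loops
        mask = np.zeros(frame.data.shape, bool)
        for s in spots:
            mask[s.pixels[:, 0], s.pixels[:, 1]] = True
        pad = np.pad(mask, 2)
        for _ in range(2):
            grown = pad.copy()
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    grown |= np.roll(np.roll(pad, dy, 0), dx, 1)
            pad = grown
        mask = pad[2:-2, 2:-2]
        hmap = resolution_map(geom)
        idx = shells.shell_index(hmap)
        for i in range(shells.n_shells):
            if not curve.usable[i] or curve.flagged[i]:
                continue
            shell_px = idx == i
            spot_px = shell_px & mask
            if not spot_px.any():
                assert np.isnan(ibar[i])
                continue
            expect = (frame.data[spot_px] - curve.b_of_h[i]).sum() / shell_px.sum()
            assert ibar[i] == pytest.approx(expect, rel=1e-9)


class TestWilsonFit:
    def test_exact_model_recovered(self):
        h = np.linspace(0.08, 0.4, 12)
        ibar = 5.0 * standard_wilson_curve(h) * np.exp(-2 * 30.0 * (h / 2) ** 2)
        fit = fit_wilson(ibar, h)
        assert fit.scale_k == pytest.approx(5.0, rel=1e-6)
        assert fit.b_iso == pytest.approx(30.0, rel=1e-6)
        assert fit.cc_powder == pytest.approx(1.0, abs=1e-9)

    def test_uniform_noise_gives_low_correlation(self):
        h = np.linspace(0.08, 0.4, 12)
        ccs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            fit = fit_wilson(rng.uniform(0.5, 1.5, 12), h)
            ccs.append(abs(fit.cc_powder))
        assert np.median(ccs) < 0.5

    def test_intensity_scaling_invariance(self):
        h = np.linspace(0.08, 0.4, 12)
        rng = np.random.default_rng(3)
        ibar = standard_wilson_curve(h) * np.exp(-2 * 20.0 * (h / 2) ** 2)
        ibar = ibar * rng.lognormal(0, 0.2, 12)
        f1 = fit_wilson(ibar, h)
        f2 = fit_wilson(10.0 * ibar, h)
        assert f2.b_iso == pytest.approx(f1.b_iso, rel=1e-9)
        assert f2.cc_powder == pytest.approx(f1.cc_powder, abs=1e-12)
        assert f2.scale_k == pytest.approx(10.0 * f1.scale_k, rel=1e-9)

    def test_too_few_shells_gives_no_fit(self):
        assert fit_wilson(np.array([1.0, 2.0, np.nan]), np.array([0.1, 0.2, 0.3])) is None


class TestScore:
    def test_no_spots_scores_zero(self, geom, shells):
        frame = render_frame(FrameRecipe(background_level=30, seed=6), geom)
        result = score_frame(frame, shells)
        assert result.score == 0.0
        assert result.spots == []

    def test_score_linear_in_mean_intensity(self, geom, shells, dense_params):
        frame = render_frame(
            FrameRecipe(background_level=20, n_spots=250, spot_scale=6e4,
                        spot_sigma_px=1.0, wilson_B=25, seed=7),
            geom,
        )
        curve = flag_sharp_rings(estimate_background(frame, shells, dense_params))
        spots = find_spots(frame, curve, dense_params)
        ibar, h_of = mean_spot_intensity(frame, spots, curve)
        fit = fit_wilson(ibar, h_of)
        s1 = diffraction_score(ibar, curve, fit, has_spots=True)
        fit2 = fit_wilson(2.0 * ibar, h_of)  # doubling leaves cc and B unchanged
        s2 = diffraction_score(2.0 * ibar, curve, fit2, has_spots=True)
        assert s1 > 0
        assert s2 == pytest.approx(2.0 * s1, rel=1e-9)

    def test_protein_outranks_salt_at_equal_flux(self, geom, shells, dense_params):
        protein = render_frame(
            FrameRecipe(background_level=20, n_spots=300, spot_scale=5e4,
                        spot_sigma_px=1.0, wilson_B=25, seed=8),
            geom,
        )
        salt = render_frame(
            FrameRecipe(background_level=20, n_spots=0, salt_spots=12,
                        spot_scale=5e4, salt_scale=1.5e5, seed=8),
            geom,
        )
        # the salt frame carries at least as much above-background flux
        bg = 20.0 * 128 * 128
        assert salt.data.sum() - bg >= 0.9 * (protein.data.sum() - bg)
        sp = score_frame(protein, shells, dense_params)
        ss = score_frame(salt, shells, dense_params)
        assert sp.score > ss.score
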