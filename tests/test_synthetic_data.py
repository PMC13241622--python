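from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from nanocluster.errors import PlacementError, ValidationError
from nanocluster.io_formats import LocalizationTable
from nanocluster.synthetic_data import (
    EmissionConfig,
    SceneConfig,
    calibrate_n_clusters_for_nnd,
    make_two_group_dataset,
    render,
    render_density,
    sample_count_law,
    scale_count_law,
    simulate_localizations,
    simulate_scene,
)

TINY_SCENE = SceneConfig(
    frame_size_nm=(1500.0, 1500.0), n_clusters=8, cluster_size_law=("geometric", 8.0),
    nucleus_radius_frac=0.1, seed=42,
)


class TestLaws:
    def test_constant(self, rng):
        np.testing.assert_array_equal(sample_count_law(("constant", 3), 5, rng), [3] * 5)

    @pytest.mark.parametrize("law", [("geometric", 15.0), ("poisson", 15.0)])
    def test_mean_within_2_se(self, law, rng):
        draws = sample_count_law(law, 10_000, rng)
        assert draws.min() >= 1
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - 15.0) <= 2 * se

    def test_scale(self):
        assert scale_count_law(("geometric", 10.0), 0.79) == ("geometric", 7.9)
        assert scale_count_law(("geometric", 1.0), 0.5) == ("geometric", 1.0)

    def test_invalid(self, rng):
        with pytest.raises(ValidationError):
            sample_count_law(("geometric", 0.5), 1, rng)
        with pytest.raises(ValidationError):
            sample_count_law(("weird", 1), 1, rng)


class TestSimulateScene:
    def test_empty_scene(self):
        scene = simulate_scene(SceneConfig(n_clusters=0, seed=1))
        assert scene.n_clusters == 0

    def test_single_channel_clusters_have_footprint_area(self):
        cfg = SceneConfig(
            frame_size_nm=(2000.0, 2000.0), n_clusters=10,
            cluster_size_law=("constant", 1), seed=2, nucleus_radius_frac=0.0,
        )
        scene = simulate_scene(cfg)
        np.testing.assert_allclose(scene.true_areas_nm2(), 900.0)

    def test_size_law_mean_recovered(self):
        # ~1000 clusters across scenes: empirical mean within 2 SE of the law
        counts = []
        for s in range(30):
            scene = simulate_scene(
                SceneConfig(frame_size_nm=(4000.0, 4000.0), n_clusters=36,
                            cluster_size_law=("geometric", 15.0), seed=s)
            )
            counts.append(scene.channel_counts())
        counts = np.concatenate(counts)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 15.0) <= 2 * se

    def test_determinism(self):
        a = simulate_scene(TINY_SCENE)
        b = simulate_scene(TINY_SCENE)
        assert a.n_clusters == b.n_clusters
        for ca, cb in zip(a.clusters, b.clusters):
            np.testing.assert_array_equal(ca.channel_xy_nm, cb.channel_xy_nm)

    def test_seed_changes_scene(self):
        from dataclasses import replace

        a = simulate_scene(replace(TINY_SCENE, seed=1))
        b = simulate_scene(replace(TINY_SCENE, seed=2))
        assert not np.array_equal(a.clusters[0].channel_xy_nm, b.clusters[0].channel_xy_nm)

    def test_clusters_inside_frame_and_outside_nucleus(self):
        scene = simulate_scene(TINY_SCENE)
        fw, fh = TINY_SCENE.frame_size_nm
        for c in scene.clusters:
            assert (c.channel_xy_nm[:, 0] >= 0).all() and (c.channel_xy_nm[:, 0] <= fw).all()
            assert (c.channel_xy_nm[:, 1] >= 0).all() and (c.channel_xy_nm[:, 1] <= fh).all()
            d = np.hypot(
                c.channel_xy_nm[:, 0] - scene.nucleus_center_nm[0],
                c.channel_xy_nm[:, 1] - scene.nucleus_center_nm[1],
            )
            assert (d >= scene.nucleus_radius_nm).all()

    def test_min_edge_gap_respected(self):
        cfg = SceneConfig(frame_size_nm=(3000.0, 3000.0), n_clusters=20,
                          min_edge_gap_law=("constant", 60.0), seed=5)
        scene = simulate_scene(cfg)
        nnd = scene.true_nnd_nm()
        # the circumradius-based placement bound is conservative, so the
        # realized channel-based edge distances are at least the gap
        assert np.nanmin(nnd) >= 60.0

    def test_placement_failure(self):
        cfg = SceneConfig(frame_size_nm=(1200.0, 1200.0), n_clusters=200,
                          cluster_size_law=("constant", 20), max_placement_tries=50)
        with pytest.raises(PlacementError):
            simulate_scene(cfg)

    def test_roi_mask_geometry(self):
        scene = simulate_scene(TINY_SCENE)
        roi = scene.make_roi(5.0)
        assert roi.include.shape == (300, 300)
        assert roi.exclude.sum() > 0  # nucleus disc present
        expected_px = np.pi * scene.nucleus_radius_nm**2 / 25.0
        assert roi.exclude.sum() == pytest.approx(expected_px, rel=0.05)


class TestSimulateLocalizations:
    def test_empty_when_nothing_emits(self):
        scene = simulate_scene(TINY_SCENE)
        em = EmissionConfig(labeling_efficiency=0.0, background_rate_per_um2=0.0, seed=1)
        assert len(simulate_localizations(scene, em)) == 0

    def test_zero_precision_single_blink(self):
        cfg = SceneConfig(frame_size_nm=(500.0, 500.0), n_clusters=1,
                          cluster_size_law=("constant", 1), seed=3,
                          nucleus_radius_frac=0.0, lattice_jitter_frac=0.0)
        scene = simulate_scene(cfg)
        em = EmissionConfig(
            labeling_efficiency=1.0, blinks_per_fluorophore_law=("constant", 1),
            localization_precision_nm=0.0, background_rate_per_um2=0.0, seed=4,
        )
        locs = simulate_localizations(scene, em)
        assert len(locs) == 1
        np.testing.assert_allclose(
            locs.data[["x_nm", "y_nm"]].to_numpy()[0], scene.clusters[0].channel_xy_nm[0]
        )

    def test_expected_blink_count(self):
        # 1000 channels, mean 5 blinks -> rows within 2 SE of 5000
        cfg = SceneConfig(frame_size_nm=(20_000.0, 20_000.0), n_clusters=100,
                          cluster_size_law=("constant", 10), seed=6, nucleus_radius_frac=0.0)
        scene = simulate_scene(cfg)
        assert scene.channel_counts().sum() == 1000
        em = EmissionConfig(blinks_per_fluorophore_law=("geometric", 5.0),
                            background_rate_per_um2=0.0, seed=7)
        locs = simulate_localizations(scene, em)
        # var of geometric(mean 5) is (1-p)/p^2 = 20 per channel
        se = np.sqrt(1000 * 20.0)
        assert abs(len(locs) - 5000) <= 2 * se

    def test_determinism(self):
        scene = simulate_scene(TINY_SCENE)
        em = EmissionConfig(seed=9)
        a = simulate_localizations(scene, em)
        b = simulate_localizations(scene, em)
        np.testing.assert_array_equal(a.data.to_numpy(), b.data.to_numpy())

    def test_emission_validation(self):
        with pytest.raises(ValidationError):
            EmissionConfig(labeling_efficiency=1.5)
        with pytest.raises(ValidationError):
            EmissionConfig(localization_precision_nm=-1)


class TestRender:
    def test_single_event_nearest_pixel(self):
        locs = LocalizationTable.from_arrays([12.0], [22.0], weight=3.0)
        img = render(locs, 5.0, (100.0, 100.0), sigma_render_nm=0.0, gain=1.0)
        assert img.total_intensity() == 3
        assert img.pixels[4, 2] == 3  # row = y // 5, col = x // 5

    def test_conservation_binning(self, rng):
        n = 500
        locs = LocalizationTable.from_arrays(
            rng.uniform(50, 450, n), rng.uniform(50, 450, n)
        )
        img = render(locs, 5.0, (500.0, 500.0), sigma_render_nm=0.0, gain=1.0)
        assert img.total_intensity() == n

    def test_conservation_gaussian_prequantization(self, rng):
        n = 200
        locs = LocalizationTable.from_arrays(
            rng.uniform(100, 400, n), rng.uniform(100, 400, n)
        )
        dens = render_density(locs, 5.0, (500.0, 500.0), sigma_render_nm=8.0)
        assert dens.sum() == pytest.approx(n, rel=1e-6)

    def test_corner_event_four_fold_symmetry(self):
        # event exactly on the corner shared by pixels (9,9),(9,10),(10,9),(10,10)
        locs = LocalizationTable.from_arrays([50.0], [50.0])
        dens = render_density(locs, 5.0, (200.0, 200.0), sigma_render_nm=6.0)
        quad = dens[9:11, 9:11]
        assert quad[0, 0] == pytest.approx(quad[0, 1], rel=1e-9)
        assert quad[0, 0] == pytest.approx(quad[1, 0], rel=1e-9)
        assert quad[0, 0] == pytest.approx(quad[1, 1], rel=1e-9)
        # analytic kernel integral over one pixel: (Phi(0) - Phi(-1/s))^2 ... s in px
        s = 6.0 / 5.0
        phi = stats.norm.cdf
        expected = (phi(0) - phi(-1 / s)) ** 2
        assert quad[1, 1] == pytest.approx(expected, rel=1e-9)

    def test_gain_and_clipping(self):
        locs = LocalizationTable.from_arrays([12.0], [12.0], weight=1000.0)
        img = render(locs, 5.0, (100.0, 100.0), sigma_render_nm=0.0, gain=100.0)
        assert img.pixels.max() == 65535  # clipped, not wrapped

    def test_invalid_pixel_size(self):
        locs = LocalizationTable.from_arrays([1.0], [1.0])
        with pytest.raises(ValidationError):
            render(locs, 0.0, (10.0, 10.0))


class TestTwoGroupDataset:
    def test_one_cell_per_group(self):
        ds = make_two_group_dataset(
            TINY_SCENE, EmissionConfig(), n_animals_per_group=1, cells_per_animal=1,
            seed=1, render_images=True,
        )
        assert len(ds.cells) == 2
        assert {c.group for c in ds.cells} == {"control", "disease"}
        assert all(c.image is not None and c.roi is not None for c in ds.cells)

    def test_determinism(self):
        a = make_two_group_dataset(TINY_SCENE, None, 2, 2, seed=5)
        b = make_two_group_dataset(TINY_SCENE, None, 2, 2, seed=5)
        for ca, cb in zip(a.cells, b.cells):
            assert ca.cell_id == cb.cell_id
            np.testing.assert_array_equal(
                np.vstack([t.channel_xy_nm for t in ca.scene.clusters]),
                np.vstack([t.channel_xy_nm for t in cb.scene.clusters]),
            )

    def test_group_effect_on_true_areas(self):
        ds = make_two_group_dataset(
            SceneConfig(frame_size_nm=(4000.0, 4000.0), n_clusters=36,
                        cluster_size_law=("geometric", 14.9)),
            None, n_animals_per_group=3, cells_per_animal=10, group_effect=0.79, seed=2,
        )
        means = {"control": [], "disease": []}
        for cell in ds.cells:
            means[cell.group].append(cell.scene.true_areas_nm2().mean())
        ratio = np.mean(means["disease"]) / np.mean(means["control"])
        assert ratio == pytest.approx(0.79, abs=0.05)

    def test_null_exchangeability(self):
        # group_effect = 1, no animal effect: per-cell true mean areas are
        # exchangeable, so a two-sample t-test is non-significant >= 94/100 times
        hits = 0
        for rep in range(100):
            ds = make_two_group_dataset(
                TINY_SCENE, None, n_animals_per_group=2, cells_per_animal=5,
                group_effect=1.0, animal_rel_sd=0.0, seed=1000 + rep,
            )
            vals = {"control": [], "disease": []}
            for cell in ds.cells:
                vals[cell.group].append(cell.scene.true_areas_nm2().mean())
            p = stats.ttest_ind(vals["control"], vals["disease"]).pvalue
            hits += p > 0.05
        assert hits >= 94

    def test_animal_effect_changes_between_animal_spread(self):
        ds = make_two_group_dataset(
            TINY_SCENE, None, n_animals_per_group=4, cells_per_animal=8,
            group_effect=1.0, animal_rel_sd=0.4, seed=8,
        )
        import pandas as pd

        rows = [
            {"animal": c.animal_id, "m": c.scene.channel_counts().mean()} for c in ds.cells
        ]
        df = pd.DataFrame(rows)
        between = df.groupby("animal")["m"].mean().std()
        assert between > 0.5  # animal-level effect visible

    def test_validation(self):
        with pytest.raises(ValidationError):
            make_two_group_dataset(TINY_SCENE, None, 0, 1)
        with pytest.raises(ValidationError):
            make_two_group_dataset(TINY_SCENE, None, 1, 1, animal_rel_sd=-0.1)


class TestCalibration:
    def test_calibrates_toward_target(self):
        cfg = SceneConfig(frame_size_nm=(3000.0, 3000.0), cluster_size_law=("geometric", 14.9))
        cal = calibrate_n_clusters_for_nnd(
            cfg, 119.0, n_scenes=2, n_refine_scenes=6, tol_nm=6.0, seed=1
        )
        assert cal.achieved_mean_nnd_nm == pytest.approx(119.0, abs=10.0)
        from dataclasses import replace

        vals = []
        for s in range(6):
            scene = simulate_scene(replace(cfg, n_clusters=cal.n_clusters, seed=500 + s))
            vals.append(scene.true_nnd_nm())
        mean = np.nanmean(np.concatenate(vals))
        assert mean == pytest.approx(119.0, abs=20.0)
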