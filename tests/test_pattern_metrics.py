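"""RNL clustering, patch sizes, edge contrast and the pipeline driver."""

import numpy as np
import pytest

import camoquant as cq
from conftest import constant_catches


def halfplane_catches(obs, jnd_step, shape=(20, 20), base=0.3, px_per_cm=45.0):
    lum = np.full(shape, base)
    lum[:, shape[1] // 2:] = base * np.exp(jnd_step * obs.luminance_weber)
    q = np.repeat(lum[..., None], 3, axis=-1)
    return cq.ConeCatchImage(q, obs.channel_names, px_per_cm=px_per_cm)


class TestClustering:
    def test_uniform_roi_is_one_cluster(self, obs):
        catches = constant_catches(0.5)
        roi = np.ones(catches.shape, bool)
        cmap = cq.rnl_cluster(catches, roi, obs)
        assert cmap.n_clusters == 1
        assert cmap.n_patches == 1
        assert set(np.unique(cmap.labels)) == {1}

    @pytest.mark.parametrize("jnd_step, expected_clusters", [
        (5.0, 2),    # supra-threshold pair never merges
        (0.5, 1),    # sub-threshold pair merges
    ])
    def test_halfplane_merging_follows_threshold(self, obs, jnd_step, expected_clusters):
        catches = halfplane_catches(obs, jnd_step)
        roi = np.ones(catches.shape, bool)
        cmap = cq.rnl_cluster(catches, roi, obs, jnd_threshold=1.0)
        assert cmap.n_clusters == expected_clusters

    def test_adjacent_clusters_separated_by_threshold(self, obs):
        rng = np.random.default_rng(13)
        lum = 0.4 * np.exp(0.08 * rng.standard_normal((16, 16)))
        q = np.repeat(lum[..., None], 3, axis=-1)
        catches = cq.ConeCatchImage(q, obs.channel_names, px_per_cm=45.0)
        roi = np.ones((16, 16), bool)
        cmap = cq.rnl_cluster(catches, roi, obs, jnd_threshold=1.0)
        means = cmap.mean_catches
        from camoquant.pattern_metrics import _adjacent_label_pairs
        for a, b in _adjacent_label_pairs(cmap.labels, 4):
            d = cq.rnl_combined_distance(means[int(a)], means[int(b)], obs)
            assert d >= 1.0

    def test_cluster_count_non_increasing_in_threshold(self, obs):
        rng = np.random.default_rng(14)
        lum = 0.4 * np.exp(0.05 * rng.standard_normal((20, 20)))
        q = np.repeat(lum[..., None], 3, axis=-1)
        catches = cq.ConeCatchImage(q, obs.channel_names, px_per_cm=45.0)
        roi = np.ones((20, 20), bool)
        counts = [
            cq.rnl_cluster(catches, roi, obs, jnd_threshold=t).n_clusters
            for t in (0.5, 1.0, 2.0, 4.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_empty_roi_rejected(self, obs):
        with pytest.raises(ValueError, match="empty"):
            cq.rnl_cluster(constant_catches(0.5), np.zeros((20, 20), bool), obs)


class TestPatchSize:
    def test_single_cluster_patch_equals_roi(self, obs):
        catches = constant_catches(0.5, shape=(25, 40))
        roi = np.ones((25, 40), bool)
        cmap = cq.rnl_cluster(catches, roi, obs)
        px2, cm2 = cq.average_patch_size(cmap)
        assert px2 == 1000.0
        assert cm2 == pytest.approx(1000.0 / 45.0 ** 2)

    def test_checkerboard_of_four_patches(self, obs):
        lum = np.full((20, 20), 0.1)
        lum[:10, 10:] = 0.9
        lum[10:, :10] = 0.9
        q = np.repeat(lum[..., None], 3, axis=-1)
        catches = cq.ConeCatchImage(q, obs.channel_names, px_per_cm=45.0)
        roi = np.ones((20, 20), bool)
        cmap = cq.rnl_cluster(catches, roi, obs)
        # merging is between adjacent clusters only, so the four equal-tone
        # islands stay distinct: four patches under 4-connectivity
        assert cmap.n_patches == 4
        assert cq.average_patch_size(cmap)[0] == pytest.approx(400 / 4)

    def test_mean_patch_size_identity(self, obs):
        rng = np.random.default_rng(15)
        lum = 0.4 * np.exp(0.07 * rng.standard_normal((18, 18)))
        q = np.repeat(lum[..., None], 3, axis=-1)
        catches = cq.ConeCatchImage(q, obs.channel_names, px_per_cm=45.0)
        roi = np.ones((18, 18), bool)
        cmap = cq.rnl_cluster(catches, roi, obs)
        px2, _ = cq.average_patch_size(cmap)
        assert px2 == pytest.approx(cmap.roi_area_px2 / cmap.n_patches)

    def test_area_weighted_toggle_is_at_least_simple_mean(self, obs):
        lum = np.full((20, 20), 0.1)
        lum[:5, :5] = 0.9
        q = np.repeat(lum[..., None], 3, axis=-1)
        catches = cq.ConeCatchImage(q, obs.channel_names, px_per_cm=45.0)
        cmap = cq.rnl_cluster(catches, np.ones((20, 20), bool), obs)
        simple, _ = cq.average_patch_size(cmap)
        weighted, _ = cq.average_patch_size(cmap, area_weighted=True)
        assert weighted >= simple


class TestLEIA:
    def test_uniform_roi_has_zero_contrast(self, obs):
        catches = constant_catches(0.5)
        assert cq.leia_mean_luminance_contrast(
            catches, np.ones(catches.shape, bool), obs
        ) == 0.0

    def test_halfplane_mean_is_border_fraction_times_step(self, obs):
        h, w, step = 10, 20, 3.0
        catches = halfplane_catches(obs, step, shape=(h, w))
        roi = np.ones((h, w), bool)
        # horizontal pairs: h*(w-1), vertical: (h-1)*w; crossing pairs: h
        n_pairs = h * (w - 1) + (h - 1) * w
        expected = step * h / n_pairs
        got = cq.leia_mean_luminance_contrast(catches, roi, obs)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_invariant_under_global_luminance_scaling(self, obs):
        rng = np.random.default_rng(16)
        lum = 0.3 * np.exp(0.1 * rng.standard_normal((15, 15)))
        roi = np.ones((15, 15), bool)
        def metric(scale):
            q = np.repeat((scale * lum)[..., None], 3, axis=-1)
            c = cq.ConeCatchImage(q, obs.channel_names, px_per_cm=45.0)
            return cq.leia_mean_luminance_contrast(c, roi, obs)
        assert metric(1.0) == pytest.approx(metric(2.5), rel=1e-12)

    def test_invariant_under_90_degree_rotation(self, obs):
        rng = np.random.default_rng(17)
        lum = 0.3 * np.exp(0.1 * rng.standard_normal((12, 18)))
        roi = np.ones((12, 18), bool)
        q = np.repeat(lum[..., None], 3, axis=-1)
        c = cq.ConeCatchImage(q, obs.channel_names, px_per_cm=45.0)
        qr = np.repeat(np.rot90(lum)[..., None], 3, axis=-1)
        cr = cq.ConeCatchImage(qr, obs.channel_names, px_per_cm=45.0)
        a = cq.leia_mean_luminance_contrast(c, roi, obs)
        b = cq.leia_mean_luminance_contrast(cr, np.rot90(roi), obs)
        assert a == pytest.approx(b, rel=1e-12)

    def test_increases_with_pattern_amplitude(self, obs, small_cfg):
        mask = cq.elliptical_body_mask(small_cfg, area_cm2=4.0)
        values = {amp: [] for amp in (0.05, 0.10)}
        for seed in range(5):
            for amp in values:
                fish = cq.generate_fish_texture(
                    cq.FishTextureSpec(mask, marking_scale_px=10,
                                       pattern_amplitude=amp, seed=seed),
                    small_cfg,
                )
                q = np.repeat(np.clip(fish.pixels, 1e-3, 1)[..., None], 3, axis=-1)
                c = cq.ConeCatchImage(q, obs.channel_names, px_per_cm=45.0)
                values[amp].append(cq.leia_mean_luminance_contrast(c, mask, obs))
        assert all(hi > lo for lo, hi in zip(values[0.05], values[0.10]))

    def test_tiny_roi_rejected(self, obs):
        roi = np.zeros((20, 20), bool)
        roi[0, 0] = True
        with pytest.raises(ValueError):
            cq.leia_mean_luminance_contrast(constant_catches(0.5), roi, obs)


class TestMeasureSpecimen:
    def _scene(self, cfg, amplitude, seed=0):
        bg = cq.ReflectanceImage(
            np.full(cfg.canvas_size_px, 0.5), px_per_cm=cfg.px_per_cm
        )
        mask = cq.elliptical_body_mask(cfg, area_cm2=4.0)
        fish = cq.generate_fish_texture(
            cq.FishTextureSpec(mask, marking_scale_px=10,
                               pattern_amplitude=amplitude, seed=seed), cfg,
        )
        return cq.compose_scene(bg, fish, cfg)

    def test_flat_specimen_has_no_pattern(self, obs, small_cfg):
        scene = self._scene(small_cfg, amplitude=0.0)
        row = cq.measure_specimen(scene, obs, bands=cq.BandSet(2, 30, 2))
        assert row.leia_luminance_jnd == pytest.approx(0.0, abs=1e-9)
        # body and uniform background are indistinguishable: a single patch
        assert row.average_patch_size_px2 == scene.roi("body").sum()

    def test_rows_are_bit_reproducible(self, obs, small_cfg):
        scene = self._scene(small_cfg, amplitude=0.12, seed=5)
        a = cq.measure_specimen(scene, obs, bands=cq.BandSet(2, 30, 2))
        b = cq.measure_specimen(scene, obs, bands=cq.BandSet(2, 30, 2))
        assert a.to_row() == b.to_row()

    def test_body_area_follows_pixel_count(self, obs, small_cfg):
        scene = self._scene(small_cfg, amplitude=0.1)
        row = cq.measure_specimen(scene, obs, metrics=("leia",))
        assert row.body_area_cm2 == pytest.approx(
            scene.roi("body").sum() / small_cfg.px_per_cm ** 2
        )
        assert row.average_patch_size_px2 is None  # unselected metric

    def test_stage_errors_carry_stage_name(self, obs, small_cfg):
        scene = self._scene(small_cfg, amplitude=0.1)
        del scene.rois["std12"]
        with pytest.raises(RuntimeError, match="preprocess"):
            cq.measure_specimen(scene, obs, metrics=("leia",))

    def test_grey_scene_has_no_chromatic_contrast(self, obs, small_cfg):
        # flat-spectrum scenes carry essentially no chromatic signal, which
        # licenses the luminance-only analysis
        scene = self._scene(small_cfg, amplitude=0.15, seed=2)
        from camoquant.pattern_metrics import preprocess_scene
        filtered = preprocess_scene(scene, obs)
        body = np.argwhere(scene.roi("body"))
        rng = np.random.default_rng(0)
        pick = body[rng.choice(len(body), size=50, replace=False)]
        q = filtered.catches[pick[:, 0], pick[:, 1]]
        d = cq.rnl_chromatic_distance(q[:25], q[25:], obs.weber_fractions)
        assert np.max(d) < 0.05
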