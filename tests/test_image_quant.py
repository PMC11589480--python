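"""Projection, background, segmentation, quantification and fold change."""

import numpy as np
import pandas as pd
import pytest

from napdyn import image_quant, synthetic


def match_truth(table: pd.DataFrame, truth: pd.DataFrame, channel: str) -> pd.DataFrame:
    """Pair quantified nuclei with ground truth by nearest centroid."""
    sub = table[table.channel == channel].reset_index(drop=True)
    tt = truth[truth.channel == channel].reset_index(drop=True)
    d = np.hypot(sub.centroid_row.to_numpy()[:, None] - tt.centroid_row.to_numpy(),
                 sub.centroid_col.to_numpy()[:, None] - tt.centroid_col.to_numpy())
    nearest = d.argmin(axis=1)
    assert len(set(nearest)) == len(sub), "ambiguous nucleus matching"
    return sub.assign(true_intensity=tt.true_intensity.to_numpy()[nearest],
                      rendered_intensity=tt.rendered_intensity.to_numpy()[nearest])


class TestMaxProject:
    def test_single_plane_identity(self):
        img = np.random.default_rng(0).random((1, 16, 16))
        np.testing.assert_array_equal(image_quant.max_project(img), img[0])

    def test_single_bright_pixel_survives(self):
        stack = np.zeros((5, 8, 8))
        stack[3, 2, 6] = 5.0
        assert image_quant.max_project(stack)[2, 6] == 5.0

    def test_projection_dominates_every_plane_and_is_idempotent(self):
        stack = np.random.default_rng(1).random((6, 20, 20))
        proj = image_quant.max_project(stack)
        assert (proj[None] >= stack).all()
        np.testing.assert_array_equal(image_quant.max_project(proj), proj)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            image_quant.max_project(np.empty((0, 8, 8)))


class TestBackground:
    def test_uniform_image(self):
        assert image_quant.estimate_background(np.full((10, 10), 7.0)) == 7.0

    def test_recovers_scene_background(self, small_scene):
        stacks, _ = synthetic.make_image_stack(small_scene, synthetic.NoiseModel(),
                                               n_z=1, seed=0)
        proj = image_quant.max_project(next(iter(stacks.values())))
        labels = image_quant.segment_nuclei(np.log1p(proj))
        bg = image_quant.estimate_background(proj, mask=labels > 0)
        assert bg == pytest.approx(small_scene.background_level, rel=1e-6)

    def test_all_masked_is_error(self):
        with pytest.raises(ValueError):
            image_quant.estimate_background(np.ones((4, 4)), mask=np.ones((4, 4), bool))


class TestSegmentation:
    def test_blank_image_gives_zero_labels(self):
        labels = image_quant.segment_nuclei(np.zeros((32, 32)))
        assert labels.max() == 0

    def test_noiseless_scene_gives_exact_count(self, small_scene):
        stacks, _ = synthetic.make_image_stack(small_scene, synthetic.NoiseModel(),
                                               n_z=3, seed=0)
        comp = sum(image_quant.max_project(s) for s in stacks.values())
        labels = image_quant.segment_nuclei(np.log1p(comp))
        assert labels.max() == small_scene.n_nuclei

    def test_watershed_splits_touching_blobs(self):
        img = np.zeros((60, 60))
        rr, cc = np.mgrid[:60, :60]
        for c in ((30, 22), (30, 38)):
            img += 100 * np.exp(-((rr - c[0]) ** 2 + (cc - c[1]) ** 2) / (2 * 5.0**2))
        merged = image_quant.segment_nuclei(img, split_touching=False)
        split = image_quant.segment_nuclei(img, split_touching=True)
        assert merged.max() == 1
        assert split.max() == 2

    def test_bad_area_bounds(self):
        with pytest.raises(ValueError):
            image_quant.segment_nuclei(np.zeros((8, 8)), min_area=50, max_area=10)


class TestQuantification:
    def test_noiseless_recovery_is_near_exact(self, small_scene):
        stacks, truth = synthetic.make_image_stack(small_scene, synthetic.NoiseModel(),
                                                   n_z=4, seed=0)
        table, labels = image_quant.quantify_image(stacks)
        assert labels.max() == small_scene.n_nuclei
        for ch in small_scene.channel_names:
            matched = match_truth(table, truth, ch)
            err = (matched.intensity - matched.true_intensity).abs() / matched.true_intensity
            assert err.max() < 0.05

    def test_intensity_linearity(self, small_scene):
        """Scaling the image by c scales every integrated intensity by c."""
        stacks, _ = synthetic.make_image_stack(small_scene, synthetic.NoiseModel(),
                                               n_z=2, seed=0)
        ch = small_scene.channel_names[0]
        proj = {ch: image_quant.max_project(stacks[ch])}
        labels = image_quant.segment_nuclei(np.log1p(proj[ch]), )
        bg = {ch: small_scene.background_level}
        base = image_quant.quantify_nuclei(proj, labels, bg)
        scaled = image_quant.quantify_nuclei({ch: 3.0 * proj[ch]}, labels,
                                             {ch: 3.0 * bg[ch]})
        np.testing.assert_allclose(scaled.intensity, 3.0 * base.intensity, rtol=1e-12)

    def test_background_only_nucleus_is_censored(self):
        labels = np.zeros((20, 20), int)
        labels[5:10, 5:10] = 1
        img = np.full((20, 20), 10.0)
        table = image_quant.quantify_nuclei({"c": img}, labels, {"c": 10.0},
                                            noise_sd={"c": 1.0})
        assert table.intensity.iloc[0] == 0.0
        assert bool(table.censored.iloc[0])

    def test_zero_background_gives_raw_sums(self):
        labels = np.zeros((10, 10), int)
        labels[2:5, 2:5] = 1
        img = np.arange(100, dtype=float).reshape(10, 10)
        table = image_quant.quantify_nuclei({"c": img}, labels, {"c": 0.0})
        assert table.intensity.iloc[0] == img[labels == 1].sum()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            image_quant.quantify_nuclei({"c": np.zeros((5, 5))},
                                        np.zeros((6, 6), int), {"c": 0.0})


class TestTracking:
    @staticmethod
    def records(centroids):
        return pd.DataFrame({"nucleus_id": range(len(centroids)),
                             "centroid_row": [c[0] for c in centroids],
                             "centroid_col": [c[1] for c in centroids]})

    def test_identity_and_small_shift(self):
        pts = [(10, 10), (30, 30), (50, 10)]
        a = self.records(pts)
        assert image_quant.track_nuclei(a, a) == {0: 0, 1: 1, 2: 2}
        b = self.records([(r + 1, c) for r, c in pts])
        assert image_quant.track_nuclei(a, b, max_displacement=5) == {0: 0, 1: 1, 2: 2}

    def test_removed_nucleus_unmatched(self):
        a = self.records([(10, 10), (30, 30), (50, 10)])
        b = self.records([(10, 10), (50, 10)])
        pairing = image_quant.track_nuclei(a, b, max_displacement=5)
        assert pairing[0] == 0 and pairing[2] == 1 and pairing[1] is None


class TestFoldChange:
    @staticmethod
    def toy_table(rep_means: dict[str, dict[float, float]], n_nuclei: int = 30):
        rows = []
        for rep, means in rep_means.items():
            for t, mu in means.items():
                for i in range(n_nuclei):
                    rows.append({"gemma_id": rep, "time_h": t, "nucleus_id": i,
                                 "channel": "ARF1", "intensity": mu})
        return pd.DataFrame(rows)

    def test_constant_intensity_gives_unit_fc(self):
        table = self.toy_table({"r1": {0.0: 50, 8.0: 50}, "r2": {0.0: 80, 8.0: 80}})
        out = image_quant.compute_fold_change(table)
        np.testing.assert_array_equal(out.fc_mean, 1.0)
        np.testing.assert_array_equal(out.fc_se, 0.0)

    def test_halving_across_all_replicates(self):
        table = self.toy_table({f"r{i}": {0.0: 100, 8.0: 50} for i in range(3)})
        out = image_quant.compute_fold_change(table)
        at8 = out[out.time_h == 8.0].iloc[0]
        assert at8.fc_mean == pytest.approx(0.5)
        assert at8.fc_se == pytest.approx(0.0)
        assert at8.n_replicates == 3

    def test_low_nucleus_count_flagged(self):
        table = self.toy_table({"r1": {0.0: 10, 8.0: 5}}, n_nuclei=10)
        with pytest.warns(UserWarning, match="30"):
            out = image_quant.compute_fold_change(table)
        assert out.low_n_warning.all()

    def test_missing_t0_is_error(self):
        table = self.toy_table({"r1": {4.0: 10, 8.0: 5}})
        with pytest.raises(ValueError, match="t = 0"):
            image_quant.compute_fold_change(table)

    def test_generator_decline_recovered(self, arf_tables):
        """End to end on generated fold changes: summary tracks the truth."""
        noisy, truth = arf_tables
        rows = []
        rng = np.random.default_rng(0)
        for _, r in noisy[noisy.arf == "ARF1"].iterrows():
            for i in range(30):
                rows.append({"gemma_id": f"g{r.replicate}", "time_h": r.time_h,
                             "nucleus_id": i, "channel": "ARF1",
                             "intensity": 1000 * r.fc * rng.lognormal(0, 0.05)})
        out = image_quant.compute_fold_change(pd.DataFrame(rows))
        expected = truth[(truth.arf == "ARF1") & (truth.replicate == 1)]
        merged = out.merge(expected, left_on="time_h", right_on="time_h")
        np.testing.assert_allclose(merged.fc_mean, merged.fc, rtol=0.25)
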