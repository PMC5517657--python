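"""Vessel segmentation, skeleton branch counting, neuron detection and the
group summary."""

import numpy as np
import pandas as pd
import pytest

from xpct import DiseaseModel, PhantomSpec, count_branches, detect_neurons, \
    generate_phantom, group_summary, rasterize_vessels, segment_vessels
from xpct.quantify import UnimodalHistogramError, tubular_components


def tube_mask(shape, p0, p1, r):
    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=float) for s in shape),
                             indexing="ij")
    pts = np.stack([zz, yy, xx], -1)
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    u = p1 - p0
    t = np.clip(np.tensordot(pts - p0, u, axes=(-1, 0)) / (u @ u), 0, 1)
    d2 = np.sum((pts - p0 - t[..., None] * u) ** 2, axis=-1)
    return d2 <= r * r


class TestBranchCounting:
    def test_straight_tube_is_one_branch_no_junction(self):
        mask = tube_mask((64, 32, 32), (5, 16, 16), (58, 16, 16), 4)
        graph, n = count_branches(mask)
        assert n == 1
        assert graph.junction_count == 0

    def test_y_tube_has_three_branches_one_junction(self):
        mask = tube_mask((80, 48, 48), (5, 24, 24), (40, 24, 24), 4)
        mask |= tube_mask((80, 48, 48), (40, 24, 24), (72, 38, 24), 4)
        mask |= tube_mask((80, 48, 48), (40, 24, 24), (72, 10, 24), 4)
        graph, n = count_branches(mask)
        assert n == 3
        assert graph.junction_count == 1

    def test_empty_mask_counts_zero_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            _, n = count_branches(np.zeros((8, 8, 8), bool))
        assert n == 0

    def test_junction_counting_mode(self):
        mask = tube_mask((80, 48, 48), (5, 24, 24), (40, 24, 24), 4)
        mask |= tube_mask((80, 48, 48), (40, 24, 24), (72, 38, 24), 4)
        mask |= tube_mask((80, 48, 48), (40, 24, 24), (72, 10, 24), 4)
        _, n = count_branches(mask, count_mode="junctions")
        assert n == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_registry_oracle_on_seeded_trees(self, seed):
        spec = PhantomSpec.micro_default(shape=(96, 96, 96), seed=seed)
        vol = generate_phantom(spec, DiseaseModel())
        mask = rasterize_vessels(vol.vessel_graph, spec.shape, spec.voxel_size_um)
        _, n = count_branches(mask, voxel_size_um=spec.voxel_size_um)
        assert n == vol.branch_count

    def test_count_invariant_under_isotropic_upsampling(self):
        from scipy import ndimage

        mask = tube_mask((60, 40, 40), (4, 20, 20), (30, 20, 20), 3.5)
        mask |= tube_mask((60, 40, 40), (30, 20, 20), (55, 32, 20), 3.5)
        mask |= tube_mask((60, 40, 40), (30, 20, 20), (55, 8, 20), 3.5)
        _, n1 = count_branches(mask, voxel_size_um=2.0)
        # interpolated upsampling; nearest-neighbour block repetition leaves
        # staircase surfaces that topological thinning cannot handle
        up = ndimage.zoom(mask.astype(float), 2.0, order=1) > 0.5
        _, n2 = count_branches(up, voxel_size_um=1.0)
        assert n1 == n2 == 3


class TestSegmentation:
    def volume_with_tubes(self):
        rng = np.random.default_rng(0)
        vol = 0.1 + 0.01 * rng.standard_normal((48, 48, 48))
        mask = tube_mask((48, 48, 48), (4, 24, 20), (44, 24, 20), 3.5)
        mask |= tube_mask((48, 48, 48), (4, 12, 34), (44, 36, 34), 3)
        vol[mask] += 1.0
        return vol, mask

    def test_recovers_bright_tubes(self):
        vol, gt = self.volume_with_tubes()
        roi = np.ones(vol.shape, bool)
        seg = segment_vessels(vol, roi)
        dice = 2 * np.sum(seg & gt) / (seg.sum() + gt.sum())
        assert dice > 0.9

    def test_constant_volume_is_unimodal_error(self):
        with pytest.raises(UnimodalHistogramError):
            segment_vessels(np.full((16, 16, 16), 3.0), np.ones((16, 16, 16), bool))

    def test_polarity_flip_symmetry(self):
        vol, _ = self.volume_with_tubes()
        roi = np.ones(vol.shape, bool)
        bright = segment_vessels(vol, roi, polarity="bright")
        dark = segment_vessels(-vol, roi, polarity="dark")
        assert np.array_equal(bright, dark)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="ROI"):
            segment_vessels(np.ones((8, 8, 8)), np.zeros((8, 8, 8), bool))

    def test_tubular_component_classifier(self):
        shape = (48, 48, 48)
        tubes = tube_mask(shape, (4, 10, 10), (44, 10, 10), 3)
        zz, yy, xx = np.meshgrid(*(np.arange(48) - 30.0,) * 3, indexing="ij")
        ball = zz**2 + yy**2 + xx**2 <= 5**2
        out = tubular_components(tubes | ball)
        assert np.all(out[tubes])
        assert not np.any(out & ball)


class TestNeuronDetection:
    def synthetic_scene(self, centers, diam_vox, shape=(64, 64, 64)):
        vol = np.zeros(shape)
        zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=float) for s in shape),
                                 indexing="ij")
        for c, d in zip(centers, diam_vox):
            r = d / 2
            blob = np.exp(-(((zz - c[0]) ** 2 + (yy - c[1]) ** 2 +
                             (xx - c[2]) ** 2) / (2 * (r / 1.6) ** 2)))
            vol = np.maximum(vol, blob)
        return vol

    def test_exact_count_on_synthetic_somata(self):
        centers = [(16, 20, 20), (40, 30, 40), (50, 44, 18), (22, 44, 44)]
        vol = self.synthetic_scene(centers, [7, 8, 6, 7])
        mask = np.ones(vol.shape, bool)
        det = detect_neurons(vol, mask, size_band_um=(12, 45), voxel_size_um=3.5)
        assert det.count == len(centers)
        for c in centers:
            d = np.linalg.norm(det.centroids_um / 3.5 - np.asarray(c), axis=1)
            assert d.min() < 2.0

    def test_elongated_structures_rejected(self):
        vol = np.zeros((64, 48, 48))
        vol[tube_mask((64, 48, 48), (5, 24, 24), (58, 24, 24), 3.5)] = 1.0
        det = detect_neurons(vol + 1e-6 * np.arange(64)[:, None, None],
                             np.ones(vol.shape, bool), size_band_um=(12, 45),
                             voxel_size_um=3.5)
        assert det.count == 0

    def test_empty_size_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            detect_neurons(np.ones((8, 8, 8)), np.ones((8, 8, 8), bool),
                           size_band_um=(1.0, 2.0), voxel_size_um=3.5)

    def test_ground_truth_counts_monotone_in_loss(self, small_spec):
        counts = []
        for loss in (0.2, 0.6):
            d = DiseaseModel(condition="eae", neuron_loss=loss)
            counts.append(generate_phantom(small_spec, d).neuron_count)
        assert counts[0] >= counts[1]


class TestGroupSummary:
    def rows(self, values, cond="naive", tp=1):
        return [dict(sample_id=f"s{i}", condition=cond, timepoint_dpo=tp,
                     branch_count=v) for i, v in enumerate(values)]

    def test_hand_computed_mean_and_sd(self):
        rep = group_summary(self.rows([2, 4]))
        row = rep.per_group.iloc[0]
        assert row["branch_count_mean"] == pytest.approx(3.0)
        assert row["branch_count_sd"] == pytest.approx(np.sqrt(2.0))
        assert row["n"] == 2

    def test_identical_samples_have_zero_sd(self):
        rep = group_summary(self.rows([3, 3, 3]))
        assert rep.per_group.iloc[0]["branch_count_sd"] == 0.0

    def test_permutation_invariance(self):
        a = group_summary(self.rows([5, 9, 7])).per_group
        b = group_summary(self.rows([9, 7, 5])).per_group
        pd.testing.assert_frame_equal(a, b)

    def test_single_sample_warns_and_reports_zero_sd(self):
        with pytest.warns(UserWarning, match="n = 1"):
            rep = group_summary(self.rows([4]))
        assert rep.per_group.iloc[0]["branch_count_sd"] == 0.0

    def test_six_group_layout(self):
        rows = []
        for cond in ("naive", "eae", "eae_msc"):
            for tp in (1, 5):
                rows += self.rows([1, 2, 3], cond=cond, tp=tp)
        rep = group_summary(rows)
        assert len(rep.per_group) == 6
        assert set(rep.per_group["n"]) == {3}

    def test_missing_group_keys_rejected(self):
        with pytest.raises(ValueError, match="group keys"):
            group_summary([{"branch_count": 1}])
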