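"""Phantom generation: determinism, disease severities, registry ground truth."""

import numpy as np
import pytest

from xpct import (DiseaseModel, MaterialTable, PhantomSpec, contrast_grids,
                  count_branches, generate_phantom, rasterize_refractive,
                  ventral_horn_mask)
from xpct import materials as mat
from xpct.phantom import NeuronParams


def disease(**kw):
    kw.setdefault("condition", "eae")
    return DiseaseModel(**kw)


class TestSpecValidation:
    def test_structures_must_span_more_than_two_voxels(self):
        spec = PhantomSpec(shape=(32, 64, 64), voxel_size_um=6.0, mode="micro")
        with pytest.raises(ValueError, match="two voxels"):
            spec.validate()

    def test_cord_must_fit_grid_with_margin(self):
        spec = PhantomSpec(shape=(32, 64, 64), voxel_size_um=3.5,
                           cord_radius_um=0.5 * 64 * 3.5)
        with pytest.raises(ValueError, match="margin"):
            spec.validate()

    def test_naive_condition_rejects_nonzero_severity(self):
        with pytest.raises(ValueError, match="naive"):
            DiseaseModel(condition="naive", neuron_loss=0.2)

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            disease(vessel_dropout=1.5)
        with pytest.raises(ValueError):
            disease(vessel_contrast=0.0)


class TestGeneration:
    def test_bit_identical_under_fixed_seeds(self, small_spec):
        a = generate_phantom(small_spec, DiseaseModel())
        b = generate_phantom(small_spec, DiseaseModel())
        assert np.array_equal(a.labels, b.labels)
        assert a.branch_count == b.branch_count
        assert [tuple(n["centroid_um"]) for n in a.neurons] == \
               [tuple(n["centroid_um"]) for n in b.neurons]

    def test_total_neuron_loss_empties_registry(self, small_spec):
        vol = generate_phantom(small_spec, disease(neuron_loss=1.0))
        assert vol.neurons == []
        assert not np.any(vol.labels == mat.NEURON)

    def test_registry_branch_count_matches_skeleton_oracle(self):
        spec = PhantomSpec.micro_default(shape=(96, 96, 96), seed=7)
        vol = generate_phantom(spec, DiseaseModel())
        _, n = count_branches(vol.vessel_mask(), voxel_size_um=spec.voxel_size_um)
        assert n == vol.branch_count

    def test_occlusions_rejected_in_micro_mode(self, small_spec):
        d = disease(timepoint_dpo=5, capillary_occlusion_per_mm=5.0)
        with pytest.raises(ValueError, match="nano"):
            generate_phantom(small_spec, d)

    def test_nano_phantom_has_capillaries_membranes_and_occlusions(self):
        spec = PhantomSpec.nano_default(seed=2)
        healthy = generate_phantom(spec, DiseaseModel())
        assert np.any(healthy.labels == mat.VESSEL)
        assert np.any(healthy.labels == mat.MEMBRANE)
        assert healthy.occlusions == []
        sick = generate_phantom(spec, disease(timepoint_dpo=5,
                                              capillary_occlusion_per_mm=120.0,
                                              neuron_loss=0.6, vessel_contrast=0.9))
        assert len(sick.occlusions) > 0
        # occluding cells replace lumen with membrane material
        assert np.sum(sick.labels == mat.VESSEL) < np.sum(healthy.labels == mat.VESSEL)


class TestSeverityMonotonicity:
    def test_vessel_volume_non_increasing_in_dropout(self, small_spec):
        vols = []
        for f in (0.0, 0.3, 0.6, 1.0):
            d = DiseaseModel() if f == 0 else disease(vessel_dropout=f)
            vols.append(int(np.sum(generate_phantom(small_spec, d).labels == mat.VESSEL)))
        assert all(a >= b for a, b in zip(vols, vols[1:]))

    def test_neuron_count_non_increasing_in_loss(self, small_spec):
        counts = []
        for f in (0.0, 0.4, 0.8, 1.0):
            d = DiseaseModel() if f == 0 else disease(neuron_loss=f)
            counts.append(generate_phantom(small_spec, d).neuron_count)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_msc_severities_are_eae_times_multiplier(self):
        eae = DiseaseModel.preset("eae", 1)
        msc = DiseaseModel.preset("eae_msc", 1)
        eff = msc.effective()
        m = msc.treatment_multiplier
        assert eff.vessel_dropout == pytest.approx(eae.vessel_dropout * m)
        assert eff.neuron_loss == pytest.approx(eae.neuron_loss * m)
        assert 1 - eff.vessel_contrast == pytest.approx(m * (1 - eae.vessel_contrast))

    def test_msc_ground_truth_between_naive_and_eae(self, small_spec):
        counts = {}
        for cond in ("naive", "eae", "eae_msc"):
            vol = generate_phantom(small_spec, DiseaseModel.preset(cond, 1, seed=3))
            counts[cond] = (vol.branch_count, vol.neuron_count)
        assert counts["naive"][0] >= counts["eae_msc"][0] >= counts["eae"][0]
        assert counts["naive"][1] >= counts["eae_msc"][1] >= counts["eae"][1]

    def test_artery_survives_any_dropout(self, small_spec):
        vol = generate_phantom(small_spec, disease(vessel_dropout=1.0))
        kinds = {d["kind"] for _, _, d in vol.vessel_graph.edges(data=True)}
        assert "artery" in kinds


class TestVentralHornMask:
    def test_contains_every_neuron_centroid(self, small_phantom):
        mask = ventral_horn_mask(small_phantom)
        v = small_phantom.voxel_size_um
        for n in small_phantom.neurons:
            idx = tuple(np.round(np.asarray(n["centroid_um"]) / v).astype(int))
            assert mask[idx]

    def test_strict_subset_of_grey_matter(self, small_phantom):
        mask = ventral_horn_mask(small_phantom)
        grey = np.isin(small_phantom.labels, [mat.GREY_MATTER, mat.NEURON, mat.VESSEL])
        # the ventral section is carved from the butterfly cross-section
        assert mask.sum() < grey.sum()

    def test_left_right_mirror_symmetry(self, small_phantom):
        mask = ventral_horn_mask(small_phantom)
        assert np.array_equal(mask, mask[:, :, ::-1])


class TestRasterize:
    def test_pointwise_lookup_constant_for_single_material(self, table30):
        spec = PhantomSpec.micro_default(shape=(16, 64, 64), seed=0,
                                         neurons=NeuronParams(per_horn=1))
        vol = generate_phantom(spec, DiseaseModel())
        vol.labels[:] = mat.GREY_MATTER
        delta, beta = rasterize_refractive(vol, table30)
        assert np.unique(delta).size == 1
        assert delta.flat[0] == table30.delta(mat.GREY_MATTER)

    def test_two_material_grid_has_exactly_two_values(self, table30, small_phantom):
        import copy

        vol = copy.copy(small_phantom)
        vol.labels = np.where(small_phantom.labels == mat.BACKGROUND,
                              mat.BACKGROUND, mat.WHITE_MATTER).astype(np.uint8)
        delta, _ = rasterize_refractive(vol, table30)
        assert np.unique(delta).size == 2

    def test_unknown_label_raises_with_offenders(self, table30, small_phantom):
        import copy

        vol = copy.copy(small_phantom)
        vol.labels = small_phantom.labels.copy()
        vol.labels[0, 0, 0] = 99
        with pytest.raises(KeyError, match="99"):
            rasterize_refractive(vol, table30)

    def test_vessel_contrast_attenuation_blends_toward_grey(self, table30, small_spec):
        full = generate_phantom(small_spec, DiseaseModel())
        att = generate_phantom(small_spec, disease(vessel_contrast=0.5))
        d_full, _ = rasterize_refractive(full, table30)
        d_att, _ = rasterize_refractive(att, table30)
        vm = full.labels == mat.VESSEL
        dg = table30.delta(mat.GREY_MATTER)
        assert d_att[vm].max() < d_full[vm].max()
        assert d_att[vm].min() > dg

    def test_contrast_grids_vanish_in_embedding(self, table30, small_phantom):
        delta, beta = contrast_grids(small_phantom, table30, smooth_sigma_vox=0.0)
        bg = small_phantom.labels == mat.BACKGROUND
        assert np.all(delta[bg] == 0.0)
        assert np.all(beta[bg] == 0.0)
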