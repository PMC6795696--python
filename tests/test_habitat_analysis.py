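import numpy as np
import pytest

from habitatmap.classifiers import HabitatMap
from habitatmap.habitat_analysis import (
    compare_timepoints,
    export_overlay,
    spie_geometry,
    summarize_habitats,
)
from habitatmap.volumes_io import MaskVolume, ParameterVolume, Quantity, VoxelGrid


def toy_study(labels, adc_values, spacing=(1.0, 1.0, 1.0)):
    labels = np.asarray(labels, dtype=int)
    grid = VoxelGrid(shape=labels.shape, spacing=spacing)
    habitat = HabitatMap(grid=grid, labels=labels, valid=labels > 0)
    adc = ParameterVolume(grid=grid, values=np.asarray(adc_values, dtype=float),
                          quantity=Quantity.ADC)
    voi = MaskVolume(grid=grid, membership=labels > 0, label="voi")
    return habitat, adc, voi


class TestSummarizeHabitats:
    def test_pure_class3_voi(self):
        labels = np.full((5, 2, 1), 3)
        adc = np.full((5, 2, 1), 2.4e-3)
        habitat, adc_vol, voi = toy_study(labels, adc)
        s = summarize_habitats(habitat, adc_vol, voi)
        assert [s.fractions[c] for c in (1, 2, 3, 4, 5)] == [0, 0, 1.0, 0, 0]
        assert s.mean_adc[3] == pytest.approx(2.4e-3)

    def test_hand_arithmetic_two_class_toy(self):
        # 10 voxels: 6 class-1 at ADC 1.0e-3, 4 class-3 at ADC 2.5e-3
        labels = np.array([1] * 6 + [3] * 4).reshape(10, 1, 1)
        adc = np.array([1.0e-3] * 6 + [2.5e-3] * 4).reshape(10, 1, 1)
        habitat, adc_vol, voi = toy_study(labels, adc)
        s = summarize_habitats(habitat, adc_vol, voi)
        assert s.fractions[1] == pytest.approx(0.6)
        assert s.fractions[3] == pytest.approx(0.4)
        assert s.mean_adc[1] == pytest.approx(1.0e-3)
        assert s.mean_adc[3] == pytest.approx(2.5e-3)
        assert np.isnan(s.mean_adc[2]) and np.isnan(s.mean_adc[4])

    def test_voxel_volume_scaling(self):
        labels = np.ones((50, 1, 1), dtype=int)
        adc = np.full((50, 1, 1), 1e-3)
        habitat, adc_vol, voi = toy_study(labels, adc, spacing=(2.0, 1.0, 1.0))
        s = summarize_habitats(habitat, adc_vol, voi)
        assert s.total_volume_mm3 == pytest.approx(100.0)

    def test_fractions_sum_to_one_and_counts_conserve(self, default_phantom):
        s = summarize_habitats(default_phantom.truth, default_phantom.adc,
                               default_phantom.voi)
        assert sum(s.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(s.voxel_counts.values()) == default_phantom.voi.size

    def test_fat_adc_flagged_non_interpretable(self):
        labels = np.full((4, 1, 1), 4)
        habitat, adc_vol, voi = toy_study(labels, np.full((4, 1, 1), 1e-3))
        s = summarize_habitats(habitat, adc_vol, voi)
        assert not s.adc_interpretable[4]
        assert np.isfinite(s.mean_adc[4])  # computed, just flagged

    def test_phantom_ground_truth_recovers_designed_means(self, default_phantom):
        s = summarize_habitats(default_phantom.truth, default_phantom.adc,
                               default_phantom.voi)
        for c, params in default_phantom.spec.class_params.items():
            se = params.adc_sd / np.sqrt(s.voxel_counts[c])
            assert abs(s.mean_adc[c] - params.adc_mean) < 2 * se, c

    def test_empty_voi_rejected(self):
        labels = np.zeros((3, 3, 1), dtype=int)
        grid = VoxelGrid(shape=labels.shape, spacing=(1, 1, 1))
        habitat = HabitatMap(grid=grid, labels=labels, valid=labels > 0)
        adc = ParameterVolume(grid=grid, values=np.ones(labels.shape) * 1e-3,
                              quantity=Quantity.ADC)
        voi = MaskVolume(grid=grid, membership=np.zeros(labels.shape, bool))
        with pytest.raises(ValueError):
            summarize_habitats(habitat, adc, voi)


class TestSpieGeometry:
    def _summary(self, fractions, adcs):
        labels = np.concatenate([np.full(int(f * 100), c)
                                 for c, f in fractions.items()])
        adc = np.concatenate([np.full(int(fractions[c] * 100), adcs[c])
                              for c in fractions])
        habitat, adc_vol, voi = toy_study(labels.reshape(-1, 1, 1),
                                          adc.reshape(-1, 1, 1))
        return summarize_habitats(habitat, adc_vol, voi)

    def test_half_half_gives_two_180_degree_segments(self):
        s = self._summary({1: 0.5, 3: 0.5}, {1: 1e-3, 3: 2e-3})
        segments = {seg.class_id: seg for seg in spie_geometry(s)}
        assert segments[1].angle_deg == pytest.approx(180.0)
        assert segments[3].angle_deg == pytest.approx(180.0)

    def test_angles_conserve_360(self):
        s = self._summary({1: 0.2, 2: 0.3, 3: 0.5}, {1: 1e-3, 2: 1.2e-3, 3: 2.4e-3})
        total = sum(seg.angle_deg for seg in spie_geometry(s))
        assert total == pytest.approx(360.0, abs=1e-6)

    def test_reference_radii_attached(self):
        pre = self._summary({1: 0.5, 3: 0.5}, {1: 1.0e-3, 3: 2.0e-3})
        post = self._summary({1: 0.3, 3: 0.7}, {1: 1.4e-3, 3: 2.0e-3})
        segments = {seg.class_id: seg for seg in spie_geometry(post, reference=pre)}
        # shared radial scale: max interpretable mean ADC across both = 2.0e-3
        assert segments[1].reference_radius == pytest.approx(1.0e-3 / 2.0e-3)
        assert segments[1].radius == pytest.approx(1.4e-3 / 2.0e-3)

    def test_class_colors_match_taxonomy(self):
        s = self._summary({1: 0.5, 3: 0.5}, {1: 1e-3, 3: 2e-3})
        colors = {seg.class_id: seg.color for seg in spie_geometry(s)}
        assert colors[1] == "red" and colors[3] == "blue"


class TestCompareTimepoints:
    def _summary(self, labels, adc):
        habitat, adc_vol, voi = toy_study(np.asarray(labels).reshape(-1, 1, 1),
                                          np.asarray(adc).reshape(-1, 1, 1))
        return summarize_habitats(habitat, adc_vol, voi)

    def test_identical_summaries_all_zero(self):
        s = self._summary([1] * 6 + [3] * 4, [1e-3] * 6 + [2e-3] * 4)
        comparison = compare_timepoints(s, s)
        assert comparison.total_volume_change_pct == 0.0
        assert all(v == 0.0 for v in comparison.delta_fraction.values())

    def test_volume_reduction_arithmetic(self):
        pre = self._summary([1] * 1000, [1e-3] * 1000)
        post = self._summary([1] * 943, [1e-3] * 943)
        comparison = compare_timepoints(pre, post)
        assert comparison.total_volume_change_pct == pytest.approx(-5.7)

    def test_class_appearing_only_post(self):
        pre = self._summary([1] * 10, [1e-3] * 10)
        post = self._summary([1] * 6 + [2] * 4, [1e-3] * 10)
        comparison = compare_timepoints(pre, post)
        assert comparison.delta_fraction[2] == pytest.approx(0.4)
        assert np.isnan(comparison.delta_mean_adc[2])  # undefined pre-treatment

    def test_zero_pre_volume_rejected(self):
        s = self._summary([1] * 10, [1e-3] * 10)
        import dataclasses
        broken = dataclasses.replace(s, total_volume_mm3=0.0)
        with pytest.raises(ValueError):
            compare_timepoints(broken, s)


class TestExportOverlay:
    def test_legend_always_five_entries(self, default_phantom):
        overlay, legend = export_overlay(default_phantom.truth)
        assert sorted(legend) == ["1", "2", "3", "4", "5"]
        assert legend["1"]["color"] == "red"
        assert legend["3"]["color"] == "blue"

    def test_empty_class_absent_from_overlay_present_in_legend(self, default_phantom):
        overlay, legend = export_overlay(default_phantom.truth)
        present = set(np.unique(overlay.values[default_phantom.voi.membership]))
        assert 5 not in present  # no novelty voxels in ground truth
        assert "5" in legend

    def test_misaligned_anatomical_rejected(self, default_phantom):
        other = ParameterVolume(
            grid=VoxelGrid(shape=(4, 4, 4), spacing=(1, 1, 1)),
            values=np.zeros((4, 4, 4)), quantity=Quantity.SIGNAL)
        with pytest.raises(ValueError):
            export_overlay(default_phantom.truth, anatomical=other)
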