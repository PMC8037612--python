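import numpy as np
import pandas as pd
import pytest

import prolifmap as pm
from prolifmap import phantom as ph


class TestBuildPhantom:
    def test_every_compartment_has_volume(self, phantom_volume):
        vols = phantom_volume.volumes_mm3()
        for label in (ph.SEZ, ph.CMS_OTHER, ph.RMS, ph.MIDLAYER, ph.SGZ, ph.WM, ph.PARENCHYMA):
            assert vols.get(label, 0.0) > 0.0

    def test_mirror_symmetric_at_voxel_level(self, phantom_volume):
        assert np.array_equal(phantom_volume.mirrored().data, phantom_volume.data)

    def test_labels_partition_brain(self, phantom_volume):
        labels = np.unique(phantom_volume.data)
        assert set(labels.tolist()) == {0, 1, 2, 3, 4, 5, 6, 7}

    def test_volume_estimates_converge_under_voxel_halving(self, phantom_volume):
        fine = pm.build_phantom(pm.PhantomSpec(voxel_size_um=25.0))
        coarse = phantom_volume.volumes_mm3()
        halved = fine.volumes_mm3()
        for label in coarse:
            if label == 0:
                continue
            assert halved[label] == pytest.approx(coarse[label], rel=0.05)
        # brain total against the analytic ellipsoid volume 4/3*pi*abc
        brain = sum(v for k, v in coarse.items() if k > 0)
        assert brain == pytest.approx(4 / 3 * np.pi * 3.0 * 2.0 * 4.0, rel=0.05)

    def test_nonpositive_extents_rejected(self):
        with pytest.raises(ValueError):
            pm.PhantomSpec(brain_extents_um=(6000.0, -1.0, 8000.0))
        with pytest.raises(ValueError):
            pm.PhantomSpec(voxel_size_um=0.0)


class TestSampleNuclei:
    def test_zero_intensity_gives_empty_cloud(self, phantom_volume):
        lam = {label: 0.0 for label in range(1, 8)}
        gt = pm.sample_nuclei(phantom_volume, lam, seed=1)
        assert len(gt) == 0

    def test_unknown_label_named_in_error(self, phantom_volume):
        with pytest.raises(ValueError, match="99"):
            pm.sample_nuclei(phantom_volume, {99: 10.0}, seed=1)

    def test_negative_intensity_rejected(self, phantom_volume):
        with pytest.raises(ValueError):
            pm.sample_nuclei(phantom_volume, {ph.SGZ: -1.0}, seed=1)

    def test_intensity_names_accepted(self, phantom_volume):
        gt = pm.sample_nuclei(phantom_volume, {"sgz": 100.0}, seed=1)
        assert (gt.points["label"] == ph.SGZ).all()

    def test_poisson_count_law_in_unit_region(self):
        # one cubic millimetre at 400 nuclei/mm3, repeated over 100 seeds
        box = pm.LabelVolume(np.ones((10, 10, 10), dtype=np.int16), voxel_size_um=100.0)
        counts = np.array([len(pm.sample_nuclei(box, {1: 400.0}, seed=s)) for s in range(100)])
        assert abs(counts.mean() - 400.0) <= 3.0 * 20.0 / 10.0  # 3 SE of the mean
        dispersion = counts.var(ddof=1) / counts.mean()
        assert 0.7 <= dispersion <= 1.3

    def test_positions_lie_in_their_label(self, truth_2m, phantom_volume):
        looked_up = phantom_volume.label_at(
            truth_2m.points[["x_um", "y_um", "z_um"]].to_numpy())
        assert np.array_equal(looked_up, truth_2m.points["label"].to_numpy())

    def test_calibrated_young_phantom_size(self, truth_2m):
        # expected total is the published whole-brain count for the youngest age
        assert sum(truth_2m.expected_counts.values()) == pytest.approx(68010, abs=1)
        assert abs(len(truth_2m) - 68010) < 4 * np.sqrt(68010)


class TestVirtualSectioning:
    def test_section_index_is_floor_of_z_over_thickness(self):
        pts = pd.DataFrame({"x_um": [0.0], "y_um": [0.0], "z_um": [125.0]})
        secs = pm.virtual_sectioning(pts, thickness_um=50.0)
        assert [s.index for s in secs] == [2]

    def test_sections_partition_the_cloud(self, truth_2m):
        secs = pm.virtual_sectioning(truth_2m.points)
        assert sum(len(s) for s in secs) == len(truth_2m.points)

    def test_full_z_extent_gives_160_sections(self):
        z = np.arange(0.0, 8000.0, 10.0) + 5.0
        pts = pd.DataFrame({"x_um": 0.0, "y_um": 0.0, "z_um": z})
        secs = pm.virtual_sectioning(pts, thickness_um=50.0)
        assert len(secs) == 160
        assert secs[-1].index == 159

    def test_nonpositive_thickness_rejected(self):
        with pytest.raises(ValueError):
            pm.virtual_sectioning(pd.DataFrame({"x_um": [], "y_um": [], "z_um": []}), 0.0)

    def test_round_trip_bounded_by_half_thickness(self, truth_2m):
        secs = pm.virtual_sectioning(truth_2m.points, thickness_um=50.0)
        cloud = pm.assemble_stack(secs, thickness_um=50.0)
        orig = truth_2m.points.sort_values(["x_um", "y_um"], ignore_index=True)
        back = cloud.sort_values(["x_um", "y_um"], ignore_index=True)
        assert np.array_equal(orig["x_um"], back["x_um"])
        assert np.array_equal(orig["y_um"], back["y_um"])
        assert np.abs(orig["z_um"] - back["z_um"]).max() <= 25.0


class TestRenderSections:
    def _one_section(self, xy_um):
        tab = pd.DataFrame({"x": [p[0] for p in xy_um], "y": [p[1] for p in xy_um]})
        return pm.SectionTable(index=0, table=tab)

    def test_no_nuclei_renders_pure_background(self):
        imgs = pm.render_sections([self._one_section([])], background=200,
                                  shape_px=(32, 32))
        assert (imgs[0] == 200).all()

    def test_single_nucleus_argmax_at_its_pixel(self):
        imgs = pm.render_sections([self._one_section([(25.8, 12.9)])],
                                  psf_sigma_um=2.58, shape_px=(32, 32))
        row, col = np.unravel_index(np.argmax(imgs[0]), imgs[0].shape)
        assert (row, col) == (10, 20)  # y/1.29, x/1.29

    def test_peak_above_bit_depth_rejected(self):
        with pytest.raises(ValueError):
            pm.render_sections([self._one_section([])], bit_depth=8, peak_intensity=5000)

    def test_out_of_frame_spots_clipped_and_logged(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="prolifmap.phantom"):
            imgs = pm.render_sections([self._one_section([(10000.0, 10000.0)])],
                                      shape_px=(16, 16), background=7)
        assert (imgs[0] == 7).all()
        assert "clipped" in caplog.text

    def test_dtype_matches_bit_depth(self):
        sec = self._one_section([(12.9, 12.9)])
        assert pm.render_sections([sec], bit_depth=16)[0].dtype == np.uint16
        assert pm.render_sections([sec], bit_depth=8, peak_intensity=200)[0].dtype == np.uint8
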