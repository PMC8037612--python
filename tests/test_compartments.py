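import logging

import numpy as np
import pandas as pd
import pytest

import prolifmap as pm
from prolifmap import phantom as ph


class TestScheme:
    def test_leaves_and_nodes(self):
        scheme = pm.DEFAULT_SCHEME
        assert set(scheme.leaves()) == {"sez", "other_cms", "rms", "midlayer",
                                        "sgz", "wm", "parenchyma"}
        assert scheme.nodes()[0] == "brain"
        assert scheme.leaf_ids("cms") == [ph.SEZ, ph.CMS_OTHER]
        assert scheme.children("mpz") == ["cms", "rms", "midlayer"]

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError):
            pm.DEFAULT_SCHEME.leaf_ids("cerebellum")


class TestTable1Fixture:
    def test_shape_and_ages(self):
        t1 = pm.load_table1()
        assert len(t1) == 10
        assert sorted(t1["age_months"].unique()) == [2, 4, 8, 12, 30]

    def test_hierarchy_identities_hold_exactly(self):
        t1 = pm.load_table1()
        assert (t1["brain_npc"] == t1["mpz_npc"] + t1["sgz_npc"] + t1["other_npc"]).all()
        assert (t1["mpz_npc"] == t1["cms_npc"] + t1["rms_npc"] + t1["midlayer_npc"]).all()
        assert (t1["cms_npc"] == t1["sez_npc"] + t1["other_cms_npc"]).all()

    def test_young_adult_row_sums(self):
        row = pm.load_table1().set_index("mouse").loc["2M-A"]
        assert row["mpz_npc"] + row["sgz_npc"] + row["other_npc"] == 68010
        assert row["sez_npc"] + row["other_cms_npc"] == 30607


class TestAssignCompartments:
    def test_phantom_points_recover_generator_labels(self, cloud_2m):
        # sampled positions are jittered inside label voxels, so nearest-voxel
        # lookup must agree with the generator everywhere
        assert (cloud_2m["label"] == cloud_2m["true_label"]).all()

    def test_empty_cloud(self, phantom_volume):
        empty = pd.DataFrame({"x_um": [], "y_um": [], "z_um": []})
        assert len(pm.assign_compartments(empty, phantom_volume)) == 0

    def test_point_on_voxel_center(self, phantom_volume):
        vol = phantom_volume
        idx = np.argwhere(vol.data == ph.SGZ)[0]
        center = vol.origin_um + (idx + 0.5) * vol.voxel_size_um
        pts = pd.DataFrame({"x_um": [center[0]], "y_um": [center[1]], "z_um": [center[2]]})
        assert pm.assign_compartments(pts, vol)["label"].iloc[0] == ph.SGZ

    def test_outside_points_fall_back_and_log(self, phantom_volume, caplog):
        pts = pd.DataFrame({"x_um": [1e6], "y_um": [1e6], "z_um": [1e6]})
        with caplog.at_level(logging.WARNING, logger="prolifmap.compartments"):
            out = pm.assign_compartments(pts, phantom_volume)
        assert out["label"].iloc[0] == ph.PARENCHYMA
        assert "outside" in caplog.text


class TestCountsTable:
    def test_hierarchy_conservation_on_phantom(self, cloud_2m):
        row = pm.counts_table(cloud_2m, mouse_id="phantom", age_months=2)
        assert pm.verify_hierarchy(row)
        assert row["brain_npc"].iloc[0] == len(cloud_2m)

    def test_empty_cloud_zero_counts_nan_densities(self):
        empty = pd.DataFrame({"x_um": [], "y_um": [], "z_um": [],
                              "label": pd.Series(dtype=int),
                              "density": pd.Series(dtype=float)})
        row = pm.counts_table(empty)
        assert row["brain_npc"].iloc[0] == 0
        assert np.isnan(row["brain_avnd"].iloc[0])

    def test_requires_labels_and_densities(self, truth_2m):
        with pytest.raises(ValueError):
            pm.counts_table(truth_2m.points.drop(columns="label"))


class TestSelectHighDensity:
    def _pts(self, densities):
        n = len(densities)
        return pd.DataFrame({"x_um": np.arange(n, dtype=float), "y_um": 0.0,
                             "z_um": 0.0, "section_index": 0,
                             "density": densities})

    def test_full_fraction_returns_everything(self):
        pts = self._pts([3, 1, 2])
        assert len(pm.select_high_density(pts, 1.0)) == 3

    def test_top_fifth_of_ranked_densities(self):
        pts = self._pts(list(range(10)))
        sel = pm.select_high_density(pts, 0.2)
        assert sorted(sel["density"]) == [8, 9]

    def test_output_size_is_ceiling(self):
        assert len(pm.select_high_density(self._pts([1] * 7), 0.2)) == 2  # ceil(1.4)

    def test_idempotent_at_same_fraction(self):
        pts = self._pts(list(range(25)))
        once = pm.select_high_density(pts, 0.2)
        twice = pm.select_high_density(once, 1.0)
        assert sorted(twice.index) == sorted(once.index)

    def test_deterministic_tie_break(self):
        pts = pd.DataFrame({"x_um": [5.0, 1.0, 3.0], "y_um": 0.0, "z_um": 0.0,
                            "section_index": [1, 0, 0], "density": [4, 4, 4]})
        sel = pm.select_high_density(pts, 0.5)  # ceil(1.5) = 2
        assert sel["x_um"].tolist() == [1.0, 3.0]  # section asc, then x asc

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            pm.select_high_density(self._pts([1]), 0.0)


class TestBilateralFilter:
    def test_symmetric_set_unchanged(self):
        x = np.array([-300.0, 300.0, -500.0, 500.0])
        pts = pd.DataFrame({"x_um": x, "y_um": 0.0, "z_um": 0.0})
        assert len(pm.bilateral_filter(pts, 0.0)) == 4

    def test_unilateral_cluster_removed(self):
        pts = pd.DataFrame({"x_um": [800.0, 820.0, 790.0], "y_um": 0.0, "z_um": 0.0})
        assert len(pm.bilateral_filter(pts, 0.0)) == 0

    def test_midline_point_pairs_with_itself(self):
        pts = pd.DataFrame({"x_um": [0.0], "y_um": [0.0], "z_um": [0.0]})
        assert len(pm.bilateral_filter(pts, 0.0)) == 1

    def test_mixed_case(self):
        pts = pd.DataFrame({"x_um": [-400.0, 400.0, 1500.0], "y_um": 0.0, "z_um": 0.0})
        kept = pm.bilateral_filter(pts, 0.0)
        assert kept["x_um"].tolist() == [-400.0, 400.0]
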