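"""ROI aggregation, Gini sparseness, voxelwise maps, NIfTI round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurocost.fmri import (aggregate_roi_costs, gini_index, map_to_nifti,
                            nifti_to_beta_table, roi_associations,
                            sparseness_association, sparseness_profile,
                            voxelwise_map)
from neurocost.synthetic import SyntheticBetaSpec, gen_voxel_betas


class TestAggregation:
    def test_hand_worked_levels(self, tiny_beta_table):
        costs = aggregate_roi_costs(tiny_beta_table)
        pres = costs.per_presentation.set_index(
            ["subject", "image", "presentation"])["cost"]
        assert pres[("sub1", 0, 1)] == pytest.approx(0.2)   # signed sum
        si = costs.per_subject_image.set_index(["subject", "image"])["cost"]
        assert si[("sub1", 0)] == pytest.approx(0.3)        # repeat mean
        grp = costs.per_image.set_index("image")["cost"]
        assert grp[0] == pytest.approx(0.4)                 # subject mean

    def test_matches_groupby_sum_oracle(self, rng):
        n = 300
        table = pd.DataFrame({
            "subject": rng.choice(["s1", "s2"], n),
            "image": rng.integers(0, 5, n),
            "presentation": 1,
            "roi": rng.choice(["A", "B"], n),
            "voxel": np.arange(n),
            "beta": rng.standard_normal(n),
        })
        costs = aggregate_roi_costs(table)
        want = (table.groupby(["subject", "image", "presentation", "roi"])
                ["beta"].sum())
        got = costs.per_presentation.set_index(
            ["subject", "image", "presentation", "roi"])["cost"]
        pd.testing.assert_series_equal(got.sort_index(), want.sort_index(),
                                       check_names=False)

    def test_linearity_in_betas(self, tiny_beta_table):
        a = aggregate_roi_costs(tiny_beta_table)
        scaled = tiny_beta_table.assign(beta=tiny_beta_table["beta"] * 3.0)
        b = aggregate_roi_costs(scaled)
        np.testing.assert_allclose(b.per_image["cost"],
                                   3.0 * a.per_image["cost"])

    def test_first_presentation_policy(self, tiny_beta_table):
        costs = aggregate_roi_costs(tiny_beta_table, repeat_policy="first")
        si = costs.per_subject_image.set_index(["subject", "image"])["cost"]
        assert si[("sub1", 0)] == pytest.approx(0.2)

    def test_empty_roi_named_in_error(self, tiny_beta_table):
        roi_map = {f"PPA_v{v}": "PPA" for v in range(3)}
        roi_map["ghost_voxel"] = "FFA"  # FFA gets no actual voxels
        with pytest.raises(ValueError, match="FFA"):
            aggregate_roi_costs(tiny_beta_table, roi_map=roi_map)

    def test_roi_map_assigns_and_ignores_unassigned(self, tiny_beta_table):
        roi_map = {"PPA_v0": "left", "PPA_v1": "left"}  # v2 unassigned
        costs = aggregate_roi_costs(tiny_beta_table, roi_map=roi_map)
        pres = costs.per_presentation.set_index(
            ["subject", "image", "presentation"])["cost"]
        assert pres[("sub1", 0, 1)] == pytest.approx(0.1 - 0.2)


class TestGini:
    def test_closed_forms(self):
        assert gini_index(np.full(6, 2.5)) == pytest.approx(0.0)
        assert gini_index([0, 0, 0, 0, 7.0]) == pytest.approx(0.8)  # (n-1)/n
        assert gini_index([1, 2, 3, 4]) == pytest.approx(0.25)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 100), min_size=2, max_size=20),
           st.floats(0.1, 50))
    def test_scale_and_permutation_invariance(self, values, c):
        v = np.asarray(values)
        g = gini_index(v)
        assert gini_index(c * v) == pytest.approx(g, abs=1e-9)
        assert gini_index(v[::-1]) == pytest.approx(g, abs=1e-12)
        assert 0 <= g < 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            gini_index(np.zeros(4))

    def test_signed_policies(self):
        v = np.array([-1.0, 2.0, -3.0])
        with pytest.raises(ValueError, match="signed_policy"):
            gini_index(v)
        assert gini_index(v, signed_policy="abs") == \
            pytest.approx(gini_index([1.0, 2.0, 3.0]))
        assert gini_index(v, signed_policy="positive-part") == \
            pytest.approx(gini_index([0.0, 2.0, 0.0]))


class TestRoiAssociations:
    def test_planted_rho_recovered(self, rng):
        ratings = rng.standard_normal(150)
        spec = SyntheticBetaSpec(n_images=150, n_subjects=2, repeats=2,
                                 rois=("PPA", "V1"), voxels_per_roi=6,
                                 planted_roi_rho={"PPA": -0.5}, seed=2)
        costs = aggregate_roi_costs(gen_voxel_betas(spec, ratings))
        assoc = roi_associations(
            costs, pd.Series(ratings, index=np.arange(150)))
        by_roi = assoc.set_index("roi")
        assert by_roi.loc["PPA", "rho"] == pytest.approx(-0.5, abs=0.15)
        assert abs(by_roi.loc["V1", "rho"]) < 0.2
        assert by_roi.loc["PPA", "ci_low"] <= by_roi.loc["PPA", "rho"] \
            <= by_roi.loc["PPA", "ci_high"]

    def test_too_few_images_rejected(self, rng):
        spec = SyntheticBetaSpec(n_images=3, n_subjects=1, repeats=1,
                                 rois=("V1",), voxels_per_roi=2, seed=0)
        costs = aggregate_roi_costs(gen_voxel_betas(spec,
                                                    rng.standard_normal(3)))
        with pytest.raises(ValueError, match="need >= 4"):
            roi_associations(costs, pd.Series(rng.standard_normal(3)))

    def test_subject_level_rows(self, rng):
        spec = SyntheticBetaSpec(n_images=10, n_subjects=3, repeats=1,
                                 rois=("V1", "V2"), voxels_per_roi=2, seed=1)
        costs = aggregate_roi_costs(gen_voxel_betas(spec,
                                                    rng.standard_normal(10)))
        assoc = roi_associations(costs, pd.Series(rng.standard_normal(10)),
                                 level="subject")
        assert len(assoc) == 3 * 2
        assert {"subject", "roi", "rho"} <= set(assoc.columns)


class TestSparseness:
    def test_df_is_nrois_minus_two(self, rng):
        profile = pd.DataFrame({"roi": [f"r{i}" for i in range(8)],
                                "mean_gini": rng.random(8)})
        assoc = pd.DataFrame({"roi": [f"r{i}" for i in range(8)],
                              "rho": rng.random(8)})
        _, dof, _ = sparseness_association(profile, assoc)
        assert dof == 6

    def test_perfect_linear_relation(self):
        rho = np.array([-0.4, -0.2, 0.0, 0.3])
        profile = pd.DataFrame({"roi": list("abcd"),
                                "mean_gini": 0.5 + 0.2 * rho})
        assoc = pd.DataFrame({"roi": list("abcd"), "rho": rho})
        r, dof, p = sparseness_association(profile, assoc)
        assert r == pytest.approx(1.0)

    def test_too_few_rois_rejected(self):
        two = pd.DataFrame({"roi": ["a", "b"], "mean_gini": [0.1, 0.2],
                            "rho": [0.0, 0.1]})
        with pytest.raises(ValueError, match=">= 3"):
            sparseness_association(two[["roi", "mean_gini"]],
                                   two[["roi", "rho"]])

    def test_profile_values_in_unit_interval(self, rng):
        spec = SyntheticBetaSpec(n_images=12, n_subjects=2, repeats=2,
                                 rois=("V1", "PPA"), voxels_per_roi=8, seed=3)
        betas = gen_voxel_betas(spec, rng.standard_normal(12))
        profile = sparseness_profile(betas)
        assert ((profile["mean_gini"] >= 0) &
                (profile["mean_gini"] < 1)).all()


class TestVoxelwise:
    def _noise_table(self, rng, n_vox=40, n_img=30):
        return pd.DataFrame({
            "subject": "s1",
            "image": np.tile(np.arange(n_img), n_vox),
            "presentation": 1,
            "voxel": np.repeat(np.arange(n_vox), n_img),
            "beta": rng.standard_normal(n_vox * n_img),
        })

    def test_alpha_zero_flags_nothing(self, rng):
        table = self._noise_table(rng)
        vmap = voxelwise_map(table, pd.Series(rng.standard_normal(30)),
                             alpha=0.0)
        assert not vmap["flag"].any()

    def test_planted_voxels_detected(self, rng):
        n_img = 150
        ratings = rng.standard_normal(n_img)
        frames = [self._noise_table(rng, n_vox=20, n_img=n_img)]
        planted = pd.DataFrame({
            "subject": "s1",
            "image": np.tile(np.arange(n_img), 5),
            "presentation": 1,
            "voxel": np.repeat([f"sig{v}" for v in range(5)], n_img),
            "beta": np.tile(-ratings, 5) + rng.normal(0, 0.6, 5 * n_img),
        })
        table = pd.concat([*frames, planted], ignore_index=True)
        vmap = voxelwise_map(table, pd.Series(ratings), alpha=1e-4)
        sig = vmap[vmap["voxel"].astype(str).str.startswith("sig")]
        assert sig["flag"].mean() >= 0.9
        assert (sig["rho"] < 0).all()

    def test_false_positive_rate_near_alpha(self):
        rng = np.random.default_rng(77)
        table = self._noise_table(rng, n_vox=300, n_img=60)
        vmap = voxelwise_map(table, pd.Series(rng.standard_normal(60)),
                             alpha=0.05)
        assert 0.01 <= vmap["flag"].mean() <= 0.10

    def test_constant_voxel_flagged_undefined(self, rng):
        table = self._noise_table(rng, n_vox=3, n_img=10)
        table.loc[table["voxel"] == 0, "beta"] = 1.0
        vmap = voxelwise_map(table, pd.Series(rng.standard_normal(10)),
                             alpha=0.05)
        row = vmap[vmap["voxel"] == 0].iloc[0]
        assert row["undefined"] and not row["flag"]


class TestNiftiAdapters:
    def test_round_trip_matches_direct_table(self, rng):
        nib = pytest.importorskip("nibabel")
        shape = (4, 4, 3)
        labels = np.zeros(shape, dtype=np.int16)
        labels[0, 0, 0] = 1
        labels[1, 1, 1] = 1
        labels[2, 2, 2] = 2
        label_img = nib.Nifti1Image(labels, np.eye(4))
        legend = {"V1": 1, "PPA": 2}
        vols = {}
        raw = {}
        for img_id in ["a", "b", "c", "d", "e"]:
            data = rng.standard_normal(shape + (2,)).astype(np.float32)
            vols[img_id] = nib.Nifti1Image(data, np.eye(4))
            raw[img_id] = data
        table = nifti_to_beta_table(vols, label_img, legend, subject="s1")
        costs = aggregate_roi_costs(table)
        pres = costs.per_presentation.set_index(
            ["image", "presentation", "roi"])["cost"]
        want = raw["a"][0, 0, 0, 0] + raw["a"][1, 1, 1, 0]
        assert pres[("a", 1, "V1")] == pytest.approx(want, abs=1e-6)

        ratings = pd.Series(rng.standard_normal(5),
                            index=["a", "b", "c", "d", "e"])
        vmap = voxelwise_map(table, ratings, alpha=1.0)
        out = map_to_nifti(vmap, label_img, column="rho")
        arr = np.asanyarray(out.dataobj)
        got = arr[0, 0, 0]
        expect = vmap.set_index("voxel").loc["0_0_0", "rho"]
        assert got == pytest.approx(expect, abs=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        nib = pytest.importorskip("nibabel")
        labels = np.ones((3, 3, 3), dtype=np.int16)
        label_img = nib.Nifti1Image(labels, np.eye(4))
        bad = nib.Nifti1Image(np.zeros((2, 2, 2), dtype=np.float32),
                              np.eye(4))
        with pytest.raises(ValueError, match="shape"):
            nifti_to_beta_table({"x": bad}, label_img, {"V1": 1})
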