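"""SUV / SUVR outcomes, composites, and ROI extraction."""

import numpy as np
import pandas as pd
import pytest

from tspoquant.cohort import make_phantom, simulate_subject_tacs
from tspoquant.frames import make_frame_schedule
from tspoquant.semiquant import (
    composite_regions,
    compute_suv,
    compute_suvr,
    extract_regional_tacs,
    regional_outcomes,
)


class TestSuv:
    def test_balanced_normalisation(self, schedule):
        """1 kBq/ml with 70 MBq into 70 kg gives exactly SUV = 1 g/ml."""
        tac = np.ones(schedule.n_frames)
        assert compute_suv(tac, schedule, 70.0, 70.0) == pytest.approx(1.0)

    def test_linearity_in_dose_and_weight(self, schedule):
        tac = np.full(schedule.n_frames, 2.5)
        suv = compute_suv(tac, schedule, 300.0, 80.0)
        assert compute_suv(tac, schedule, 300.0, 160.0) == pytest.approx(2 * suv)
        assert compute_suv(tac, schedule, 600.0, 80.0) == pytest.approx(suv / 2)

    def test_window_contains_last_three_frames(self, schedule):
        """On the printed schedule the 60-90 min window holds exactly the
        last three 600 s frames (mid times 3900, 4500, 5100 s)."""
        sel = (schedule.mid >= 3600.0) & (schedule.mid < 5400.0)
        assert sel.sum() == 3
        assert np.allclose(schedule.mid[sel], [3900.0, 4500.0, 5100.0])
        tac = np.zeros(schedule.n_frames)
        tac[sel] = [1.0, 2.0, 3.0]
        assert compute_suv(tac, schedule, 70.0, 70.0) == pytest.approx(2.0)

    def test_midtime_vs_overlap_weighting(self, noiseless_tac, schedule):
        """On the printed schedule the two window conventions differ < 1%."""
        a = compute_suv(noiseless_tac, schedule, 337.0, 85.0, method="midtime")
        b = compute_suv(noiseless_tac, schedule, 337.0, 85.0, method="overlap")
        assert a == pytest.approx(b, rel=0.01)

    def test_invalid_inputs(self, schedule):
        tac = np.ones(schedule.n_frames)
        with pytest.raises(ValueError):
            compute_suv(tac, schedule, -1.0, 70.0)
        with pytest.raises(ValueError):
            compute_suv(tac, schedule, 300.0, 70.0, window_s=(6000.0, 7000.0))


class TestSuvr:
    def _outcomes(self, suvs):
        return pd.DataFrame({"region": list(suvs), "SUV": list(suvs.values())})

    def test_reference_ratio(self):
        out = compute_suvr(self._outcomes({"hippocampus": 0.9, "cerebellum": 0.9}))
        assert out.loc[out.region == "hippocampus", "SUVR"].iloc[0] == pytest.approx(1.0)
        assert out.loc[out.region == "cerebellum", "SUVR"].iloc[0] == 1.0

    def test_invariant_to_global_rescaling(self):
        a = compute_suvr(self._outcomes({"frontal": 0.8, "cerebellum": 1.0}))
        b = compute_suvr(
            pd.DataFrame({"region": ["frontal", "cerebellum"], "SUV": [0.8 * 3, 1.0 * 3]})
        )
        assert np.allclose(a["SUVR"], b["SUVR"])

    def test_region_order_irrelevant(self):
        a = compute_suvr(self._outcomes({"frontal": 0.7, "cerebellum": 0.9}))
        b = compute_suvr(self._outcomes({"cerebellum": 0.9, "frontal": 0.7}))
        merged = a.merge(b, on="region", suffixes=("_a", "_b"))
        assert np.allclose(merged["SUVR_a"], merged["SUVR_b"])

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            compute_suvr(self._outcomes({"frontal": 0.7, "cerebellum": 0.0}))


class TestComposites:
    def test_equal_volume_mean(self):
        out = pd.DataFrame(
            {"region": ["pallidum", "striatum", "thalamus", "cerebellum"],
             "SUV": [0.7, 0.8, 0.9, 1.0]}
        )
        out = compute_suvr(out)
        comp = composite_regions(out, volumes={r: 1.0 for r in out.region})
        sub = comp.loc[comp.region == "subcortex"].iloc[0]
        assert sub.SUV == pytest.approx(0.8)
        assert sub.SUVR == pytest.approx(0.8)

    def test_volume_weighted_mean(self):
        out = compute_suvr(
            pd.DataFrame({"region": ["pallidum", "striatum", "thalamus", "cerebellum"],
                          "SUV": [0.6, 0.6, 0.9, 1.0]})
        )
        comp = composite_regions(
            out, volumes={"pallidum": 1.0, "striatum": 1.0, "thalamus": 1.0,
                          "cerebellum": 1.0}
        )
        assert comp.loc[comp.region == "subcortex", "SUV"].iloc[0] == pytest.approx(0.7)
        comp2 = composite_regions(
            out, volumes={"pallidum": 2.0, "striatum": 2.0, "thalamus": 2.0,
                          "cerebellum": 1.0}
        )  # equal weights within members: same mean
        assert comp2.loc[comp2.region == "subcortex", "SUV"].iloc[0] == pytest.approx(0.7)

    def test_missing_member_skips_composite(self):
        out = compute_suvr(
            pd.DataFrame({"region": ["pallidum", "cerebellum"], "SUV": [0.7, 1.0]})
        )
        comp = composite_regions(out)
        assert "subcortex" not in set(comp.region)


class TestExtraction:
    def test_uniform_image(self):
        img = np.full((4, 4, 4, 5), 5.0)
        lab = np.zeros((4, 4, 4), dtype=int)
        lab[:2] = 1
        lab[2:] = 2
        tacs = extract_regional_tacs(img, lab, {1: "a", 2: "b"})
        assert np.allclose(tacs["a"], 5.0) and np.allclose(tacs["b"], 5.0)

    def test_two_voxel_mean(self):
        img = np.zeros((2, 1, 1, 3))
        img[0, 0, 0] = [2, 2, 2]
        img[1, 0, 0] = [4, 4, 4]
        lab = np.ones((2, 1, 1), dtype=int)
        tacs = extract_regional_tacs(img, lab, {1: "r"})
        assert np.allclose(tacs["r"], 3.0)

    def test_empty_region_skipped(self):
        img = np.ones((2, 2, 2, 3))
        lab = np.ones((2, 2, 2), dtype=int)
        tacs = extract_regional_tacs(img, lab, {1: "a", 9: "ghost"})
        assert "ghost" not in tacs

    def test_phantom_round_trip(self, region_truth, true_input, schedule):
        """TACs painted into a 4-D phantom come back exactly through the
        image-extraction layer."""
        tacs = simulate_subject_tacs(region_truth, true_input, schedule, 0.0, seed=0)
        by_region = {
            r: df.sort_values("frame_start_s")["concentration_kBq_per_ml"].to_numpy()
            for r, df in tacs.groupby("region")
        }
        img, lab, table = make_phantom(by_region)
        extracted = extract_regional_tacs(img, lab, table)
        for r, tac in by_region.items():
            assert np.allclose(extracted[r], tac)

    def test_nifti_round_trip(self, tmp_path):
        import nibabel as nib

        from tspoquant.semiquant import load_nifti_pair

        rng = np.random.default_rng(0)
        img = rng.random((3, 3, 3, 4))
        lab = rng.integers(0, 3, (3, 3, 3))
        nib.save(nib.Nifti1Image(img, np.eye(4)), tmp_path / "dyn.nii.gz")
        nib.save(nib.Nifti1Image(lab.astype(np.int16), np.eye(4)),
                 tmp_path / "lab.nii.gz")
        img2, lab2 = load_nifti_pair(tmp_path / "dyn.nii.gz", tmp_path / "lab.nii.gz")
        assert np.allclose(img2, img, atol=1e-6)
        assert np.array_equal(lab2, lab)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            extract_regional_tacs(np.ones((2, 2, 2, 3)), np.ones((3, 3, 3), int), {1: "a"})


class TestRegionalOutcomes:
    def test_two_route_composite_equivalence(self, region_truth, true_input, schedule):
        """Cortex built from member SUVs equals direct extraction over the
        union mask of the phantom (volume-equal voxels)."""
        from tspoquant.regions import CORTEX_MEMBERS

        tacs = simulate_subject_tacs(region_truth, true_input, schedule, 0.0, seed=0)
        by_region = {
            r: df.sort_values("frame_start_s")["concentration_kBq_per_ml"].to_numpy()
            for r, df in tacs.groupby("region")
        }
        img, lab, table = make_phantom(by_region)
        inv = {v: k for k, v in table.items()}
        union = np.isin(lab, [inv[m] for m in CORTEX_MEMBERS])
        union_tac = img[union].mean(axis=0)
        suv_union = compute_suv(union_tac, schedule, 337.0, 85.0)
        out = regional_outcomes(tacs, schedule, 337.0, 85.0,
                                composites=False)
        comp = composite_regions(out, volumes={r: 1.0 for r in by_region})
        suv_comp = comp.loc[comp.region == "cortex", "SUV"].iloc[0]
        assert suv_comp == pytest.approx(suv_union, abs=1e-12)
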