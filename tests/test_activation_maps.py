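"""Activation thresholds, binarization ties, eligibility, Wilcoxon exactness,
and activation-map export round-trips."""

import numpy as np
import pandas as pd
import pytest

from radiomap.activation_maps import (
    ActivationSummary,
    binarize,
    compare_groups,
    export_map,
    fit_threshold,
    summarize,
)
from radiomap.imaging_io import read_mask, write_mask
from radiomap.local_radiomics import label_patches, tile_patches

from conftest import make_mask
from oracles import brute_wilcoxon_two_sided


class TestThreshold:
    def test_odd_n_median(self):
        assert fit_threshold([1, 2, 3], "f").threshold == 2

    def test_even_n_average_of_middle_two(self):
        assert fit_threshold([1, 2, 3, 4], "f").threshold == 2.5

    def test_single_patient(self):
        assert fit_threshold([0.526], "f").threshold == 0.526

    def test_all_missing_raises(self):
        with pytest.raises(ValueError, match="no finite"):
            fit_threshold([np.nan, np.nan], "f")


def _patch_table(values, labels, pid="p1", feature="f"):
    return pd.DataFrame(
        {
            "patient_id": pid,
            "patch_id": range(len(values)),
            "label": labels,
            "feature": feature,
            "value": values,
        }
    )


class TestBinarizeAndSummarize:
    def test_strict_comparison_and_tie_rule(self):
        thr = fit_threshold([0.526], "f")
        table = _patch_table([0.60, 0.526, 0.40], ["rim", "rim", "rim"])
        flagged = binarize(table, thr)
        assert flagged["activated"].tolist() == [True, False, False]

    def test_counting_and_ratio(self):
        values = [1.0] * 10 + [0.0] * 10 + [1.0] * 5 + [0.0] * 5
        labels = ["rim"] * 20 + ["GTV"] * 10
        flagged = binarize(_patch_table(values, labels), fit_threshold([0.5], "f"))
        s = summarize(flagged, min_total=27, min_region=3)[0]
        assert s.ratio("rim") == 0.5 and s.ratio("GTV") == 0.5
        assert s.n_activated["rim"] + (s.n_total["rim"] - s.n_activated["rim"]) == s.n_total["rim"]
        assert s.eligible  # 30 total, 20/10 per region

    def test_eligibility_requires_27_total(self):
        flagged = binarize(
            _patch_table([1.0] * 26, ["rim"] * 13 + ["GTV"] * 13), fit_threshold([0.5], "f")
        )
        assert not summarize(flagged)[0].eligible

    def test_eligibility_requires_3_per_region(self):
        flagged = binarize(
            _patch_table([1.0] * 30, ["rim"] * 28 + ["GTV"] * 2), fit_threshold([0.5], "f")
        )
        assert not summarize(flagged)[0].eligible

    def test_sentinel_patches_excluded(self):
        flagged = binarize(
            _patch_table([1.0, np.nan, 0.0], ["rim"] * 3), fit_threshold([0.5], "f")
        )
        s = summarize(flagged)[0]
        assert s.n_total["rim"] == 2


def _summaries(ratios_a, ratios_b, region="rim"):
    out = []
    for label, ratios, tag in ((1, ratios_a, "a"), (0, ratios_b, "b")):
        for i, r in enumerate(ratios):
            out.append(
                ActivationSummary(
                    f"{tag}{i}", {region: int(round(r * 20))}, {region: 20}, True, label
                )
            )
    return out


class TestWilcoxon:
    def test_complete_separation_3v3_exact_p(self):
        res = compare_groups(_summaries([0.1, 0.2, 0.3], [0.7, 0.8, 0.9]), "rim")
        assert res["method"] == "exact"
        assert res["p_value"] == pytest.approx(0.1)  # 2/C(6,3)

    def test_exact_p_matches_enumeration_oracle(self, rng):
        """Exact p equals full rank-assignment enumeration for n,m <= 6."""
        for _ in range(10):
            n, m = rng.integers(2, 7, 2)
            vals = rng.permutation(21)[: n + m] / 20.0  # distinct values, no ties
            a, b = vals[:n], vals[n:]
            res = compare_groups(_summaries(a, b), "rim", exact_max_n=12)
            assert res["method"] == "exact"
            assert res["p_value"] == pytest.approx(brute_wilcoxon_two_sided(a, b))

    def test_identical_groups_p_one(self):
        res = compare_groups(_summaries([0.1, 0.5, 0.9], [0.1, 0.5, 0.9]), "rim")
        assert res["p_value"] == pytest.approx(1.0)

    def test_tie_falls_back_to_normal_approximation(self):
        res = compare_groups(_summaries([0.1, 0.5, 0.9], [0.1, 0.5, 0.9]), "rim")
        assert res["method"] == "normal_approximation"

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="empty comparison group"):
            compare_groups(_summaries([0.1], []), "rim")

    def test_ineligible_patients_excluded(self):
        summ = _summaries([0.1, 0.2, 0.3], [0.7, 0.8, 0.9])
        summ[0].eligible = False
        res = compare_groups(summ, "rim")
        assert res["n_group_a"] == 2


class TestExportMap:
    def test_round_trip_preserves_patch_labels(self, tmp_path, rng):
        roi = np.zeros((9, 6, 3), dtype=bool)
        roi[0:6, 0:6, 0:3] = True
        roi_m = make_mask(roi)
        gtv = np.zeros_like(roi)
        gtv[0:3, 0:3, 0:3] = True
        grid = tile_patches(roi_m)
        grid = label_patches(grid, roi_m, make_mask(gtv))
        labeled = grid.labeled()
        values = [1.0 if i % 2 else 0.0 for i in range(len(labeled))]
        table = pd.DataFrame(
            {
                "patient_id": "p",
                "patch_id": [p.patch_id for p in labeled],
                "label": [p.label for p in labeled],
                "feature": "f",
                "value": values,
            }
        )
        flagged = binarize(table, fit_threshold([0.5], "f"))
        vol = export_map(grid, flagged, roi_m)
        path = tmp_path / "map.nii.gz"
        write_mask(roi_m, path, data=vol)
        import nibabel as nib

        back = np.asanyarray(nib.load(str(path)).dataobj)
        np.testing.assert_array_equal(back, vol)
        # every labeled patch's voxels carry one uniform code
        from radiomap.local_radiomics import _patch_voxels

        for p in labeled:
            vox = _patch_voxels(p, grid, roi_m.data)
            codes = set(vol[vox[:, 0], vox[:, 1], vox[:, 2]].tolist())
            assert len(codes) == 1 and codes <= {1, 2}

    def test_mixed_patches_labeled_3_and_outside_ratio(self):
        roi = np.zeros((3, 3, 3), dtype=bool)
        roi[:] = True
        roi_m = make_mask(roi)
        gtv = np.zeros_like(roi)
        gtv.ravel()[:13] = True  # 13/27 -> mixed
        grid = tile_patches(roi_m)
        grid = label_patches(grid, roi_m, make_mask(gtv))
        flagged = pd.DataFrame(
            columns=["patient_id", "patch_id", "label", "feature", "value",
                     "valid", "activated"]
        )
        vol = export_map(grid, flagged, roi_m)
        assert np.all(vol == 3)
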