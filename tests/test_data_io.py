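"""Data model, TSV/NIfTI round trips, template construction."""

import numpy as np
import pytest

from structcov.data_io import (
    CohortTable,
    DataModelError,
    ROIMeasureTable,
    TemplateMask,
    VoxelMetricMatrix,
    WMHMask,
    average_hemispheres,
    build_template_mask,
    devectorize,
    read_cohort,
    read_roi_table,
    read_volume_stack,
    vectorize,
    wmh_burden,
    write_cohort,
    write_roi_table,
    write_volume_stack,
)


def toy_table(values, regions=("r1", "r2"), measure="thickness"):
    return ROIMeasureTable(
        measure,
        np.array([f"p{i}" for i in range(len(values))], dtype=object),
        np.array(regions, dtype=object),
        np.asarray(values, dtype=float),
    )


class TestROITables:
    def test_round_trip_identity(self, tmp_path):
        t = toy_table([[2.0, 3.0], [2.5, 3.5]])
        path = tmp_path / "t.tsv"
        write_roi_table(t, path)
        back = read_roi_table(path, "thickness")
        assert list(back.regions) == list(t.regions)
        assert list(back.participants) == list(t.participants)
        assert np.allclose(back.values, t.values)

    def test_large_synthetic_table_preserves_order(self, tmp_path, coupled):
        t = coupled["thickness"]
        path = tmp_path / "thick.tsv"
        write_roi_table(t, path)
        back = read_roi_table(path, "thickness")
        assert back.values.shape == (186, 34)
        assert list(back.regions) == list(t.regions)
        assert np.allclose(back.values, t.values, atol=1e-9)

    def test_negative_thickness_rejected(self):
        with pytest.raises(DataModelError, match="strictly positive"):
            toy_table([[2.0, -0.1], [2.5, 3.5]])

    def test_non_numeric_cell_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("participant_id\tr1\tr2\np0\t2.0\toops\n")
        with pytest.raises(DataModelError, match="p0.*r2"):
            read_roi_table(path, "thickness")

    def test_duplicate_regions_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("participant_id\tr1\tr1\np0\t2.0\t3.0\n")
        with pytest.raises(DataModelError, match="duplicate"):
            read_roi_table(path, "thickness")

    def test_cohort_round_trip(self, tmp_path):
        c = CohortTable(
            np.array(["a", "b"], dtype=object), [30.0, 70.0], [0, 1],
            np.array(["g1", "g2"], dtype=object),
        )
        path = tmp_path / "cohort.tsv"
        write_cohort(c, path)
        back = read_cohort(path)
        assert np.allclose(back.age, c.age)
        assert np.array_equal(back.sex, c.sex)


class TestTemplateMask:
    def test_one_low_participant_excludes_voxel(self):
        stack = np.full((3, 2, 2, 2), 0.5)
        stack[1, 0, 0, 0] = 0.10
        tpl = build_template_mask(stack)
        assert not tpl.mask[0, 0, 0]
        assert tpl.n_voxels == 7

    def test_uniform_pass_full_grid(self):
        stack = np.full((4, 2, 3, 2), 0.16)
        tpl = build_template_mask(stack)
        assert tpl.n_voxels == 12

    def test_boundary_value_excluded_strictly(self):
        # FA exactly 0.15 in one participant -> excluded (strict >)
        stack = np.full((2, 2, 1, 1), 0.5)
        stack[0, 1, 0, 0] = 0.15
        tpl = build_template_mask(stack)
        assert tpl.mask[0, 0, 0] and not tpl.mask[1, 0, 0]

    def test_monotone_in_threshold(self, rng):
        stack = rng.uniform(0, 1, size=(5, 4, 4, 3))
        masks = [build_template_mask(stack, th).mask for th in (0.1, 0.3, 0.5)]
        for lo, hi in zip(masks, masks[1:]):
            # raising the threshold never adds a voxel: hi is a subset of lo
            assert not np.any(hi & ~lo)

    def test_empty_mask_warns(self):
        stack = np.full((2, 2, 2, 2), 0.05)
        with pytest.warns(UserWarning, match="empty"):
            tpl = build_template_mask(stack)
        assert tpl.n_voxels == 0


class TestVectorize:
    def test_full_mask_enumeration_order(self):
        # 2x2x1 grid, row-major (x, y, z): columns follow flat C order
        vol = np.arange(4.0).reshape(1, 2, 2, 1) / 10 + 0.1
        tpl = TemplateMask((2, 2, 1), np.ones((2, 2, 1), bool))
        m = vectorize(vol, tpl, "FA", np.array(["p0"], dtype=object))
        assert np.allclose(m.values[0], [0.1, 0.2, 0.3, 0.4])

    def test_round_trip_inside_mask(self, rng):
        vols = rng.uniform(0.2, 0.9, size=(3, 4, 3, 2))
        mask = rng.uniform(size=(4, 3, 2)) > 0.4
        tpl = TemplateMask((4, 3, 2), mask)
        m = vectorize(vols, tpl, "FA", np.array(["a", "b", "c"], dtype=object))
        back = devectorize(m)
        assert np.array_equal(back[:, mask], vols[:, mask])
        assert np.all(back[:, ~mask] == 0.0)

    def test_column_count_equals_mask_size(self, rng):
        mask = np.zeros((4, 4, 2), bool)
        mask[:2] = True
        tpl = TemplateMask((4, 4, 2), mask)
        m = vectorize(np.full((2, 4, 4, 2), 0.5), tpl, "FA",
                      np.array(["a", "b"], dtype=object))
        assert m.values.shape == (2, 16)

    def test_grid_mismatch_rejected(self):
        tpl = TemplateMask((2, 2, 2), np.ones((2, 2, 2), bool))
        with pytest.raises(DataModelError, match="does not match"):
            vectorize(np.full((1, 3, 2, 2), 0.5), tpl, "FA",
                      np.array(["a"], dtype=object))

    def test_nifti_stack_round_trip(self, tmp_path, rng):
        vols = rng.uniform(0, 1, size=(3, 4, 5, 2))
        path = tmp_path / "stack.nii.gz"
        write_volume_stack(vols, path)
        assert np.allclose(read_volume_stack(path), vols)


class TestHemisphereAveraging:
    def test_pair_means(self):
        t = toy_table(
            [[2.0, 2.0, 1.0, 3.0]],
            regions=("lh_a", "rh_a", "lh_b", "rh_b"),
        )
        av = average_hemispheres(t)
        assert list(av.regions) == ["a", "b"]
        assert np.allclose(av.values, [[2.0, 2.0]])

    def test_brute_force_pairwise_mean(self, rng):
        names = [f"reg{j}" for j in range(34)]
        regions = [f"lh_{n}" for n in names] + [f"rh_{n}" for n in names]
        vals = rng.uniform(1.5, 3.5, size=(20, 68))
        t = toy_table(vals, regions=tuple(regions))
        av = average_hemispheres(t)
        # oracle: loop over pairs explicitly
        for j, n in enumerate(names):
            expect = (vals[:, regions.index(f"lh_{n}")]
                      + vals[:, regions.index(f"rh_{n}")]) / 2
            assert np.allclose(av.values[:, list(av.regions).index(n)], expect)

    def test_missing_partner_listed(self):
        t = toy_table([[2.0, 2.0, 1.0]], regions=("lh_a", "rh_a", "lh_b"))
        with pytest.raises(DataModelError, match="b"):
            average_hemispheres(t)


class TestWMHBurden:
    def test_reported_template_burden(self):
        # 541 flagged of 138,283 template voxels -> 0.39%
        tpl = TemplateMask((138283, 1, 1), np.ones((138283, 1, 1), bool))
        wmh = WMHMask({"median_participant": np.arange(541)}, 138283)
        burden = wmh_burden(wmh, tpl)
        assert round(float(burden["median_participant"]), 2) == 0.39

    def test_empty_and_toy_fractions(self):
        tpl = TemplateMask((4, 1, 1), np.ones((4, 1, 1), bool))
        burden = wmh_burden(WMHMask({"a": [], "b": [2]}, 4), tpl)
        assert burden["a"] == 0.0
        assert burden["b"] == 25.0
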