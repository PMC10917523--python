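import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from conftest import single_cell_labels
from magicquant.image_io import Projection2D
from magicquant.spgfp import mito_mask, quantify_image, spgfp_per_cell
from magicquant.stats import PairingError, summarize_groups
from magicquant.synth import SceneSpec, generate_scene


def square_cell(shape=(12, 12), top=2, left=2, size=8):
    mask = np.zeros(shape, dtype=bool)
    mask[top : top + size, left : left + size] = True
    return mask


class TestMitoMask:
    def test_five_percent_of_cell_max(self):
        cell = square_cell()
        labels = single_cell_labels(cell)
        marker = np.zeros(cell.shape)
        marker[cell] = 5.0
        marker[3, 3] = 200.0
        marker[4, 4] = 9.9  # just below 5% of 200
        marker[5, 5] = 10.0  # exactly at threshold -> included
        mask = mito_mask(1, labels, Projection2D(marker), threshold_frac=0.05)
        assert mask[3, 3] and mask[5, 5]
        assert not mask[4, 4]

    def test_uniform_marker_whole_cell(self):
        cell = square_cell()
        labels = single_cell_labels(cell)
        marker = np.where(cell, 50.0, 0.0)
        mask = mito_mask(1, labels, Projection2D(marker))
        np.testing.assert_array_equal(mask, cell)

    def test_no_signal_empty_mask(self):
        cell = square_cell()
        labels = single_cell_labels(cell)
        mask = mito_mask(1, labels, Projection2D(np.zeros(cell.shape)))
        assert not mask.any()

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            cell = square_cell()
            labels = single_cell_labels(cell)
            marker = rng.uniform(0, 100, cell.shape)
            mask = mito_mask(1, labels, Projection2D(marker), threshold_frac=0.05)
            cmax = marker[cell].max()
            for y in range(cell.shape[0]):
                for x in range(cell.shape[1]):
                    expected = cell[y, x] and marker[y, x] >= 0.05 * cmax
                    assert mask[y, x] == expected

    @given(frac_lo=st.floats(0.01, 0.5), frac_hi=st.floats(0.5, 0.99))
    def test_threshold_monotonicity(self, frac_lo, frac_hi):
        rng = np.random.default_rng(3)
        cell = square_cell()
        labels = single_cell_labels(cell)
        marker = Projection2D(rng.uniform(0, 10, cell.shape))
        lo = mito_mask(1, labels, marker, threshold_frac=frac_lo)
        hi = mito_mask(1, labels, marker, threshold_frac=frac_hi)
        assert hi.sum() <= lo.sum()
        assert not (hi & ~lo).any()

    def test_per_image_max_option(self):
        cell = square_cell()
        labels = single_cell_labels(cell)
        marker = np.where(cell, 6.0, 0.0)
        marker[0, 0] = 1000.0  # outside the cell; dominates the image max
        in_cell = mito_mask(1, labels, Projection2D(marker), 0.05, per_image_max=False)
        global_ref = mito_mask(1, labels, Projection2D(marker), 0.05, per_image_max=True)
        assert in_cell.sum() == cell.sum()
        assert global_ref.sum() == 0  # 5% of 1000 exceeds every in-cell value


class TestSpGFPPerCell:
    def test_median_of_three(self):
        cell = square_cell()
        labels = single_cell_labels(cell)
        gfp = np.zeros(cell.shape)
        mito = np.zeros(cell.shape, dtype=bool)
        for value, pos in zip((1.0, 2.0, 3.0), ((3, 3), (4, 4), (5, 5))):
            gfp[pos] = value
            mito[pos] = True
        m = spgfp_per_cell(1, labels, Projection2D(gfp), mito)
        assert m.spgfp_median == 2.0
        assert m.mito_area_px == 3

    def test_even_count_median_interpolates(self):
        cell = square_cell()
        labels = single_cell_labels(cell)
        gfp = np.zeros(cell.shape)
        mito = np.zeros(cell.shape, dtype=bool)
        for value, pos in zip((1.0, 2.0, 10.0, 20.0), ((3, 3), (3, 4), (4, 3), (4, 4))):
            gfp[pos] = value
            mito[pos] = True
        m = spgfp_per_cell(1, labels, Projection2D(gfp), mito)
        assert m.spgfp_median == 6.0

    def test_mask_locality(self):
        rng = np.random.default_rng(5)
        cell = square_cell()
        labels = single_cell_labels(cell)
        gfp = rng.uniform(0, 10, cell.shape)
        mito = cell & (rng.uniform(size=cell.shape) < 0.4)
        before = spgfp_per_cell(1, labels, Projection2D(gfp), mito).spgfp_median
        gfp2 = gfp.copy()
        gfp2[~mito] += 100.0  # touch only pixels outside the mask
        after = spgfp_per_cell(1, labels, Projection2D(gfp2), mito).spgfp_median
        assert before == after

    def test_shift_equivariance(self):
        rng = np.random.default_rng(6)
        cell = square_cell()
        labels = single_cell_labels(cell)
        gfp = rng.uniform(0, 10, cell.shape)
        mito = cell & (rng.uniform(size=cell.shape) < 0.5)
        base = spgfp_per_cell(1, labels, Projection2D(gfp), mito).spgfp_median
        shifted_img = gfp.copy()
        shifted_img[mito] += 7.5
        shifted = spgfp_per_cell(1, labels, Projection2D(shifted_img), mito).spgfp_median
        assert shifted == pytest.approx(base + 7.5, rel=1e-12)

    def test_empty_mask_excluded_not_zero(self):
        cell = square_cell()
        labels = single_cell_labels(cell)
        m = spgfp_per_cell(1, labels, Projection2D(np.ones(cell.shape)), np.zeros_like(cell))
        assert m.excluded
        assert np.isnan(m.spgfp_median)
        assert "mitochondrial" in m.reason

    def test_matches_sort_and_pick_oracle(self):
        rng = np.random.default_rng(7)
        cell = square_cell()
        labels = single_cell_labels(cell)
        for _ in range(50):
            gfp = rng.uniform(0, 100, cell.shape)
            mito = cell & (rng.uniform(size=cell.shape) < 0.5)
            if not mito.any():
                continue
            m = spgfp_per_cell(1, labels, Projection2D(gfp), mito)
            vals = np.sort(gfp[mito])
            n = vals.size
            oracle = vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
            assert m.spgfp_median == oracle


class TestSummarizeGroups:
    def test_identical_groups_t0_p1(self):
        df = pd.DataFrame(
            {
                "group": ["a"] * 3 + ["b"] * 3,
                "replicate": [1, 2, 3, 1, 2, 3],
                "value": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
            }
        )
        _, tests = summarize_groups(df)
        assert tests[0].statistic == pytest.approx(0.0)
        assert tests[0].pvalue == pytest.approx(1.0)

    def test_welch_matches_textbook_formula(self):
        df = pd.DataFrame(
            {
                "group": ["a"] * 3 + ["b"] * 3,
                "replicate": [1, 2, 3] * 2,
                "value": [1.0, 2.0, 3.0, 2.0, 3.0, 4.0],
            }
        )
        _, tests = summarize_groups(df, test="welch")
        # hand-computed Welch statistic for replicate means {1,2,3} vs {2,3,4}
        va, vb, n = 1.0, 1.0, 3
        t_hand = (2.0 - 3.0) / np.sqrt(va / n + vb / n)
        df_hand = (va / n + vb / n) ** 2 / (
            (va / n) ** 2 / (n - 1) + (vb / n) ** 2 / (n - 1)
        )
        p_hand = 2 * sps.t.sf(abs(t_hand), df_hand)
        assert tests[0].statistic == pytest.approx(t_hand, rel=1e-12)
        assert tests[0].pvalue == pytest.approx(p_hand, rel=1e-12)

    def test_paired_requires_matching_replicates(self):
        df = pd.DataFrame(
            {
                "group": ["a", "a", "b", "b"],
                "replicate": [1, 2, 1, 3],
                "value": [1.0, 2.0, 1.5, 2.5],
            }
        )
        with pytest.raises(PairingError):
            summarize_groups(df, test="paired")

    def test_paired_on_matching_replicates(self):
        df = pd.DataFrame(
            {
                "group": ["a"] * 3 + ["b"] * 3,
                "replicate": [1, 2, 3] * 2,
                "value": [1.0, 2.0, 3.0, 2.0, 3.1, 4.2],
            }
        )
        _, tests = summarize_groups(df, test="paired")
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 3.1, 4.2])
        ref = sps.ttest_rel(a, b)
        assert tests[0].statistic == pytest.approx(float(ref.statistic))
        assert tests[0].pvalue == pytest.approx(float(ref.pvalue))

    def test_relative_values_use_reference_grand_mean(self):
        df = pd.DataFrame(
            {
                "group": ["ctrl"] * 2 + ["mut"] * 2,
                "replicate": [1, 2, 1, 2],
                "value": [10.0, 10.0, 25.0, 15.0],
            }
        )
        summaries, _ = summarize_groups(df, reference="ctrl")
        by = {s.group: s for s in summaries}
        assert by["ctrl"].relative_value == pytest.approx(1.0)
        assert by["mut"].relative_value == pytest.approx(2.0)

    def test_replicate_means_not_pooled_cells(self):
        # one replicate with many cells must count once, not per cell
        df = pd.DataFrame(
            {
                "group": ["a"] * 4 + ["b"] * 2,
                "replicate": [1, 1, 1, 2, 1, 2],
                "value": [0.0, 0.0, 30.0, 20.0, 5.0, 15.0],
            }
        )
        summaries, _ = summarize_groups(df)
        by = {s.group: s for s in summaries}
        assert by["a"].n_replicates == 2
        assert by["a"].grand_mean == pytest.approx((10.0 + 20.0) / 2)


class TestAssayMonotonicity:
    def test_group_mean_monotone_in_enrichment(self):
        means = []
        for enr in (1.0, 2.0, 3.0):
            scene = generate_scene(
                SceneSpec(n_cells=8, reporter_mito_enrichment=enr, seed=21)
            )
            table, _ = quantify_image(scene.gfp_stack, scene.marker_stack)
            means.append(table.loc[~table["excluded"], "spgfp_median"].mean())
        assert means[0] < means[1] < means[2]
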