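"""Connected components, Dmax, lesion matching, Dice, agreement and ICC."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lowfield import (
    connected_components,
    dice,
    dmax,
    icc_2_1,
    match_lesions,
    study_summary,
    tpr_fdr_sweep,
    volume_agreement,
)
from tests.conftest import make_volume

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def flood_fill_components(mask, connectivity):
    """Brute-force labelling by BFS flood fill."""
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((di, dj, dk))
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for seed in np.argwhere(mask):
        seed = tuple(seed)
        if labels[seed]:
            continue
        current += 1
        queue = [seed]
        labels[seed] = current
        while queue:
            i, j, k = queue.pop()
            for di, dj, dk in offsets:
                n = (i + di, j + dj, k + dk)
                if all(0 <= n[a] < mask.shape[a] for a in range(3)) and mask[n] and not labels[n]:
                    labels[n] = current
                    queue.append(n)
    return labels, current


def dmax_oracle(voxels, spacing):
    """O(n^2) all-pairs scan per plane family."""
    voxels = np.asarray(voxels, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    best = 0.0
    for ax in range(3):
        ip = [a for a in range(3) if a != ax]
        pitch = max(spacing[ip])
        for level in set(voxels[:, ax]):
            pts = voxels[voxels[:, ax] == level][:, ip] * spacing[ip]
            span = 0.0
            for a in range(len(pts)):
                for b in range(a + 1, len(pts)):
                    span = max(span, float(np.linalg.norm(pts[a] - pts[b])))
            best = max(best, span + pitch)
    return best


def match_oracle(ref, pred, connectivity):
    ref_lab, n_ref = flood_fill_components(ref, connectivity)
    pred_lab, n_pred = flood_fill_components(pred, connectivity)
    tp = sum(1 for l in range(1, n_ref + 1) if np.any(pred[ref_lab == l]))
    fp = sum(1 for l in range(1, n_pred + 1) if not np.any(ref[pred_lab == l]))
    tpr = tp / n_ref if n_ref else float("nan")
    fdr = fp / n_pred if n_pred else float("nan")
    return n_ref, n_pred, tpr, fdr


# ---------------------------------------------------------------------------


class TestConnectedComponents:
    def test_two_cubes_arithmetic(self):
        data = np.zeros((12, 12, 12))
        data[1:4, 1:4, 1:4] = 1
        data[7:10, 7:10, 7:10] = 1
        table = connected_components(make_volume(data))
        assert len(table) == 2
        assert list(table["voxel_count"]) == [27, 27]
        assert table["volume_ml"].tolist() == pytest.approx([0.027, 0.027])

    def test_diagonal_touch_connectivity(self):
        data = np.zeros((4, 4, 4))
        data[0, 0, 0] = 1
        data[1, 1, 1] = 1
        assert len(connected_components(make_volume(data), connectivity=26)) == 1
        assert len(connected_components(make_volume(data), connectivity=6)) == 2

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(connectivity)
        for _ in range(10):
            mask = rng.random((16, 16, 16)) < 0.18
            table = connected_components(make_volume(mask.astype(float)), connectivity)
            _, n = flood_fill_components(mask, connectivity)
            assert len(table) == n

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            connected_components(make_volume(np.full((4, 4, 4), 0.5)))

    def test_mean_intensity_column(self):
        data = np.zeros((6, 6, 6))
        data[1:3, 1, 1] = 1
        intens = make_volume(np.full((6, 6, 6), 2.5))
        table = connected_components(make_volume(data), intensity_image=intens)
        assert table["mean_norm_intensity"].iloc[0] == 2.5


class TestDmax:
    def test_single_voxel_has_pitch_diameter(self):
        assert dmax(np.array([[3, 3, 3]]), (1, 1, 1)) == 1.0

    def test_rod_diameter(self):
        voxels = np.array([[1, j, 1] for j in range(5)])
        assert dmax(voxels, (1, 1, 1)) == 5.0

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(0)
        for spacing in ((1, 1, 1), (1.6, 1.6, 5.0)):
            for _ in range(8):
                n = rng.integers(1, 200)
                voxels = np.unique(rng.integers(0, 12, size=(n, 3)), axis=0)
                assert dmax(voxels, spacing) == pytest.approx(
                    dmax_oracle(voxels, spacing), abs=1e-12
                )

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            dmax(np.empty((0, 3)), (1, 1, 1))


class TestMatchLesions:
    def test_perfect_prediction(self):
        data = np.zeros((8, 8, 8))
        data[1:3, 1:3, 1:3] = 1
        ref = make_volume(data)
        m = match_lesions(ref, ref.like(data.copy()))
        assert m.tpr == 1.0 and m.fdr == 0.0 and m.fdr_defined

    def test_empty_prediction_flags_fdr(self):
        data = np.zeros((10, 10, 10))
        for c in (1, 4, 7):
            data[c, c, c] = 1
        m = match_lesions(make_volume(data), make_volume(np.zeros_like(data)))
        assert m.tpr == 0.0
        assert np.isnan(m.fdr) and not m.fdr_defined

    def test_grid_mismatch_instructs_resampling(self):
        a = make_volume(np.zeros((6, 6, 6)))
        b = make_volume(np.zeros((6, 6, 6)), spacing=(2, 2, 2))
        with pytest.raises(ValueError, match="resample"):
            match_lesions(a, b)

    def test_matches_bruteforce_on_random_pairs(self):
        rng = np.random.default_rng(50)
        for _ in range(50):
            ref = rng.random((16, 16, 16)) < 0.12
            pred = rng.random((16, 16, 16)) < 0.12
            m = match_lesions(make_volume(ref.astype(float)), make_volume(pred.astype(float)))
            n_ref, n_pred, tpr, fdr = match_oracle(ref, pred, 26)
            assert (m.n_ref, m.n_pred) == (n_ref, n_pred)
            if n_ref:
                assert m.tpr == pytest.approx(tpr)
            if n_pred:
                assert m.fdr == pytest.approx(fdr)

    def test_nested_prediction_has_zero_fdr(self):
        rng = np.random.default_rng(7)
        ref = rng.random((14, 14, 14)) < 0.2
        pred = ref & (rng.random((14, 14, 14)) < 0.6)
        m = match_lesions(make_volume(ref.astype(float)), make_volume(pred.astype(float)))
        if m.n_pred:
            assert m.fdr == 0.0


class TestSweep:
    @staticmethod
    def _tables_and_match():
        ref = np.zeros((16, 16, 16))
        ref[1:5, 1:5, 1:5] = 1  # 64 voxels = 0.064 ml
        ref[10:12, 10:12, 10:12] = 1  # 8 voxels
        pred = np.zeros_like(ref)
        pred[2:5, 2:5, 2:5] = 1  # overlaps the big one
        pred[13, 1, 1] = 1  # false positive
        rv, pv = make_volume(ref), make_volume(pred)
        rt = connected_components(rv)
        pt = connected_components(pv)
        return rt, pt, match_lesions(rv, pv)

    def test_noop_threshold_reproduces_unthresholded(self):
        rt, pt, m = self._tables_and_match()
        curve = tpr_fdr_sweep(rt, pt, m, axis="size_ml", thresholds=[-1.0])
        assert curve.loc[0, "tpr"] == pytest.approx(m.tpr)
        assert curve.loc[0, "fdr"] == pytest.approx(m.fdr)

    def test_row_count_and_flags(self):
        rt, pt, m = self._tables_and_match()
        thresholds = [0.0, 0.01, 0.05, 10.0]
        curve = tpr_fdr_sweep(rt, pt, m, axis="size_ml", thresholds=thresholds)
        assert len(curve) == len(thresholds)
        assert bool(curve.iloc[-1]["empty_ref"]) and bool(curve.iloc[-1]["empty_pred"])

    def test_large_lesions_all_detected(self):
        rt, pt, m = self._tables_and_match()
        curve = tpr_fdr_sweep(rt, pt, m, axis="size_ml", thresholds=[0.02])
        # only the 0.064 ml lesion survives the filter, and it is detected
        assert curve.loc[0, "tpr"] == 1.0
        assert curve.loc[0, "fdr"] == 0.0


class TestDice:
    def test_identical_masks(self):
        data = np.zeros((6, 6, 6))
        data[2:4, 2:4, 2:4] = 1
        v = make_volume(data)
        assert dice(v, v.like(data.copy())).value == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((6, 6, 6))
        b = np.zeros((6, 6, 6))
        a[0, 0, 0] = 1
        b[5, 5, 5] = 1
        assert dice(make_volume(a), make_volume(b)).value == 0.0

    def test_arithmetic_oracle(self):
        a = np.zeros((10, 10, 10))
        b = np.zeros((10, 10, 10))
        a.ravel()[:100] = 1
        b.ravel()[75:125] = 1  # |B| = 50, overlap = 25
        d = dice(make_volume(a), make_volume(b))
        assert d.value == pytest.approx(2 * 25 / 150)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = make_volume((rng.random((8, 8, 8)) < 0.3).astype(float))
            b = make_volume((rng.random((8, 8, 8)) < 0.3).astype(float))
            dab, dba = dice(a, b), dice(b, a)
            assert dab.value == dba.value
            assert 0 <= dab.value <= 1

    def test_both_empty_flagged(self):
        v = make_volume(np.zeros((4, 4, 4)))
        d = dice(v, v.like(np.zeros((4, 4, 4))))
        assert d.value == 1.0 and d.both_empty


class TestVolumeAgreement:
    def test_identical_series_rejected_zero_variance_guard(self):
        with pytest.raises(ValueError, match="variance"):
            volume_agreement([1, 1, 1], [1, 1, 1])

    def test_identical_pairs_collapse(self):
        stats_ = volume_agreement([1, 2, 3, 4], [1, 2, 3, 4])
        assert stats_.bias_ml == 0.0
        assert stats_.loa_low_ml == stats_.loa_high_ml == 0.0
        assert not stats_.prop_bias_defined

    def test_constant_offset(self):
        stats_ = volume_agreement([1, 2, 3], [2, 3, 4])
        assert stats_.bias_ml == pytest.approx(1.0)
        assert stats_.sd_diff_ml == pytest.approx(0.0)

    def test_proportional_error_gives_negative_trend(self):
        ref = np.linspace(1, 30, 15)
        pred = 0.8 * ref + 2.0  # over-measures small, under-measures large
        stats_ = volume_agreement(ref, pred)
        assert stats_.prop_bias_r < 0
        assert stats_.pearson_r > 0.99

    def test_sem_modes(self):
        ref = np.array([1.0, 2, 3, 4, 6])
        pred = ref + np.array([0.1, -0.2, 0.3, 0.0, -0.1])
        a = volume_agreement(ref, pred, sem_mode="sd_over_sqrt2")
        b = volume_agreement(ref, pred, sem_mode="sd")
        assert a.sem_ml == pytest.approx(b.sem_ml / np.sqrt(2))

    def test_loa_ordering(self):
        rng = np.random.default_rng(11)
        ref = rng.uniform(1, 20, 12)
        pred = ref + rng.normal(0, 1.5, 12)
        s = volume_agreement(ref, pred)
        assert s.loa_low_ml < s.bias_ml < s.loa_high_ml


def icc_oracle(x):
    """From-scratch two-way ANOVA mean squares for ICC(2,1)."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
    sse = ((x - x.mean(1, keepdims=True) - x.mean(0, keepdims=True) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_duplicated_rater_gives_one(self):
        col = np.arange(10, dtype=float)
        res = icc_2_1(np.column_stack([col, col]))
        assert res.icc == 1.0

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            x = rng.normal(size=(10, 2)) + rng.normal(size=(10, 1))
            assert icc_2_1(x).icc == pytest.approx(icc_oracle(x), abs=1e-10)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(100)
        x = rng.normal(size=(100, 2))
        assert abs(icc_2_1(x).icc) < 0.2

    def test_matches_pingouin_value_and_ci(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(33)
        x = rng.normal(size=(12, 3)) + 2.0 * rng.normal(size=(12, 1))
        res = icc_2_1(x)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": x.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        # two-way random, single measure, absolute agreement
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        assert res.icc == pytest.approx(row["ICC"], abs=1e-8)
        assert res.ci_low == pytest.approx(row[ci_col][0], abs=0.011)
        assert res.ci_high == pytest.approx(row[ci_col][1], abs=0.011)

    def test_missing_cells_rejected(self):
        x = np.ones((5, 2))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            icc_2_1(x)
        with pytest.raises(ValueError, match=">= 3 subjects"):
            icc_2_1(np.ones((2, 2)))


class TestStudySummary:
    def test_single_lesion_extrema_coincide(self):
        data = np.zeros((8, 8, 8))
        data[2:4, 2:4, 2:4] = 1
        t = connected_components(make_volume(data))
        s = study_summary(t, t)
        assert s["smallest_dmax_ref_mm"] == s["largest_dmax_ref_mm"]

    def test_totals_are_sums(self):
        data = np.zeros((12, 12, 12))
        data[1:3, 1:3, 1:3] = 1
        data[8:11, 8:11, 8:11] = 1
        t = connected_components(make_volume(data))
        s = study_summary(t, t)
        assert s["total_vol_ref_ml"] == pytest.approx(t["volume_ml"].sum())

    def test_empty_reference_flagged(self):
        empty = connected_components(make_volume(np.zeros((5, 5, 5))))
        s = study_summary(empty, empty)
        assert s["ref_empty"]
        assert np.isnan(s["smallest_dmax_ref_mm"])

    def test_detection_flag_from_match(self):
        data = np.zeros((8, 8, 8))
        data[2:4, 2:4, 2:4] = 1
        v = make_volume(data)
        t = connected_components(v)
        m = match_lesions(v, v.like(data.copy()))
        assert study_summary(t, t, m)["any_lesion_detected"]
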