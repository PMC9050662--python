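"""Weighted re-binning, normalisation, binarization, SMC filter and
pseudo-bulk RT."""

import numpy as np
import pandas as pd
import pytest

from scrt import rt
from scrt._utils import weighted_median
from scrt.rt import RTMatrix


def _rt_bins(n=1, width=200_000):
    starts = np.arange(n) * width
    return pd.DataFrame({"chrom": "chr1", "start": starts,
                         "end": starts + width})


def _segs(rows):
    df = pd.DataFrame(rows, columns=["start", "end", "cn"])
    df["chrom"] = "chr1"
    return df[["chrom", "start", "end", "cn"]]


class TestWeightedMedianRebin:
    def test_bin_inside_single_segment(self):
        segs = _segs([(0, 500_000, 3)])
        assert rt.rebin_cn(segs, _rt_bins())[0] == 3

    def test_majority_overlap_wins(self):
        segs = _segs([(0, 150_000, 2), (150_000, 500_000, 4)])
        assert rt.rebin_cn(segs, _rt_bins())[0] == 2

    def test_even_split_takes_mean_of_straddling_values(self):
        segs = _segs([(0, 100_000, 2), (100_000, 500_000, 4)])
        assert rt.rebin_cn(segs, _rt_bins())[0] == 3

    def test_uncovered_bin_missing(self):
        segs = _segs([(0, 100_000, 2)])
        out = rt.rebin_cn(segs, _rt_bins(n=3))
        assert np.isnan(out[1]) and np.isnan(out[2])

    def test_weighted_median_helper_validates(self):
        with pytest.raises(ValueError):
            weighted_median([], [])
        assert weighted_median([5], [10]) == 5


class TestReferenceAndNormalisation:
    def test_identical_cells_reference_equals_any_cell(self):
        m = pd.DataFrame([[2, 3, 4]] * 5, columns=list("abc"))
        assert rt.g1g2_reference(m).tolist() == [2, 3, 4]

    def test_single_outlier_does_not_move_median(self):
        m = pd.DataFrame([[2]] * 11, columns=["a"])
        m.iloc[0, 0] = 8
        assert rt.g1g2_reference(m)["a"] == 2

    def test_zero_bins_masked(self):
        m = pd.DataFrame([[0, 2]] * 3, columns=["a", "b"])
        cng = rt.g1g2_reference(m)
        assert np.isnan(cng["a"]) and cng["b"] == 2

    @pytest.mark.parametrize("cn200,cng,expected", [
        (2.0, 2.0, 0.0),
        (4.0, 2.0, 1.0),
        (3.0, 2.0, np.log2(1.5)),
    ])
    def test_log2_ratio(self, cn200, cng, expected):
        row = pd.Series([cn200], index=["a"])
        ref = pd.Series([cng], index=["a"])
        assert rt.normalize_s_cell(row, ref)["a"] \
            == pytest.approx(expected)


class TestBinarize:
    def test_binary_input_reproduced_with_zero_loss(self):
        row = pd.Series([0.0, 1.0, 0.0, 1.0])
        binary, th, eps = rt.binarize(row)
        assert binary.tolist() == [0, 1, 0, 1]
        assert eps == pytest.approx(0.0)

    def test_four_point_example_matches_grid_oracle(self):
        row = pd.Series([0.1, 0.45, 0.55, 0.9])
        binary, th, eps = rt.binarize(row)
        assert binary.tolist() == [0, 0, 1, 1]
        # exhaustive oracle on a 1e-3 grid
        v = row.to_numpy()
        grid = np.linspace(0, 1, 1001)
        losses = [(np.where(v >= t, (v - 1) ** 2, v ** 2)).sum()
                  for t in grid]
        assert eps == pytest.approx(min(losses), abs=1e-9)

    def test_all_negative_goes_all_zero(self):
        binary, th, _ = rt.binarize(pd.Series([-0.4, -0.1, -0.9]))
        assert binary.tolist() == [0, 0, 0]

    def test_all_missing_errors(self):
        with pytest.raises(ValueError, match="missing"):
            rt.binarize(pd.Series([np.nan, np.nan]))

    def test_missing_bins_stay_missing(self):
        binary, _, _ = rt.binarize(pd.Series([0.9, np.nan, 0.1]))
        assert binary.isna().tolist() == [False, True, False]

    def test_monotone_consistency(self):
        # raising nCN never converts replicated -> unreplicated at the
        # same threshold
        rng = np.random.default_rng(2)
        row = pd.Series(rng.normal(0.5, 0.4, 100))
        b1, th, _ = rt.binarize(row)
        raised = row + rng.uniform(0, 0.2, 100)
        b2 = (raised >= th).astype(float)
        assert ((b2 - b1) >= 0).all()


def _rtm(scrt):
    scrt = pd.DataFrame(scrt, dtype=float)
    scrt.index = [f"c{i}" for i in range(len(scrt))]
    return _rtm_from(scrt)


def _rtm_from(scrt: pd.DataFrame) -> RTMatrix:
    scrt = scrt.astype(float)
    return RTMatrix(scrt=scrt, ncn=scrt.copy(),
                    thresholds=pd.Series(0.5, index=scrt.index),
                    replication_pct=scrt.mean(axis=1, skipna=True))


class TestSmcFilter:
    def test_identical_cells_all_kept(self):
        rtm = _rtm([[1, 0, 1, 0]] * 6)
        out, dropped = rt.smc_filter(rtm)
        assert dropped == []

    def test_complementary_cell_dropped(self):
        rows = [[1, 0, 1, 0]] * 6 + [[0, 1, 0, 1]]
        out, dropped = rt.smc_filter(_rtm(rows))
        assert dropped == ["c6"]

    def test_boundary_55_percent_kept(self):
        # c0 is exactly 25% divergent from 5 of its 9 peers (55% < 60%)
        base = [0] * 8
        far = [1, 1] + [0] * 6          # distance 0.25 from base
        rows = [base] + [far] * 5 + [base] * 4
        out, dropped = rt.smc_filter(_rtm(rows))
        assert "c0" not in dropped

    def test_pct_window_restricts_comparisons(self):
        # the early minority differs on 60% of bins from 6 of its 9
        # peers: dropped under the literal global rule, kept when only
        # compared with cells at a similar progression
        early = [1] * 2 + [0] * 8
        late = [1] * 8 + [0] * 2
        rows = [early] * 4 + [late] * 6
        out, dropped = rt.smc_filter(_rtm(rows))
        assert sorted(dropped) == ["c0", "c1", "c2", "c3"]
        out, dropped = rt.smc_filter(_rtm(rows), pct_window=0.1)
        assert dropped == []

    def test_replication_pct_is_profile_mean(self):
        rtm = _rtm([[1, 1, 0, 0], [1, 0, 0, 0]])
        assert rtm.replication_pct.tolist() == [0.5, 0.25]


class TestPseudoBulk:
    def test_bin_replicated_in_every_cell_is_one(self):
        rng = np.random.default_rng(0)
        rows = (rng.random((40, 20)) < np.linspace(0.1, 0.9, 40)[:, None])
        rows = rows.astype(float)
        rows[:, 0] = 1.0
        track, n = rt.pseudo_bulk(_rtm(rows))
        assert track.iloc[0] == pytest.approx(1.0)

    def test_interval_means_averaged_unweighted(self):
        # two intervals: 3 cells at pct .2 and 1 cell at pct .8; bin 0
        # replicated only in the late cell -> RT = (0 + 1)/2
        rows = [[0, 1, 0, 0, 0], [0, 1, 0, 0, 0], [0, 1, 0, 0, 0],
                [1, 1, 1, 1, 0]]
        track, n = rt.pseudo_bulk(_rtm(rows), symmetry_tol=0.5)
        assert track.iloc[0] == pytest.approx(0.5)

    def test_invariant_to_cell_order_and_interval_duplication(self):
        rng = np.random.default_rng(3)
        rows = (rng.random((30, 25))
                < np.linspace(0.05, 0.95, 30)[:, None]).astype(float)
        tol = 0.5   # disable tail trimming: it keys off cell counts
        t1, _ = rt.pseudo_bulk(_rtm(rows), symmetry_tol=tol)
        t2, _ = rt.pseudo_bulk(_rtm(rows[::-1]), symmetry_tol=tol)
        assert np.allclose(t1.to_numpy(), t2.to_numpy(), equal_nan=True)
        # duplicating every cell of one progression interval leaves the
        # unweighted interval average unchanged
        dup = np.vstack([rows, rows[:3]])
        t3, _ = rt.pseudo_bulk(_rtm(dup), symmetry_tol=tol)
        assert np.allclose(t1.to_numpy(), t3.to_numpy(), equal_nan=True)

    def test_needs_two_cells(self):
        with pytest.raises(ValueError):
            rt.pseudo_bulk(_rtm([[1, 0]]))

    def test_recovers_sigmoid_programme(self, small_sim):
        # operation-level oracle: feed the ground-truth binary masks
        # through the pseudo-bulk averaging and compare with the known
        # firing-time landscape
        from scipy.stats import spearmanr
        sim = small_sim
        s_cells = sim.truth.index[sim.truth.phase == "S"]
        mask = sim.replicated.loc[s_cells]
        track, _n = rt.pseudo_bulk(_rtm_from(mask))
        rho = spearmanr(track, sim.rt_track_truth.loc[track.index],
                        nan_policy="omit")[0]
        assert rho >= 0.95


class TestBuildRtMatrix:
    def test_widely_missing_bins_masked(self):
        cn_s = pd.DataFrame({"a": [2.0, 2.0], "b": [np.nan, np.nan],
                             "c": [4.0, 4.0]}, index=["s1", "s2"])
        cn_g = pd.DataFrame({"a": [2.0], "b": [2.0], "c": [2.0]},
                            index=["g1"])
        rtm = rt.build_rt_matrix(cn_s, cn_g)
        assert rtm.ncn["b"].isna().all()
        assert rtm.scrt["a"].tolist() == [0, 0]
        assert rtm.scrt["c"].tolist() == [1, 1]

    def test_group_specific_reference(self):
        # clone B carries a gain; normalising against its own G1/G2
        # reference removes it from the replication signal
        cn_s = pd.DataFrame({"a": [4.0], "b": [2.0]}, index=["s1"])
        cn_g = pd.DataFrame({"a": [4.0, 2.0], "b": [2.0, 2.0]},
                            index=["g1", "g2"])
        groups = pd.Series({"s1": "B", "g1": "B", "g2": "A"})
        rtm = rt.build_rt_matrix(cn_s, cn_g, groups=groups)
        assert rtm.scrt.loc["s1"].tolist() == [0, 0]
        with pytest.raises(ValueError, match="reference"):
            rt.build_rt_matrix(cn_s, cn_g,
                               groups=pd.Series({"s1": "C", "g1": "B",
                                                 "g2": "A"}))
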