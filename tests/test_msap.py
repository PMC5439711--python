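import numpy as np
import pandas as pd
import pytest

from epiclone import msap
from epiclone.io_core import BandMatrix
from epiclone.msap import (
    classify_condition,
    condition_matrix,
    find_polymorphic,
    mixed_score,
    positional_stability,
    scoring_error_rate,
    seasonal_stability,
    subepilocus_matrices,
)

TRUTH_TABLE = [
    ((1, 1), "I", (1, 0, 0)),
    ((0, 1), "II", (0, 1, 0)),
    ((1, 0), "III", (0, 0, 1)),
    ((0, 0), "IV", (0, 0, 0)),
]


@pytest.mark.parametrize("bands,cond,score", TRUTH_TABLE)
def test_condition_truth_table_and_mixed_scoring(bands, cond, score):
    """The four (HpaII, MspI) band patterns map to conditions I-IV and their
    one-hot n/m/h codes; condition IV scores zero at all three subepiloci."""
    assert classify_condition(*bands) == cond
    assert mixed_score(cond) == score


def test_missing_band_propagates():
    assert classify_condition(np.nan, 1) is None
    assert classify_condition(1, None) is None
    assert mixed_score(None) == (None, None, None)


def test_condition_matrix_matches_cellwise(band_pair):
    cm = condition_matrix(*band_pair)
    hpa, msp = band_pair
    for sid in hpa.df.index:
        for frag in hpa.df.columns:
            expect = classify_condition(hpa.df.loc[sid, frag], msp.df.loc[sid, frag])
            assert cm.loc[sid, frag] == expect or (
                expect is None and cm.loc[sid, frag] is None
            )


def test_one_hot_invariant_and_rate_partition(band_pair):
    """n + m + h is 0 or 1 everywhere, and the empirical rates of the three
    classes plus the condition-IV rate partition the non-missing calls."""
    cm = condition_matrix(*band_pair)
    mats = subepilocus_matrices(cm)
    stack = np.stack([mats[k].df.to_numpy(dtype=float) for k in "nmh"])
    total = np.nansum(stack, axis=0)
    valid = ~np.isnan(stack[0])
    assert set(np.unique(total[valid])) <= {0.0, 1.0}
    iv_rate = np.mean(cm.to_numpy()[valid] == "IV")
    class_rates = [np.nanmean(stack[c][valid]) for c in range(3)]
    assert np.isclose(sum(class_rates) + iv_rate, 1.0)


class TestFindPolymorphic:
    def _cond(self, cols):
        return pd.DataFrame(cols)

    def test_monomorphic_dropped(self):
        c = self._cond({"f1": ["II"] * 4})
        assert find_polymorphic(c) == []

    def test_two_conditions_retained(self):
        c = self._cond({"f1": ["I", "II", "I", "I"]})
        assert find_polymorphic(c) == ["f1"]

    def test_exactly_the_varying_fragments_retained(self):
        # 6-sample fixture with 5 fragments of which exactly 2 vary
        c = self._cond(
            {
                "f1": ["I"] * 6,
                "f2": ["I", "I", "II", "I", "I", "I"],
                "f3": ["IV"] * 6,
                "f4": ["III", "III", "III", "IV", "III", "III"],
                "f5": [None] * 6,
            }
        )
        # brute-force oracle: count distinct non-missing conditions
        expect = [
            col for col in c.columns
            if len({v for v in c[col] if v is not None}) >= 2
        ]
        assert find_polymorphic(c) == expect == ["f2", "f4"]

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            find_polymorphic(self._cond({"f1": ["I"]}))


class TestScoringErrorRate:
    def _bm(self, arr):
        return BandMatrix(
            "HpaII", "P1",
            pd.DataFrame(np.asarray(arr, dtype=float),
                         index=[f"s{i}" for i in range(len(arr))]),
        )

    def test_identical_matrices_zero(self):
        a = self._bm([[1, 0], [0, 1]])
        assert scoring_error_rate(a, a) == 0.0

    def test_one_mismatch_in_twenty(self):
        a = self._bm(np.zeros((5, 4)))
        b_arr = np.zeros((5, 4))
        b_arr[0, 0] = 1
        b = self._bm(b_arr)
        assert scoring_error_rate(a, b) == 5.0

    def test_missing_cells_excluded_from_denominator(self):
        # 3x4 fixture, hand enumeration: joint non-missing cells only
        a_arr = np.array(
            [[1, 0, np.nan, 1], [0, np.nan, 1, 1], [1, 1, 0, np.nan]]
        )
        b_arr = np.array(
            [[1, 1, 0, np.nan], [0, 0, 1, 0], [np.nan, 1, 0, 1]]
        )
        # paired cells: (0,0),(0,1),(1,0),(1,2),(1,3),(2,1),(2,2) -> 7
        # mismatches: (0,1) 0vs1, (1,3) 1vs0 -> 2
        expect = 100.0 * 2 / 7
        got = scoring_error_rate(self._bm(a_arr), self._bm(b_arr))
        assert np.isclose(got, expect)
        # symmetry
        assert got == scoring_error_rate(self._bm(b_arr), self._bm(a_arr))

    def test_no_paired_calls_is_missing(self):
        a = self._bm([[np.nan], [1.0]])
        b = self._bm([[1.0], [np.nan]])
        assert np.isnan(scoring_error_rate(a, b))


def _leaf_frame(records):
    return pd.DataFrame(records, columns=["ramet", "leaf_rank", "locus", "hpa", "msp"])


class TestPositionalStability:
    def test_all_leaves_match_top(self):
        rows = [
            (r, leaf, "LoX", 1, 0)
            for r in range(4)
            for leaf in range(3)
        ]
        rep = positional_stability(_leaf_frame(rows))
        assert rep.df.loc["LoX", "CG"] == 100.0
        assert rep.df.loc["LoX", "CHG"] == 100.0

    def test_single_mismatch_in_largest_ramet(self):
        # ramets with 3, 6, 8 and 13 leaves; one HpaII mismatch in the
        # 13-leaf ramet -> mean of (100, 100, 100, 100*12/13)
        rows = []
        for r, n in enumerate([3, 6, 8, 13]):
            for leaf in range(n):
                hpa = 0 if (r == 3 and leaf == 12) else 1
                rows.append((r, leaf, "LoX", hpa, 1))
        rep = positional_stability(_leaf_frame(rows))
        expect = np.mean([100, 100, 100, 100 * 12 / 13])
        assert np.isclose(rep.df.loc["LoX", "CG"], expect)
        assert rep.df.loc["LoX", "CHG"] == 100.0

    def test_per_ramet_fractions_not_pooled_leaves(self):
        # two of four ramets fully mismatched below the top leaf; the mean is
        # over per-ramet fractions, not over pooled leaves
        sizes = [2, 4, 6, 8]
        rows = []
        for r, n in enumerate(sizes):
            for leaf in range(n):
                hpa = 1 if (r < 2 or leaf == 0) else 0
                rows.append((r, leaf, "LoX", hpa, 1))
        rep = positional_stability(_leaf_frame(rows))
        # brute-force oracle over the fixture
        per_ramet = []
        for r, n in enumerate(sizes):
            matches = n if r < 2 else 1
            per_ramet.append(100.0 * matches / n)
        assert np.isclose(rep.df.loc["LoX", "CG"], np.mean(per_ramet))
        pooled = 100.0 * (2 + 4 + 1 + 1) / sum(sizes)
        assert not np.isclose(rep.df.loc["LoX", "CG"], pooled)

    def test_single_leaf_ramet_contributes_100(self):
        rep = positional_stability(_leaf_frame([(0, 0, "LoX", 1, 1)]))
        assert rep.df.loc["LoX", "CG"] == 100.0


class TestSeasonalStability:
    def _frames(self, n_pairs, n_match, channel="hpa"):
        june, sept = [], []
        for i in range(n_pairs):
            june.append({"ramet": i, "locus": "LoX", "hpa": 1, "msp": 1})
            flip = i >= n_match
            sept.append(
                {
                    "ramet": i,
                    "locus": "LoX",
                    "hpa": 0 if (flip and channel == "hpa") else 1,
                    "msp": 0 if (flip and channel == "msp") else 1,
                }
            )
        return pd.DataFrame(june), pd.DataFrame(sept)

    def test_eleven_of_twelve(self):
        rep = seasonal_stability(*self._frames(12, 11))
        assert np.isclose(rep.df.loc["LoX", "CG"], 100 * 11 / 12)  # 91.7

    def test_all_match(self):
        rep = seasonal_stability(*self._frames(5, 5))
        assert rep.df.loc["LoX", "CG"] == 100.0
        assert rep.df.loc["LoX", "CHG"] == 100.0

    def test_five_of_twelve(self):
        rep = seasonal_stability(*self._frames(12, 5, channel="msp"))
        assert np.isclose(rep.df.loc["LoX", "CHG"], 100 * 5 / 12)  # 41.7

    def test_no_pairs_is_missing(self):
        june = pd.DataFrame([{"ramet": 0, "locus": "LoX", "hpa": 1, "msp": 1}])
        sept = pd.DataFrame([{"ramet": 9, "locus": "LoX", "hpa": 1, "msp": 1}])
        rep = seasonal_stability(june, sept)
        assert np.isnan(rep.df.loc["LoX", "CG"])


def test_error_report_pools_by_enzyme(band_pair):
    hpa, msp = band_pair
    rep = msap.scoring_error_report([(hpa, hpa), (msp, msp)])
    pooled = rep[rep["primer_pair"] == "(pooled)"]
    assert set(pooled["enzyme"]) == {"HpaII", "MspI"}
    assert (rep["error_rate_pct"].dropna() == 0).all()
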