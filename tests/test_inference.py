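import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oldowan import (
    ParameterError,
    behavior_bounds,
    chi_square_yates,
    contrast_within_outside,
    core_morphology_check,
    expected_flakes,
    observed_yield,
    recovery_ratio,
)
from oldowan.inference import round_expected, shape_classes


class TestCounts:
    def test_expected_and_recovery(self):
        assert expected_flakes(10, 8.0) == 80.0
        assert recovery_ratio(40, 80) == pytest.approx(50.0)
        assert observed_yield(40, 10) == pytest.approx(4.0)

    def test_rounding_convention(self):
        assert round_expected(841.49) == 841.0
        assert round_expected(86.44) == 86.4

    def test_errors(self):
        with pytest.raises(ParameterError):
            expected_flakes(-1, 8.0)
        with pytest.raises(ParameterError):
            recovery_ratio(10, 0)
        with pytest.raises(ParameterError):
            observed_yield(10, 0)


class TestChiSquareYates:
    def test_hand_symmetric_table(self):
        # E = 15 everywhere; 4 * (4.5^2 / 15) = 5.4
        stat, df, p = chi_square_yates([[10, 20], [20, 10]])
        assert stat == pytest.approx(5.4)
        assert df == 1
        assert p == pytest.approx(sps.chi2.sf(5.4, 1))

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            table = rng.integers(1, 200, size=(2, 2))
            stat, df, p = chi_square_yates(table)
            ref = sps.chi2_contingency(table, correction=True)
            assert stat == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_clamped_when_correction_overshoots(self):
        # |O - E| < 0.5 in every cell: the corrected statistic clamps to 0
        stat, _, p = chi_square_yates([[100, 100], [100, 101]])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_larger_tables_use_pearson(self):
        rng = np.random.default_rng(9)
        table = rng.integers(5, 100, size=(3, 4))
        stat, df, p = chi_square_yates(table)
        ref = sps.chi2_contingency(table, correction=False)
        assert stat == pytest.approx(ref.statistic, abs=1e-9)
        assert df == 6

    def test_invalid_tables(self):
        with pytest.raises(ParameterError):
            chi_square_yates([[1, 2]])
        with pytest.raises(ParameterError):
            chi_square_yates([[0, 0], [0, 0]])


class TestBehaviorBounds:
    def test_perfect_classifier_collapses_bounds(self):
        table = pd.DataFrame(
            100.0 * np.eye(4),
            index=["OBA", "OBB", "OBC", "OBD"],
            columns=["OBA", "OBB", "OBC", "OBD"])
        out = behavior_bounds({"OBA": 30, "OBC": 70}, table)
        assert out["OBA"]["min"] == pytest.approx(0.3)
        assert out["OBA"]["max"] == pytest.approx(0.3)
        assert out["OBC"]["point"] == pytest.approx(0.7)
        assert out["OBB"]["max"] == 0.0

    def test_hand_mixing(self):
        # all 100 flakes classified OBC; the OBC row leaks to every class
        table = pd.DataFrame(
            [[0.86, 3.88, 65.90, 29.30]],
            index=["OBC"], columns=["OBA", "OBB", "OBC", "OBD"])
        out = behavior_bounds({"OBC": 100}, table)
        assert out["OBC"]["min"] == pytest.approx(0.659)
        assert out["OBC"]["max"] == pytest.approx(1.0)
        assert out["OBD"]["min"] == 0.0
        assert out["OBD"]["max"] == pytest.approx(0.293)

    def test_missing_row_raises(self):
        table = pd.DataFrame(
            [[100.0, 0.0, 0.0, 0.0]],
            index=["OBA"], columns=["OBA", "OBB", "OBC", "OBD"])
        with pytest.raises(ParameterError):
            behavior_bounds({"OBC": 10}, table)
        with pytest.raises(ParameterError):
            behavior_bounds({"OBA": 0}, table)


class TestContrasts:
    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(10)
        inside = pd.DataFrame({"SL": rng.normal(1.6, 0.4, 80)})
        outside = pd.DataFrame({"SL": rng.normal(2.0, 0.5, 40)})
        out = contrast_within_outside(inside, outside, measures=("SL",))
        ref = sps.ttest_ind(inside["SL"], outside["SL"], equal_var=False)
        assert out.loc["SL", "p_value"] == pytest.approx(ref.pvalue)
        assert out.loc["SL", "mean_within"] == pytest.approx(
            inside["SL"].mean())

    def test_mannwhitney_matches_scipy(self):
        rng = np.random.default_rng(11)
        a = pd.DataFrame({"ST": rng.normal(0.5, 0.1, 50)})
        b = pd.DataFrame({"ST": rng.normal(0.6, 0.1, 30)})
        out = contrast_within_outside(a, b, measures=("ST",),
                                      test="mannwhitney")
        ref = sps.mannwhitneyu(a["ST"], b["ST"], alternative="two-sided")
        assert out.loc["ST", "p_value"] == pytest.approx(ref.pvalue)

    def test_degenerate_groups(self):
        a = pd.DataFrame({"SL": [1.0, 1.0, 1.0]})
        b = pd.DataFrame({"SL": [1.0, 1.0]})
        out = contrast_within_outside(a, b, measures=("SL",))
        assert out.loc["SL", "p_value"] == 1.0  # identical values
        c = pd.DataFrame({"SL": [2.0]})
        out2 = contrast_within_outside(a, c, measures=("SL",))
        assert np.isnan(out2.loc["SL", "p_value"])
        assert not out2.loc["SL", "significant"]

    def test_empty_group_raises(self):
        a = pd.DataFrame({"SL": [1.0, 2.0]})
        with pytest.raises(ParameterError):
            contrast_within_outside(a, a.iloc[0:0], measures=("SL",))


class TestCoreMorphology:
    def test_shape_classes_binning(self):
        cores = pd.DataFrame({"length": [10.0, 13.0, 20.0],
                              "width": [10.0, 10.0, 10.0]})
        cls = shape_classes(cores)
        assert list(cls) == ["compact", "intermediate", "elongate"]

    def test_kruskal_matches_scipy(self):
        rng = np.random.default_rng(12)
        n = 90
        cores = pd.DataFrame({
            "length": rng.uniform(80, 160, n),
            "width": np.full(n, 100.0),
        })
        yields = rng.poisson(8.0, n).astype(float)
        h, p, posthoc = core_morphology_check(cores, yields)
        classes = shape_classes(cores)
        groups = [yields[(classes == c).to_numpy()] for c in classes.unique()]
        ref_h, ref_p = sps.kruskal(*groups)
        assert h == pytest.approx(ref_h)
        assert p == pytest.approx(ref_p)
        assert len(posthoc) == 3  # pairwise rows for three classes

    def test_no_shape_yield_relation_in_simulator(self, experimental):
        cores = experimental.cores[experimental.cores["material"] == "basalt"]
        counts = (experimental.flakes[
            experimental.flakes["material"] == "basalt"]
            .groupby("core_id").size()
            .reindex(cores["core_id"], fill_value=0))
        h, p, _ = core_morphology_check(cores, counts.to_numpy())
        # least-effort reduction ignores core shape
        assert p > 0.01

    def test_alignment_error(self):
        cores = pd.DataFrame({"length": [10.0, 12.0], "width": [10.0, 10.0]})
        with pytest.raises(ParameterError):
            core_morphology_check(cores, [1.0, 2.0, 3.0])
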