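"""Full-vs-adequate comparison statistics against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pelvimark import (
    CaseSeries,
    PTMeasurement,
    band,
    case_average,
    compare,
    icc_agreement,
)
from pelvimark.comparison_stats import InsufficientDataError
from pelvimark.geometry import Definition, Method, Parameter


def series(parameter, values, images=None):
    images = images or [f"img{i}" for i in range(len(values))]
    return CaseSeries(parameter, pd.Series([float(v) for v in values], index=images))


def measurements(values_by_annotator, image="img0", parameter=Parameter.PT_M_EST):
    definition = Definition.PT_A if parameter == Parameter.PT_A else Definition.PT_M
    method = Method.CALCULATION if parameter == Parameter.PT_M_CAL else Method.ESTIMATION
    return [
        PTMeasurement(image, annotator, definition, method, value)
        for annotator, value in values_by_annotator.items()
    ]


# -- naive reimplementations used as oracles --------------------------------

def naive_pearson(x, y):
    mx, my = sum(x) / len(x), sum(y) / len(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def naive_paired_t_p(x, y):
    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    md = sum(d) / n
    sd = math.sqrt(sum((v - md) ** 2 for v in d) / (n - 1))
    t = md / (sd / math.sqrt(n))
    return 2.0 * stats.t.sf(abs(t), n - 1)


def naive_icc(X, form):
    """ICC from explicitly looped ANOVA sums of squares."""
    n, k = X.shape
    grand = sum(X[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(X[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(X[i, j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((r - grand) ** 2 for r in row)
    ssc = n * sum((c - grand) ** 2 for c in col)
    sse = sum((X[i, j] - row[i] - col[j] + grand) ** 2
              for i in range(n) for j in range(k))
    msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
    if form == "2_1":
        return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return (msr - mse) / (msr + (k - 1) * mse)


class TestCaseAverage:
    def test_mean_over_annotators(self):
        ms = measurements({f"ann{i}": v for i, v in enumerate([10, 11, 12, 13, 14])})
        out = case_average(ms)
        assert out[Parameter.PT_M_EST].values["img0"] == 12.0

    def test_exclusion_drops_one_annotator(self):
        ms = measurements({f"ann{i}": v for i, v in enumerate([10, 11, 12, 13, 14])})
        out = case_average(ms, {("img0", "ann4", Parameter.PT_M_EST)})
        assert out[Parameter.PT_M_EST].values["img0"] == 11.5

    def test_none_mask_equals_empty_mask(self):
        ms = measurements({"a": 5.0, "b": 7.0})
        a = case_average(ms, None)[Parameter.PT_M_EST].values
        b = case_average(ms, set())[Parameter.PT_M_EST].values
        pd.testing.assert_series_equal(a, b)

    def test_fully_excluded_image_is_dropped(self):
        ms = measurements({"a": 5.0}) + measurements({"a": 6.0}, image="img1")
        out = case_average(ms, {("img0", "a", Parameter.PT_M_EST)})
        assert list(out[Parameter.PT_M_EST].values.index) == ["img1"]

    def test_empty_input_raises(self):
        with pytest.raises(InsufficientDataError):
            case_average([])


class TestCompare:
    def test_identity_case(self):
        full = series(Parameter.PT_A, [10, 12, 14, 9])
        rep = compare(full, series(Parameter.PT_A, [10, 12, 14, 9]))
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.mean_abs_diff == 0.0
        assert rep.max_abs_diff == 0.0
        assert (rep.ci_low, rep.ci_high) == (0.0, 0.0)
        assert rep.t_p_value == 1.0

    def test_hand_arithmetic(self):
        rep = compare(series(Parameter.PT_A, [10, 12, 14]),
                      series(Parameter.PT_A, [10, 11, 14]))
        assert rep.mean_abs_diff == pytest.approx(1 / 3)
        assert rep.max_abs_diff == 1.0

    def test_statistics_match_naive_oracles(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            x = rng.normal(13, 6, n)
            y = x + rng.normal(0, 0.8, n)
            rep = compare(series(Parameter.PT_M_CAL, x), series(Parameter.PT_M_CAL, y))
            d = x - y
            assert rep.pearson_r == pytest.approx(naive_pearson(x, y), abs=1e-12)
            assert rep.mean_abs_diff == pytest.approx(np.mean(np.abs(d)), abs=1e-12)
            assert rep.max_abs_diff == pytest.approx(np.max(np.abs(d)), abs=1e-12)
            md, sd = np.mean(d), np.std(d, ddof=1)
            assert rep.ci_low == pytest.approx(md - 1.96 * sd, abs=1e-12)
            assert rep.ci_high == pytest.approx(md + 1.96 * sd, abs=1e-12)
            assert rep.t_p_value == pytest.approx(naive_paired_t_p(x, y), abs=1e-12)

    def test_absolute_statistics_symmetric_under_swap(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=20), rng.normal(size=20)
        a = compare(series(Parameter.PT_A, x), series(Parameter.PT_A, y))
        b = compare(series(Parameter.PT_A, y), series(Parameter.PT_A, x))
        assert a.pearson_r == pytest.approx(b.pearson_r)
        assert a.mean_abs_diff == pytest.approx(b.mean_abs_diff)
        assert a.max_abs_diff == pytest.approx(b.max_abs_diff)
        assert a.t_p_value == pytest.approx(b.t_p_value)
        assert a.mean_abs_diff <= a.max_abs_diff
        assert a.ci_low <= np.mean(x - y) <= a.ci_high

    def test_sem_interval_is_narrower_than_loa(self):
        rng = np.random.default_rng(5)
        x = rng.normal(10, 5, 40)
        y = x + rng.normal(0, 1, 40)
        loa = compare(series(Parameter.PT_A, x), series(Parameter.PT_A, y), ci="loa")
        sem = compare(series(Parameter.PT_A, x), series(Parameter.PT_A, y), ci="sem")
        assert (sem.ci_high - sem.ci_low) < (loa.ci_high - loa.ci_low)

    def test_too_few_pairs_raise(self):
        with pytest.raises(InsufficientDataError):
            compare(series(Parameter.PT_A, [1, 2]), series(Parameter.PT_A, [1, 2]))


class TestBand:
    @pytest.mark.parametrize(
        "r, expected",
        [
            (0.98, "very_strong"),
            (0.0, "poor"),
            (-0.5, "poor"),
            (0.55, "moderate"),
            (0.4, "fair"),
            (0.7, "moderate_strong"),
            # boundaries fall in the lower band
            (0.3, "poor"),
            (0.5, "fair"),
            (0.6, "moderate"),
            (0.8, "moderate_strong"),
        ],
    )
    def test_cut_points(self, r, expected):
        assert band(r) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            band(1.5)


class TestICC:
    def test_perfect_agreement(self):
        a = series(Parameter.PT_M_CAL, [10, 12, 14, 16, 11])
        assert icc_agreement(a, a) == pytest.approx(1.0)

    def test_constant_offset_is_penalized(self):
        vals = [10, 12, 14, 16, 11]
        a = series(Parameter.PT_M_CAL, vals)
        b = series(Parameter.PT_M_CAL, [v + 20 for v in vals])
        assert icc_agreement(a, b) < 0.3  # absolute agreement punishes offsets
        # the consistency form does not
        assert icc_agreement(a, b, form="3_1") == pytest.approx(1.0)

    def test_toy_table_matches_hand_anova(self):
        X = np.array([[9.0, 2.0], [1.0, 10.0], [8.0, 8.0], [2.0, 6.0], [7.0, 8.0]])
        a = series(Parameter.PT_M_CAL, X[:, 0])
        b = series(Parameter.PT_M_CAL, X[:, 1])
        for form in ("2_1", "3_1"):
            assert icc_agreement(a, b, form=form) == pytest.approx(
                naive_icc(X, form), abs=1e-12
            )

    def test_matches_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        vals = rng.normal(13, 6, 12)
        a = series(Parameter.PT_M_EST, vals)
        b = series(Parameter.PT_M_EST, vals + rng.normal(1.0, 1.5, 12))
        long = pd.DataFrame(
            {
                "targets": list(range(12)) * 2,
                "raters": ["a"] * 12 + ["b"] * 12,
                "scores": np.concatenate([a.values.to_numpy(), b.values.to_numpy()]),
            }
        )
        ref = pingouin.intraclass_corr(long, targets="targets", raters="raters",
                                       ratings="scores")
        icc2 = ref.loc[ref.Type.isin(["ICC2", "ICC(A,1)"]), "ICC"].item()
        icc3 = ref.loc[ref.Type.isin(["ICC3", "ICC(C,1)"]), "ICC"].item()
        assert icc_agreement(a, b, form="2_1") == pytest.approx(icc2, abs=1e-9)
        assert icc_agreement(a, b, form="3_1") == pytest.approx(icc3, abs=1e-9)
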