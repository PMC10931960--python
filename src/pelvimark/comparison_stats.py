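"""Full-vs-adequate comparison statistics and external-reference agreement.

The study-level question is whether excluding annotations judged
inadequate changes the pelvic-tilt parameters.  Per parameter, each
image's tilt is summarised as the *case-wise mean* over included
annotators; the full series (no exclusions) and the adequate series
(majority-rule exclusions applied) are then compared with Pearson
correlation, mean and maximum absolute paired difference, a 95% interval
on the paired differences, and a two-sided paired t-test.

The 95% interval defaults to Bland–Altman limits of agreement
(mean ± 1.96·SD of the differences), which is the reading consistent with
near-zero mean differences bracketed by ±2°; a standard-error-based CI of
the mean difference is available via ``ci="sem"``.

Agreement with an external reference series (e.g. technician-reported
tilt) uses the intraclass correlation coefficient, by default the
two-way random-effects, absolute-agreement, single-measurement form
ICC(2,1); values above 0.9 are conventionally read as excellent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import Parameter, PTMeasurement

__all__ = [
    "CaseSeries",
    "ComparisonReport",
    "InsufficientDataError",
    "case_average",
    "compare",
    "band",
    "icc_agreement",
    "report_frame",
]


class InsufficientDataError(ValueError):
    """Fewer aligned pairs than the statistic requires."""


@dataclass
class CaseSeries:
    """Per-image case-wise mean tilt for one parameter.

    ``values`` is indexed by image_id, one entry per retained image.
    """

    parameter: Parameter
    values: pd.Series


@dataclass
class ComparisonReport:
    """Full-vs-adequate comparison for one tilt parameter."""

    parameter: Parameter
    pearson_r: float
    r_band: str
    mean_abs_diff: float
    max_abs_diff: float
    ci_low: float
    ci_high: float
    t_p_value: float
    n_cases: int


def case_average(
    measurements: Iterable[PTMeasurement],
    mask: Iterable[tuple[str, str, Parameter]] | None = None,
) -> dict[Parameter, CaseSeries]:
    """Case-wise mean tilt per image and parameter, honouring exclusions.

    ``mask`` holds (image_id, annotator_id, parameter) triples to exclude
    (``None`` is equivalent to no exclusions).  An image whose annotators
    are all excluded for a parameter is dropped from that parameter's
    series.
    """
    excluded = set(mask) if mask is not None else set()
    buckets: dict[Parameter, dict[str, list[float]]] = {p: {} for p in Parameter}
    seen = False
    for m in measurements:
        seen = True
        if (m.image_id, m.annotator_id, m.parameter) in excluded:
            continue
        buckets[m.parameter].setdefault(m.image_id, []).append(m.angle)
    if not seen:
        raise InsufficientDataError("no measurements supplied")
    out = {}
    for parameter, images in buckets.items():
        series = pd.Series(
            {image: float(np.mean(vals)) for image, vals in sorted(images.items())},
            dtype=float,
        )
        out[parameter] = CaseSeries(parameter=parameter, values=series)
    return out


#: Pearson-r interpretation bands; a boundary value falls in the lower band.
_BAND_EDGES = [(0.3, "poor"), (0.5, "fair"), (0.6, "moderate"), (0.8, "moderate_strong")]


def band(r: float) -> str:
    """Interpretation band for a Pearson correlation coefficient."""
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    for edge, name in _BAND_EDGES:
        if r <= edge:
            return name
    return "very_strong"


def compare(
    full: CaseSeries,
    adequate: CaseSeries,
    *,
    ci: str = "loa",
) -> ComparisonReport:
    """Compare the full and adequate case-mean series for one parameter.

    Pairs are aligned on image id; images missing from either series
    (all annotators excluded) are dropped from both.  ``ci="loa"`` gives
    Bland–Altman limits of agreement on the paired differences;
    ``ci="sem"`` a t-based 95% CI of the mean difference.  A difference
    series with zero variance (identical datasets) reports p = 1 and a
    zero-width interval.
    """
    if full.parameter != adequate.parameter:
        raise ValueError("series measure different parameters")
    common = full.values.index.intersection(adequate.values.index)
    if len(common) < 3:
        raise InsufficientDataError(
            f"only {len(common)} aligned pairs for {full.parameter}; need >= 3"
        )
    x = full.values.loc[common].to_numpy(float)
    y = adequate.values.loc[common].to_numpy(float)
    diff = x - y
    r = float(stats.pearsonr(x, y).statistic)
    mean_diff = float(np.mean(diff))
    sd_diff = float(np.std(diff, ddof=1))
    if ci == "loa":
        lo, hi = mean_diff - 1.96 * sd_diff, mean_diff + 1.96 * sd_diff
    elif ci == "sem":
        sem = sd_diff / np.sqrt(len(diff))
        tcrit = float(stats.t.ppf(0.975, len(diff) - 1))
        lo, hi = mean_diff - tcrit * sem, mean_diff + tcrit * sem
    else:
        raise ValueError(f"unknown ci variant {ci!r}")
    if sd_diff == 0.0:
        p = 1.0  # identical series: no evidence of any difference
    else:
        p = float(stats.ttest_rel(x, y).pvalue)
    return ComparisonReport(
        parameter=full.parameter,
        pearson_r=r,
        r_band=band(r),
        mean_abs_diff=float(np.mean(np.abs(diff))),
        max_abs_diff=float(np.max(np.abs(diff))),
        ci_low=float(lo),
        ci_high=float(hi),
        t_p_value=p,
        n_cases=int(len(common)),
    )


def icc_agreement(
    series_a: CaseSeries | pd.Series,
    series_b: CaseSeries | pd.Series,
    *,
    form: str = "2_1",
) -> float:
    """Intraclass correlation between two aligned measurement series.

    ``form="2_1"`` is ICC(2,1): two-way random effects, absolute
    agreement, single measurement — it penalises constant offsets between
    raters.  ``form="3_1"`` is the two-way mixed, consistency form.
    Computed from the two-way ANOVA mean squares.
    """
    a = series_a.values if isinstance(series_a, CaseSeries) else series_a
    b = series_b.values if isinstance(series_b, CaseSeries) else series_b
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise InsufficientDataError(f"only {len(common)} aligned pairs; need >= 3")
    X = np.column_stack([a.loc[common].to_numpy(float), b.loc[common].to_numpy(float)])
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((X - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "2_1":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "3_1":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    if denom == 0.0:
        return 1.0  # all values identical: perfect agreement
    return float((msr - mse) / denom)


def report_frame(reports: Iterable[ComparisonReport], *, decimals: int = 2) -> pd.DataFrame:
    """Report table, one column per parameter, rounded to print precision."""
    rows = [
        "pearson_r",
        "r_band",
        "mean_abs_diff_deg",
        "max_abs_diff_deg",
        "ci_low_deg",
        "ci_high_deg",
        "t_p_value",
        "n_cases",
    ]
    data: dict[str, list] = {}
    for rep in reports:
        data[str(rep.parameter)] = [
            round(rep.pearson_r, decimals),
            rep.r_band,
            round(rep.mean_abs_diff, decimals),
            round(rep.max_abs_diff, decimals),
            round(rep.ci_low, decimals),
            round(rep.ci_high, decimals),
            round(rep.t_p_value, decimals),
            rep.n_cases,
        ]
    return pd.DataFrame(data, index=rows)
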