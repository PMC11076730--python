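"""Phase-1 epidemiology engine for school scoliosis screening.

Prevalence tables stratified by age and sex, contingency-table tests
(Pearson chi-square without continuity correction, Fisher's exact),
Welch's t from printed group summaries, Cobb-angle management/severity
classification, and curve-morphology cross-tabulation.

The statistical conventions matter here: screening reports print
chi-square statistics *without* Yates' correction and t statistics under
the unequal-variance (Welch) form, so those are the conventions
implemented.  Two-sided Fisher p-values use the point-probability method
(sum of all tables, with the observed margins, whose probability does
not exceed that of the observed table).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScreeningRecord",
    "ContingencyTable",
    "GroupSummary",
    "ChiSquareResult",
    "FisherResult",
    "WelchTResult",
    "MANAGEMENT_CLASSES",
    "SEVERITY_BY_CLASS",
    "prevalence_table",
    "stratum_counts_from_records",
    "pearson_chi_square",
    "fisher_exact_2x2",
    "welch_t_from_summary",
    "classify_management",
    "severity_of",
    "curve_profile_table",
]

SEXES = ("male", "female")
CURVE_PATTERNS = ("single", "double")
CURVE_REGIONS = ("thoracic", "thoracolumbar", "lumbar")
CONVEXITIES = ("left", "right")
EDUCATION_STAGES = ("primary", "junior", "senior")

#: Management classes over Cobb-angle intervals, closed on the left:
#: [0,10) negative, [10,20) observation, [20,40) rehabilitation or
#: bracing, [40,inf) surgical referral.
MANAGEMENT_CLASSES = ("negative", "observation", "rehabilitation_or_brace", "surgery")

#: Severity aliases for the three positive management classes.
SEVERITY_BY_CLASS = {
    "observation": "mild",
    "rehabilitation_or_brace": "moderate",
    "surgery": "severe",
}


@dataclass
class ScreeningRecord:
    """One screened student.

    Optional fields are ``None`` when not measured: a negative screen has
    no Cobb angle, and only radiographically confirmed positives carry
    curve descriptors.  Absence is encoded explicitly (never as 0) so
    negatives cannot contaminate anthropometric summaries.
    """

    subject_id: str
    age: int
    sex: str
    ethnicity: str = "unspecified"
    region: str = "unspecified"
    education_stage: str | None = None
    atr: float | None = None
    cobb: float | None = None
    curve_pattern: str | None = None
    curve_region: str | None = None
    convexity: str | None = None
    height_cm: float | None = None
    sitting_height_cm: float | None = None
    weight_kg: float | None = None
    bmi: float | None = None

    def __post_init__(self) -> None:
        if not 7 <= int(self.age) <= 19:
            raise ValueError(f"age {self.age} outside the screened range 7-19")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.cobb is not None and self.cobb < 0:
            raise ValueError("Cobb angle cannot be negative")
        if self.atr is not None and self.atr < 0:
            raise ValueError("ATR cannot be negative")
        if self.curve_pattern is not None and self.curve_pattern not in CURVE_PATTERNS:
            raise ValueError(f"unknown curve pattern {self.curve_pattern!r}")
        if self.curve_region is not None:
            if self.curve_pattern != "single":
                raise ValueError("curve_region is defined for single curves only")
            if self.curve_region not in CURVE_REGIONS:
                raise ValueError(f"unknown curve region {self.curve_region!r}")
        if self.convexity is not None and self.convexity not in CONVEXITIES:
            raise ValueError(f"unknown convexity {self.convexity!r}")

    @property
    def is_positive(self) -> bool:
        """Radiographically confirmed scoliosis (Cobb >= 10 degrees)."""
        return self.cobb is not None and self.cobb >= 10.0


@dataclass
class ContingencyTable:
    """r x c table of non-negative integer counts with axis labels."""

    counts: np.ndarray
    row_labels: Sequence[str] | None = None
    col_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (self.counts < 0).any():
            raise ValueError("contingency table counts must be non-negative")


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and SD of one group, as printed in reports."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd <= 0:
            raise ValueError("group summary needs sd > 0")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float


@dataclass(frozen=True)
class WelchTResult:
    t: float
    df: float
    p_value: float


def _as_counts(table: ContingencyTable | np.ndarray | Sequence) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return np.asarray(table.counts)
    arr = np.asarray(table)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr < 0).any():
        raise ValueError("contingency table counts must be non-negative")
    return arr


def pearson_chi_square(table: ContingencyTable | np.ndarray | Sequence) -> ChiSquareResult:
    """Pearson chi-square test of independence, *no* continuity correction.

    statistic = sum (O - E)^2 / E with E = row_total * col_total / N,
    df = (r - 1)(c - 1), p from the upper tail.  Raises when any row or
    column total is zero (an expected count of zero).
    """
    counts = _as_counts(table)
    if counts.sum(axis=1).min() == 0 or counts.sum(axis=0).min() == 0:
        raise ValueError("zero row or column total gives an expected count of 0")
    res = stats.chi2_contingency(counts, correction=False)
    return ChiSquareResult(statistic=float(res.statistic), df=int(res.dof),
                           p_value=float(res.pvalue))


def fisher_exact_2x2(table: ContingencyTable | np.ndarray | Sequence) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The two-sided p-value sums hypergeometric point probabilities, over
    tables with the observed margins, that do not exceed the probability
    of the observed table.  The odds ratio is the sample odds ratio
    ``ad/bc`` (``inf`` when ``bc == 0`` and ``ad > 0``).
    """
    counts = _as_counts(table)
    if counts.shape != (2, 2):
        raise ValueError("Fisher's exact test requires a 2x2 table")
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("Fisher's exact test requires integer counts")
        counts = counts.astype(np.int64)
    a, b = counts[0]
    c, d = counts[1]
    p = float(stats.fisher_exact(counts).pvalue)
    ad, bc = int(a) * int(d), int(b) * int(c)
    if bc == 0:
        odds = math.inf if ad > 0 else math.nan
    else:
        odds = ad / bc
    return FisherResult(p_value=min(p, 1.0), odds_ratio=odds)


def welch_t_from_summary(a: GroupSummary, b: GroupSummary) -> WelchTResult:
    """Welch's unequal-variance t-test from printed (n, mean, SD) summaries.

    t = (mean_a - mean_b) / sqrt(sd_a^2/n_a + sd_b^2/n_b) with
    Welch-Satterthwaite degrees of freedom and a two-sided p-value.
    The sign follows ``mean_a - mean_b``; reports compare magnitudes.
    """
    res = stats.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                     equal_var=False)
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return WelchTResult(t=float(res.statistic), df=float(df), p_value=float(res.pvalue))


def classify_management(cobb: float) -> str:
    """Map a Cobb angle (degrees) to its management class.

    Closed-left intervals: < 10 negative, [10, 20) regular observation,
    [20, 40) rehabilitation exercise or bracing, >= 40 surgical referral.
    """
    if cobb < 0 or not math.isfinite(cobb):
        raise ValueError("Cobb angle must be a finite value >= 0")
    if cobb < 10:
        return "negative"
    if cobb < 20:
        return "observation"
    if cobb < 40:
        return "rehabilitation_or_brace"
    return "surgery"


def severity_of(cobb: float) -> str | None:
    """Severity alias (mild/moderate/severe) of a positive Cobb angle."""
    return SEVERITY_BY_CLASS.get(classify_management(cobb))


def stratum_counts_from_records(records: Iterable[ScreeningRecord]) -> pd.DataFrame:
    """Collapse screening records into (age, sex) stratum counts."""
    rows: dict[tuple[int, str], list[int]] = {}
    for rec in records:
        key = (int(rec.age), rec.sex)
        cell = rows.setdefault(key, [0, 0])
        cell[0] += 1
        cell[1] += int(rec.is_positive)
    out = pd.DataFrame(
        [(age, sex, n, pos) for (age, sex), (n, pos) in sorted(rows.items())],
        columns=["age", "sex", "n_screened", "n_positive"],
    )
    return out


def prevalence_table(stratum_counts: pd.DataFrame | Iterable[ScreeningRecord]) -> pd.DataFrame:
    """Age x sex prevalence table with per-row sex-difference chi-square.

    Accepts either a tidy stratum-count frame (columns ``age``, ``sex``,
    ``n_screened``, ``n_positive``) or an iterable of records.  Returns a
    frame with one row per age plus a ``total`` row: screened/positive
    counts and positive rates (percent) per sex, and the 2x2 (sex x
    positive) Pearson chi-square and p-value for that age.
    """
    if not isinstance(stratum_counts, pd.DataFrame):
        stratum_counts = stratum_counts_from_records(stratum_counts)
    required = {"age", "sex", "n_screened", "n_positive"}
    if not required.issubset(stratum_counts.columns):
        raise ValueError(f"stratum counts need columns {sorted(required)}")
    if (stratum_counts["n_screened"] <= 0).any():
        bad = stratum_counts.loc[stratum_counts["n_screened"] <= 0, ["age", "sex"]]
        raise ValueError(f"empty stratum: {bad.to_dict('records')}")
    if (stratum_counts["n_positive"] > stratum_counts["n_screened"]).any():
        raise ValueError("n_positive cannot exceed n_screened")

    wide = stratum_counts.pivot_table(index="age", columns="sex",
                                      values=["n_screened", "n_positive"],
                                      aggfunc="sum", fill_value=0)
    rows = []
    for age in wide.index:
        nm = int(wide.loc[age, ("n_screened", "male")]) if ("n_screened", "male") in wide else 0
        nf = int(wide.loc[age, ("n_screened", "female")]) if ("n_screened", "female") in wide else 0
        pm = int(wide.loc[age, ("n_positive", "male")]) if ("n_positive", "male") in wide else 0
        pf = int(wide.loc[age, ("n_positive", "female")]) if ("n_positive", "female") in wide else 0
        rows.append(_prevalence_row(str(age), nm, pm, nf, pf))
    totals = stratum_counts.groupby("sex")[["n_screened", "n_positive"]].sum()
    nm = int(totals.loc["male", "n_screened"]) if "male" in totals.index else 0
    pm = int(totals.loc["male", "n_positive"]) if "male" in totals.index else 0
    nf = int(totals.loc["female", "n_screened"]) if "female" in totals.index else 0
    pf = int(totals.loc["female", "n_positive"]) if "female" in totals.index else 0
    rows.append(_prevalence_row("total", nm, pm, nf, pf))
    return pd.DataFrame(rows)


def _prevalence_row(stratum: str, n_m: int, pos_m: int, n_f: int, pos_f: int) -> dict:
    row = {
        "stratum": stratum,
        "male_n": n_m, "male_positive": pos_m,
        "male_rate": 100.0 * pos_m / n_m if n_m else math.nan,
        "female_n": n_f, "female_positive": pos_f,
        "female_rate": 100.0 * pos_f / n_f if n_f else math.nan,
        "n_screened": n_m + n_f,
        "n_positive": pos_m + pos_f,
        "rate": 100.0 * (pos_m + pos_f) / (n_m + n_f) if (n_m + n_f) else math.nan,
    }
    table = np.array([[pos_m, n_m - pos_m], [pos_f, n_f - pos_f]])
    try:
        chi = pearson_chi_square(table)
        row["chi_square"], row["p_value"] = chi.statistic, chi.p_value
    except ValueError:
        # a zero margin (e.g. no positives at this age in either sex)
        row["chi_square"], row["p_value"] = math.nan, math.nan
    return row


def curve_profile_table(records: Iterable[ScreeningRecord]) -> dict[str, pd.DataFrame]:
    """Cross-tabulate curve morphology of confirmed positives by severity.

    Returns the full severity x pattern x region x convexity cell-count
    table plus the marginal tables used for between-severity comparisons:
    severity x pattern, severity x region (single curves) and severity x
    convexity.  Any of these can be fed to :func:`pearson_chi_square` or
    :func:`fisher_exact_2x2`.
    """
    recs = []
    for rec in records:
        if not rec.is_positive:
            raise ValueError(f"record {rec.subject_id} is not a confirmed positive")
        if rec.curve_pattern is None:
            raise ValueError(f"record {rec.subject_id} lacks a curve pattern")
        if rec.curve_pattern == "single" and rec.curve_region is None:
            raise ValueError(f"single-curve record {rec.subject_id} lacks a region")
        recs.append({
            "severity": severity_of(rec.cobb),
            "pattern": rec.curve_pattern,
            "region": rec.curve_region if rec.curve_pattern == "single" else "double",
            "convexity": rec.convexity,
        })
    df = pd.DataFrame(recs)
    sev_order = ["mild", "moderate", "severe"]

    def _crosstab(col: str, frame: pd.DataFrame, categories: Sequence[str]) -> pd.DataFrame:
        tab = pd.crosstab(frame["severity"], frame[col])
        tab = tab.reindex(index=sev_order, columns=list(categories), fill_value=0)
        return tab.fillna(0).astype(int)

    cells = (df.groupby(["severity", "pattern", "region", "convexity"], dropna=False)
               .size().rename("count").reset_index())
    single = df[df["pattern"] == "single"]
    with_conv = df[df["convexity"].notna()]
    return {
        "cells": cells,
        "severity_by_pattern": _crosstab("pattern", df, CURVE_PATTERNS),
        "severity_by_region": _crosstab("region", single, CURVE_REGIONS),
        "severity_by_convexity": _crosstab("convexity", with_conv, CONVEXITIES),
        "severity_counts": df["severity"].value_counts().reindex(sev_order, fill_value=0),
    }
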