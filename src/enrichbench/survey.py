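"""Reporting-quality scoring of published enrichment analyses.

Each surveyed analysis is a checklist record: did the article state which
gene set library and version it used, which statistical test and tool (with
version), whether p-values were FDR-corrected, whether an appropriate
background gene list was defined, and whether code and gene profiles were
shared. The score deducts one point per missing item or methodological flaw
and awards one point each for sharing code and data, giving an integer in
[-9, +2]. Because the survey measures *reporting*, an item that cannot be
established from the article ("unknown") counts as the deduction.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

Answer = Literal["yes", "no", "unknown"]

#: Checklist fields, in scoring order.
CHECKLIST_FIELDS = (
    "library_origin_stated",
    "library_version_stated",
    "test_stated",
    "test_conducted",
    "fdr_corrected",
    "app_stated",
    "app_version_stated",
    "background_defined",
    "background_appropriate",
    "code_available",
    "data_provided",
)

#: One deduction per unmet item among these.
DEDUCTION_FIELDS = (
    "library_origin_stated",
    "library_version_stated",
    "test_stated",
    "test_conducted",
    "fdr_corrected",
    "app_stated",
    "app_version_stated",
)
#: One award per met item among these.
AWARD_FIELDS = ("code_available", "data_provided")

SCORE_MIN, SCORE_MAX = -9, 2


@dataclass
class SurveyRecord:
    """One published analysis's checklist answers plus optional bibliometrics.

    Checklist fields take ``"yes"``, ``"no"`` or ``"unknown"``; ``is_ora``
    marks analyses using an over-representation method, the only ones for
    which background-list questions apply.
    """

    analysis_id: str
    journal: str = ""
    omics_type: str = ""
    organism: str = ""
    tool_name: str = ""
    test_name: str = ""
    is_ora: Answer = "unknown"
    library_origin_stated: Answer = "unknown"
    library_version_stated: Answer = "unknown"
    test_stated: Answer = "unknown"
    test_conducted: Answer = "unknown"
    fdr_corrected: Answer = "unknown"
    app_stated: Answer = "unknown"
    app_version_stated: Answer = "unknown"
    background_defined: Answer = "unknown"
    background_appropriate: Answer = "unknown"
    code_available: Answer = "unknown"
    data_provided: Answer = "unknown"
    sjr: float = float("nan")
    citations: float = float("nan")

    def __post_init__(self):
        for name in CHECKLIST_FIELDS + ("is_ora",):
            value = getattr(self, name)
            if value not in ("yes", "no", "unknown"):
                raise ValueError(
                    f"{self.analysis_id}: field {name!r} must be yes/no/unknown, got {value!r}"
                )
        if not np.isnan(self.citations) and self.citations < 0:
            raise ValueError(f"{self.analysis_id}: negative citation count")


@dataclass(frozen=True)
class AnalysisScore:
    analysis_id: str
    score: int

    def __post_init__(self):
        if not SCORE_MIN <= self.score <= SCORE_MAX:
            raise ValueError(f"score {self.score} outside [{SCORE_MIN}, {SCORE_MAX}]")


def score_analysis(record: SurveyRecord) -> AnalysisScore:
    """Apply the checklist scoring schema to one record.

    One point is deducted per unmet reporting item (library origin/version,
    test stated/conducted, FDR correction, tool and tool version) and one
    for a background problem — "not defined" if no background list was
    described, otherwise "inappropriate" if the described list was wrong.
    The two background deductions are mutually exclusive: they describe the
    same flaw at different levels of visibility, so at most one applies.
    One point is awarded each for code availability and for providing the
    gene profiles.
    """
    score = 0
    for name in DEDUCTION_FIELDS:
        if getattr(record, name) != "yes":
            score -= 1
    if record.background_defined != "yes":
        score -= 1
    elif record.background_appropriate != "yes":
        score -= 1
    for name in AWARD_FIELDS:
        if getattr(record, name) == "yes":
            score += 1
    return AnalysisScore(record.analysis_id, score)


def score_records(records: Iterable[SurveyRecord]) -> list[AnalysisScore]:
    return [score_analysis(r) for r in records]


def score_summary(records: Sequence[SurveyRecord]) -> dict:
    """Median, mean, sample standard deviation and integer histogram of scores.

    The standard deviation uses the n-1 denominator and is NaN for a single
    record.
    """
    if not records:
        raise ValueError("no survey records")
    scores = np.array([score_analysis(r).score for r in records])
    hist = pd.Series(scores).value_counts().sort_index()
    return {
        "n": len(scores),
        "median": float(np.median(scores)),
        "mean": float(scores.mean()),
        "sd": float(scores.std(ddof=1)) if len(scores) > 1 else float("nan"),
        "histogram": hist,
    }


def field_frequencies(records: Sequence[SurveyRecord]) -> pd.DataFrame:
    """Per-item reporting frequencies with item-appropriate denominators.

    Most items are counted over all analyses; FDR correction only among
    analyses that conducted a statistical test (correction is meaningless
    otherwise), and the background items only among ORA analyses (FCS has no
    background list). A zero denominator yields a NaN proportion.
    """
    if not records:
        raise ValueError("no survey records")

    def _restrict(field: str) -> list[SurveyRecord]:
        if field == "fdr_corrected":
            return [r for r in records if r.test_conducted == "yes"]
        if field in ("background_defined", "background_appropriate"):
            return [r for r in records if r.is_ora == "yes"]
        return list(records)

    rows = []
    for field in CHECKLIST_FIELDS:
        denom_records = _restrict(field)
        denominator = len(denom_records)
        numerator = sum(1 for r in denom_records if getattr(r, field) == "yes")
        rows.append(
            {
                "field": field,
                "numerator": numerator,
                "denominator": denominator,
                "proportion": numerator / denominator if denominator else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def journal_scores(records: Sequence[SurveyRecord], min_n: int = 5) -> pd.DataFrame:
    """Mean analysis score per journal, for journals with at least ``min_n``
    analyses, sorted best-first."""
    df = pd.DataFrame(
        {
            "journal": [r.journal for r in records],
            "score": [score_analysis(r).score for r in records],
        }
    )
    agg = (
        df.groupby("journal")["score"]
        .agg(n="size", mean_score="mean")
        .reset_index()
    )
    agg = agg[agg["n"] >= min_n]
    return agg.sort_values("mean_score", ascending=False, ignore_index=True)


def bibliometric_correlation(
    scores: Sequence[AnalysisScore] | Sequence[float],
    metric: Sequence[float],
    transform: Literal["none", "log2p1"] = "none",
) -> dict:
    """Pearson correlation of analysis scores against a bibliometric.

    Pairs with a missing metric value are dropped; ``transform="log2p1"``
    applies log2(x + 1) first (citation counts include zeros, which a bare
    log cannot accommodate). The p-value is two-sided from the t-distribution
    with n - 2 degrees of freedom. A constant vector makes the correlation
    undefined; NaN is returned for r and p.
    """
    x = np.array([s.score if isinstance(s, AnalysisScore) else s for s in scores], dtype=float)
    y = np.asarray(metric, dtype=float)
    if x.shape != y.shape:
        raise ValueError("scores and metric must be paired")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >=3 complete pairs, got {n}")
    if transform == "log2p1":
        if np.any(y < 0):
            raise ValueError("log2p1 transform requires non-negative metric values")
        y = np.log2(y + 1.0)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": float("nan"), "p": float("nan"), "n": n}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": n}


# ---------------------------------------------------------------------------
# TSV plumbing

_TRUTHY = {"yes", "y", "true", "1", "1.0"}
_FALSY = {"no", "n", "false", "0", "0.0"}


def _coerce_answer(value) -> Answer:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "unknown"
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return "yes"
    if text in _FALSY:
        return "no"
    return "unknown"


def read_survey(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> list[SurveyRecord]:
    """Read survey records from TSV.

    ``columns`` maps :class:`SurveyRecord` field names to the column headers
    in the file (supplementary-table dialects vary); unmapped optional
    fields default to ``unknown``/empty. Checklist cells are coerced from
    yes/no/true/false/1/0 spellings; anything else becomes ``unknown``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    colmap = {f.name: f.name for f in dc_fields(SurveyRecord)}
    if columns:
        colmap.update(columns)
    if colmap["analysis_id"] not in df.columns:
        raise ValueError(f"{path}: no analysis id column {colmap['analysis_id']!r}")
    records = []
    for _, row in df.iterrows():
        kwargs: dict = {"analysis_id": str(row[colmap["analysis_id"]])}
        for field in ("journal", "omics_type", "organism", "tool_name", "test_name"):
            col = colmap[field]
            if col in df.columns and pd.notna(row[col]):
                kwargs[field] = str(row[col])
        for field in CHECKLIST_FIELDS + ("is_ora",):
            col = colmap[field]
            if col in df.columns:
                kwargs[field] = _coerce_answer(row[col])
        for field in ("sjr", "citations"):
            col = colmap[field]
            if col in df.columns and pd.notna(row[col]):
                kwargs[field] = float(row[col])
        records.append(SurveyRecord(**kwargs))
    return records


def attach_bibliometrics(
    records: Sequence[SurveyRecord],
    sjr: Mapping[str, float] | None = None,
    citations: Mapping[str, float] | None = None,
) -> None:
    """Fill ``sjr`` (by journal) and ``citations`` (by analysis id) in place."""
    for r in records:
        if sjr is not None and r.journal in sjr:
            r.sjr = float(sjr[r.journal])
        if citations is not None and r.analysis_id in citations:
            r.citations = float(citations[r.analysis_id])
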