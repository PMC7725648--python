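"""Cohort-level score comparison: descriptive summaries and nonparametric tests.

The study's analysis layer over per-learner modality scores: Shapiro-Wilk
normality screening, mean/SD/median/range descriptives, two-sided
Mann-Whitney U for group comparisons (e.g. by sex), and Spearman rank
correlation between modalities.  Tests are two-sided at alpha = .05 with no
multiple-testing correction; ties are handled with average ranks throughout.
The test statistics themselves are delegated to scipy.stats.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SCORE_COLUMNS",
    "validate_cohort",
    "summarize",
    "compare_groups",
    "correlate",
    "normality_check",
    "modality_comparison",
]

SCORE_COLUMNS = ("game_score", "handson_score", "osce_score")
REQUIRED_COLUMNS = ("learner_id", "sex") + SCORE_COLUMNS + ("trials_to_pass",)


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort table invariants (columns, score range, trial counts)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing column(s): {missing}")
    for col in SCORE_COLUMNS:
        vals = cohort[col].to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 100)):
            raise ValueError(f"{col}: scores must be in [0, 100]")
    if np.any(cohort["trials_to_pass"].to_numpy() < 1):
        raise ValueError("trials_to_pass must be >= 1")
    return cohort


def summarize(cohort: pd.DataFrame) -> dict:
    """Mean/SD/median/range per score variable plus sex counts and percentages."""
    if len(cohort) == 0:
        raise ValueError("cannot summarize an empty cohort")
    validate_cohort(cohort)
    out: dict = {"n": int(len(cohort)), "sex": {}, "variables": {}}
    counts = cohort["sex"].value_counts()
    for sex in ("male", "female"):
        k = int(counts.get(sex, 0))
        out["sex"][sex] = {"n": k, "percent": 100.0 * k / len(cohort)}
    for col in SCORE_COLUMNS + ("trials_to_pass",):
        v = cohort[col].to_numpy(dtype=float)
        out["variables"][col] = {
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            "median": float(np.median(v)),
            "range": (float(np.min(v)), float(np.max(v))),
        }
    return out


def compare_groups(values_a: Sequence[float], values_b: Sequence[float]) -> dict:
    """Two-sided Mann-Whitney U test.

    Returns the U statistic of the first group and the two-sided p-value
    (exact where scipy can, normal approximation with tie correction
    otherwise; ties are mid-ranked).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return {"U": float(res.statistic), "p": float(res.pvalue), "n_a": int(a.size), "n_b": int(b.size)}


def correlate(x: Sequence[float], y: Sequence[float]) -> dict:
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    res = sps.spearmanr(x, y)
    return {"rho": float(res.statistic), "p": float(res.pvalue), "n": int(x.size)}


def normality_check(values: Sequence[float]) -> dict:
    """Shapiro-Wilk normality test; 3 <= n <= 5000; constant input is rejected."""
    v = np.asarray(values, dtype=float)
    if not (3 <= v.size <= 5000):
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={v.size}")
    if np.ptp(v) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    res = sps.shapiro(v)
    return {"W": float(res.statistic), "p": float(res.pvalue), "n": int(v.size)}


def modality_comparison(cohort: pd.DataFrame) -> dict:
    """The study-shaped analysis bundle over one cohort.

    Per-sex Mann-Whitney comparisons of every score variable and the
    Spearman correlation matrix between modalities (plus trials-to-pass).
    """
    validate_cohort(cohort)
    male = cohort[cohort["sex"] == "male"]
    female = cohort[cohort["sex"] == "female"]
    by_sex = {}
    if len(male) and len(female):
        for col in SCORE_COLUMNS + ("trials_to_pass",):
            by_sex[col] = compare_groups(male[col], female[col])
    variables = ("trials_to_pass",) + SCORE_COLUMNS
    corr: dict[str, dict] = {}
    for va in variables:
        corr[va] = {}
        for vb in variables:
            if va == vb:
                continue
            corr[va][vb] = correlate(cohort[va], cohort[vb])
    return {"summary": summarize(cohort), "by_sex": by_sex, "correlations": corr}
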