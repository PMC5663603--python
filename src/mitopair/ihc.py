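"""Semi-quantitative immunohistochemistry scoring and association statistics.

TFAM staining is scored on two axes: intensity 0-3 (none, weak/light yellow,
moderate/yellow-brown, strong/brown) and stained-area grade 0-4 (none, 1-5%,
6-25%, 26-50%, >50% of cells). The combined score is their product (0-12) and
a sample is called positive when both axes are nonzero; an equivocal reaction
is regarded as negative. The combination rule and positivity threshold are
configurable (``score_rule`` product or sum, ``positive_min``) since the
underlying scoring convention exists in several variants.

Association with dichotomized clinicopathologic covariates (age at 60 years,
Edmondson-Steiner grade I&II vs III&IV, tumor size at 5 cm) is tested on the
2x2 table with Pearson chi-square both plain and Yates-corrected, plus
Fisher's exact test; the odds ratio uses the Haldane 0.5 correction when any
cell is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

ED_GRADES = ("I", "II", "III", "IV")


class DegenerateTableError(ValueError):
    """Degenerate 2x2 table (zero margin)."""


@dataclass(frozen=True)
class IHCScore:
    intensity: int  # 0..3
    area_grade: int  # 0..4
    combined: int
    call: str  # positive | negative | equivocal


@dataclass(frozen=True)
class CaseCovariates:
    age: float  # years
    gender: str  # male | female
    ed_grade: str  # I | II | III | IV
    tumor_size_cm: float

    def __post_init__(self):
        if self.ed_grade not in ED_GRADES:
            raise ValueError(f"ED grade must be one of {ED_GRADES}")


def combine_score(
    intensity: int,
    area_grade: int,
    score_rule: str = "product",
    positive_min: int = 1,
) -> IHCScore:
    """Combine the two staining axes into one score and a positive/negative call.

    Default rule: combined = intensity x area_grade; positive requires
    combined >= ``positive_min`` with both axes nonzero. A nonzero combined
    score with a zero axis (possible only under the sum rule) is equivocal,
    which tabulations count as negative.
    """
    if intensity not in (0, 1, 2, 3):
        raise ValueError(f"intensity must be 0..3, got {intensity}")
    if area_grade not in (0, 1, 2, 3, 4):
        raise ValueError(f"area grade must be 0..4, got {area_grade}")
    if score_rule == "product":
        combined = intensity * area_grade
    elif score_rule == "sum":
        combined = intensity + area_grade
    else:
        raise ValueError("score_rule must be 'product' or 'sum'")
    if combined >= positive_min and intensity >= 1 and area_grade >= 1:
        call = "positive"
    elif combined >= positive_min:
        call = "equivocal"  # one axis zero; regarded as negative downstream
    else:
        call = "negative"
    return IHCScore(intensity, area_grade, combined, call)


def _chi2_closed_form(a: int, b: int, c: int, d: int) -> float:
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    return n * (a * d - b * c) ** 2 / denom


def association_table(
    calls: list[str], covariate_high: list[bool]
) -> dict:
    """Test association between positivity and a dichotomized covariate.

    ``calls`` are per-case 'positive'/'negative'/'equivocal' (equivocal
    counts as negative); ``covariate_high`` marks the upper stratum of the
    dichotomization (e.g. size > 5 cm). Returns the 2x2 counts (rows: low,
    high stratum; columns: positive, negative), chi-square with and without
    Yates correction, Fisher's exact P, and the odds ratio.
    """
    if len(calls) != len(covariate_high):
        raise ValueError("calls and covariate must have equal length")
    pos = [c == "positive" for c in calls]
    a = sum(1 for p, h in zip(pos, covariate_high) if not h and p)  # low, positive
    b = sum(1 for p, h in zip(pos, covariate_high) if not h and not p)
    c = sum(1 for p, h in zip(pos, covariate_high) if h and p)  # high, positive
    d = sum(1 for p, h in zip(pos, covariate_high) if h and not p)
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError(f"zero margin in 2x2 table {table.tolist()}")
    plain = stats.chi2_contingency(table, correction=False)
    yates = stats.chi2_contingency(table, correction=True)
    fisher = stats.fisher_exact(table)
    if min(a, b, c, d) == 0:  # Haldane correction
        odds_ratio = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds_ratio = (a * d) / (b * c)
    return {
        "table": table.tolist(),
        "chi_square": float(plain.statistic),
        "P": float(plain.pvalue),
        "chi_square_yates": float(yates.statistic),
        "P_yates": float(yates.pvalue),
        "P_fisher": float(fisher.pvalue),
        "odds_ratio": float(odds_ratio),
    }


def positivity_summary(
    calls: list[str], ed_grades: list[str] | None = None
) -> dict:
    """Fraction positive overall and per Edmondson-Steiner grade."""
    n_total = len(calls)
    n_positive = sum(1 for c in calls if c == "positive")
    out = {
        "n_positive": n_positive,
        "n_total": n_total,
        "fraction": n_positive / n_total if n_total else float("nan"),
        "undefined": n_total == 0,
    }
    if ed_grades is not None:
        if len(ed_grades) != n_total:
            raise ValueError("ed_grades length must match calls")
        breakdown = {}
        for g in ED_GRADES:
            tot = sum(1 for x in ed_grades if x == g)
            pos = sum(1 for c, x in zip(calls, ed_grades) if x == g and c == "positive")
            breakdown[g] = (pos, tot)
        out["per_ed_grade"] = breakdown
    return out
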