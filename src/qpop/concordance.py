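"""Predicted-vs-clinical concordance statistics.

A patient's predicted regimen NCV is dichotomized at a viability cutoff
(default 0.65, chosen by ROC analysis): scores below the cutoff predict a
clinical responder, scores at or above it predict a non-responder.
Clinical outcome categories CR / CRi / PR collapse to "response", NR to
"no response".  The module provides the 2x2 confusion summary with exact
and continuity-corrected binomial intervals, Fisher's exact test, ROC /
Youden cutoff analysis, top-pair frequency tables across a cohort, and
paired comparisons of combination scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .surface import CombinationRanking, top_combinations

__all__ = [
    "RESPONDER",
    "NON_RESPONDER",
    "NCV_CUTOFF",
    "ConcordanceRecord",
    "ConfusionSummary",
    "classify_prediction",
    "collapse_clinical",
    "confusion_summary",
    "proportion_ci",
    "fisher_exact_2x2",
    "roc_analysis",
    "top_pair_frequency",
    "paired_combo_comparison",
]

RESPONDER = "responder"
NON_RESPONDER = "non_responder"

#: NCV classification cutoff (ROC-derived); scores >= cutoff predict non-response
NCV_CUTOFF = 0.65

_RESPONSE_CATEGORIES = {"CR": True, "CRI": True, "PR": True, "NR": False}


def classify_prediction(predicted_ncv: float, cutoff: float = NCV_CUTOFF) -> str:
    """Responder iff predicted NCV is strictly below the cutoff (the
    boundary value is assigned to non-response)."""
    if not np.isfinite(predicted_ncv):
        raise ValueError("predicted NCV must be finite")
    return RESPONDER if predicted_ncv < cutoff else NON_RESPONDER


def collapse_clinical(label: str) -> bool:
    """True for clinical response (CR, CRi or PR), False for NR."""
    key = str(label).strip().upper()
    if key not in _RESPONSE_CATEGORIES:
        raise ValueError(f"unknown clinical response category: {label!r}")
    return _RESPONSE_CATEGORIES[key]


@dataclass(frozen=True)
class ConcordanceRecord:
    """One evaluable patient: regimen, predicted score and clinical outcome."""

    patient: str
    regimen: frozenset[str]
    predicted_ncv: float
    clinical_label: str  # CR / CRi / PR / NR
    tags: Mapping[str, str] = field(default_factory=dict)  # e.g. status=ND, eln=adverse
    cutoff: float = NCV_CUTOFF

    @property
    def predicted_label(self) -> str:
        return classify_prediction(self.predicted_ncv, self.cutoff)

    @property
    def clinical_response(self) -> bool:
        return collapse_clinical(self.clinical_label)


# ---------------------------------------------------------------------------
# binomial confidence intervals
# ---------------------------------------------------------------------------


def proportion_ci(
    x: int, n: int, method: str = "clopper_pearson", conf: float = 0.95
) -> tuple[float, float]:
    """95% (by default) interval for a binomial proportion.

    ``clopper_pearson`` is the exact beta-quantile interval;
    ``wilson_cc`` the continuity-corrected Wilson score interval.  Both
    are provided because published concordance tables are not always
    consistent with a single method.
    """
    if not 0 <= x <= n or n < 1:
        raise ValueError("require 0 <= x <= n with n >= 1")
    alpha = 1.0 - conf
    if method == "clopper_pearson":
        lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
        hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
        return lo, hi
    if method == "wilson_cc":
        z = float(stats.norm.ppf(1 - alpha / 2))
        p = x / n
        den = 2 * (n + z * z)
        lo_num = 2 * n * p + z * z - 1 - z * np.sqrt(
            z * z - 2 - 1 / n + 4 * p * (n * (1 - p) + 1)
        )
        hi_num = 2 * n * p + z * z + 1 + z * np.sqrt(
            z * z + 2 - 1 / n + 4 * p * (n * (1 - p) - 1)
        )
        lo = 0.0 if x == 0 else max(0.0, lo_num / den)
        hi = 1.0 if x == n else min(1.0, hi_num / den)
        return float(lo), float(hi)
    raise ValueError(f"unknown CI method: {method!r}")


# ---------------------------------------------------------------------------
# confusion summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 prediction-vs-outcome counts and the derived proportions.

    tp counts predicted responders with clinical response.  Metrics whose
    denominator class is empty are None (undefined), never 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    ci_method: str = "clopper_pearson"

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def _ratio(self, num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> float | None:
        return self._ratio(self.tp + self.tn, self.n)

    def ci(self, metric: str, method: str | None = None) -> tuple[float, float] | None:
        """95% interval for one of the five proportions."""
        pairs = {
            "sensitivity": (self.tp, self.tp + self.fn),
            "specificity": (self.tn, self.tn + self.fp),
            "ppv": (self.tp, self.tp + self.fp),
            "npv": (self.tn, self.tn + self.fn),
            "accuracy": (self.tp + self.tn, self.n),
        }
        x, n = pairs[metric]
        if n == 0:
            return None
        return proportion_ci(x, n, method or self.ci_method)

    def as_table(self) -> np.ndarray:
        """[[tp, fn], [fp, tn]] — prediction rows, outcome columns."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])

    def to_dict(self) -> dict:
        out = {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}
        for m in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            v = getattr(self, m)
            out[m] = v
            out[f"{m}_ci"] = self.ci(m)
        return out


def confusion_summary(
    records: Iterable[ConcordanceRecord], cutoff: float | None = None
) -> ConfusionSummary:
    """Tally predicted labels against collapsed clinical outcomes."""
    tp = fp = fn = tn = 0
    for r in records:
        score_cut = cutoff if cutoff is not None else r.cutoff
        pred_resp = classify_prediction(r.predicted_ncv, score_cut) == RESPONDER
        clin_resp = r.clinical_response
        if pred_resp and clin_resp:
            tp += 1
        elif pred_resp and not clin_resp:
            fp += 1
        elif not pred_resp and clin_resp:
            fn += 1
        else:
            tn += 1
    return ConfusionSummary(tp=tp, fp=fp, fn=fn, tn=tn)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value: the total hypergeometric probability
    of all tables (margins fixed) no more likely than the observed one.

    Degenerate margins (an empty row or column) give p = 1 with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative counts")
    if t.sum() < 1:
        raise ValueError("table must contain at least one observation")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("degenerate margin in 2x2 table; Fisher p set to 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROCResult:
    auc: float
    thresholds: np.ndarray      # candidate cutoffs (midpoints between scores)
    sensitivity: np.ndarray     # at each threshold
    specificity: np.ndarray
    optimal_cutoff: float       # Youden J maximizer (midpoint convention)
    youden_j: float


def roc_analysis(
    scores: Sequence[float], responses: Sequence[bool | int]
) -> ROCResult:
    """ROC of predicted NCV against clinical response.

    Orientation is fixed: lower scores are more responder-like, so AUC is
    the probability a random responder scores below a random non-responder
    (ties count half, as in the Mann-Whitney statistic).  The optimal
    cutoff maximizes Youden's J over thresholds placed midway between
    adjacent distinct scores (classification rule: score < t -> responder);
    ties in J are broken toward the lowest threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(responses, dtype=bool)
    if len(s) != len(y):
        raise ValueError("scores and responses length mismatch")
    if y.all() or not y.any():
        raise ValueError("both clinical classes must be present")
    auc = float(roc_auc_score(y.astype(int), -s))

    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cand = np.concatenate([[uniq[0] - 1e-9], mids, [uniq[-1] + 1e-9]])
    sens = np.array([(s[y] < t).mean() for t in cand])
    spec = np.array([(s[~y] >= t).mean() for t in cand])
    j = sens + spec - 1.0
    best = int(np.argmax(j))
    return ROCResult(
        auc=auc,
        thresholds=cand,
        sensitivity=sens,
        specificity=spec,
        optimal_cutoff=float(cand[best]),
        youden_j=float(j[best]),
    )


# ---------------------------------------------------------------------------
# cohort-level combination summaries
# ---------------------------------------------------------------------------


def top_pair_frequency(
    rankings: Sequence[CombinationRanking], top_n: int = 10
) -> pd.DataFrame:
    """How many patients have each drug pair among their top ``top_n``
    two-drug combinations; sorted by count descending, ties alphabetical."""
    counts: dict[tuple[str, str], int] = {}
    for ranking in rankings:
        top2 = top_combinations(ranking, order=2, n=top_n)
        names = list(ranking.drug_names)
        seen: set[tuple[str, str]] = set()
        for _, row in top2.iterrows():
            active = tuple(sorted(d for d in names if row[d] != 0))
            seen.add(active)
        for pair in seen:
            counts[pair] = counts.get(pair, 0) + 1
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        [(a, b, c) for (a, b), c in items],
        columns=["drug_a", "drug_b", "n_patients"],
    )


@dataclass(frozen=True)
class PairedComparison:
    group: str
    n: int
    mean_difference: float
    t_statistic: float
    p_value: float
    degenerate: bool = False


def paired_combo_comparison(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    groups: Sequence[str] | None = None,
) -> list[PairedComparison]:
    """Two-sided paired t-test of combination A vs B scores, per subgroup.

    Identical vectors give t = 0, p = 1; a constant nonzero shift has zero
    difference variance and is flagged degenerate (p undefined).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    g = np.asarray(groups if groups is not None else ["all"] * len(a))
    out = []
    for label in pd.unique(g):
        mask = g == label
        if mask.sum() < 2:
            raise ValueError(f"group {label!r} has fewer than 2 pairs")
        d = a[mask] - b[mask]
        mean_d = float(d.mean())
        if float(d.std(ddof=1)) == 0.0:
            if mean_d == 0.0:
                out.append(PairedComparison(str(label), int(mask.sum()), 0.0, 0.0, 1.0))
            else:
                out.append(
                    PairedComparison(
                        str(label), int(mask.sum()), mean_d,
                        float("nan"), float("nan"), degenerate=True,
                    )
                )
            continue
        t, p = stats.ttest_rel(a[mask], b[mask])
        out.append(PairedComparison(str(label), int(mask.sum()), mean_d, float(t), float(p)))
    return out
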