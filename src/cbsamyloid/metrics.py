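"""Diagnostic-performance statistics for binary classifiers against a
binary reference standard (here: variant calls against amyloid-PET status).

Conventions: the positive predicted class is a temporoparietal call (or
marker present), the positive reference class is PIB+.  Proportion CIs are
Clopper-Pearson exact 95% intervals by default (valid at the small
denominators typical of single-center cohorts); Wald intervals are
available behind a flag for comparison.  Odds ratios use the cross-product
with a Woolf log-normal CI and the Haldane-Anscombe +0.5 correction iff
any cell is zero.  The two-sided Fisher exact p-value follows the
probability-mass convention: the sum of hypergeometric table probabilities
no greater than the observed table's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, InputError

Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """TP/FP/FN/TN counts (prediction positive = tpv / marker present,
    reference positive = PIB+)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise InputError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.total < 1:
            raise InputError("contingency table must contain at least one count")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        """[[tp, fp], [fn, tn]] — rows: prediction +/-, columns: reference +/-."""
        return np.array([[self.tp, self.fp], [self.fn, self.tn]])


def build_contingency(
    predictions: pd.Series, reference: pd.Series
) -> ContingencyTable2x2:
    """Cross-tabulate aligned boolean per-patient labels.

    Both series are indexed by patient id; the id sets must be identical
    (patients lacking a modality are dropped upstream, with a logged count).
    """
    predictions = pd.Series(predictions).astype(bool)
    reference = pd.Series(reference).astype(bool)
    if len(predictions) == 0:
        raise InputError("empty prediction set")
    pred_ids, ref_ids = set(predictions.index), set(reference.index)
    if pred_ids != ref_ids:
        raise AlignmentError(pred_ids - ref_ids, ref_ids - pred_ids)
    reference = reference.loc[predictions.index]
    return ContingencyTable2x2(
        tp=int((predictions & reference).sum()),
        fp=int((predictions & ~reference).sum()),
        fn=int((~predictions & reference).sum()),
        tn=int((~predictions & ~reference).sum()),
    )


@dataclass(frozen=True)
class EstimateCI:
    """A proportion with its 95% CI; NaN throughout when the denominator
    is empty (undefined, never reported as 0)."""

    point: float
    lower: float
    upper: float
    defined: bool = True

    def __iter__(self):
        return iter((self.point, self.lower, self.upper))


def _proportion_ci(k: int, n: int, method: str = "clopper-pearson") -> EstimateCI:
    if n == 0:
        return EstimateCI(math.nan, math.nan, math.nan, defined=False)
    p = k / n
    if method == "clopper-pearson":
        lo = 0.0 if k == 0 else float(stats.beta.ppf(0.025, k, n - k + 1))
        hi = 1.0 if k == n else float(stats.beta.ppf(0.975, k + 1, n - k))
    elif method == "wald":
        half = Z95 * math.sqrt(p * (1 - p) / n)
        lo, hi = max(0.0, p - half), min(1.0, p + half)
    else:
        raise InputError(f"unknown CI method {method!r}")
    return EstimateCI(p, lo, hi)


@dataclass(frozen=True)
class PerformanceSummary:
    sensitivity: EstimateCI
    specificity: EstimateCI
    ppv: EstimateCI
    npv: EstimateCI
    accuracy: EstimateCI


def performance(
    table: ContingencyTable2x2, ci_method: str = "clopper-pearson"
) -> PerformanceSummary:
    """Sensitivity, specificity, PPV, NPV and accuracy with exact 95% CIs.

    A statistic whose denominator is zero is returned undefined (NaN with
    ``defined=False``), not as 0.
    """
    t = table
    return PerformanceSummary(
        sensitivity=_proportion_ci(t.tp, t.tp + t.fn, ci_method),
        specificity=_proportion_ci(t.tn, t.tn + t.fp, ci_method),
        ppv=_proportion_ci(t.tp, t.tp + t.fp, ci_method),
        npv=_proportion_ci(t.tn, t.tn + t.fn, ci_method),
        accuracy=_proportion_ci(t.tp + t.tn, t.total, ci_method),
    )


def round_half_up_percent(p: float) -> int:
    """Whole-percent rounding, halves away from zero (report formatting)."""
    return int(math.floor(p * 100 + 0.5))


@dataclass(frozen=True)
class OddsRatioResult:
    or_estimate: float
    ci95: Tuple[float, float]
    correction_applied: bool


def odds_ratio(table: ContingencyTable2x2) -> OddsRatioResult:
    """Cross-product OR with Woolf log-normal 95% CI.

    The Haldane-Anscombe +0.5 continuity correction is applied to every
    cell iff any cell is zero, guaranteeing a finite estimate and CI.
    """
    cells = np.array([table.tp, table.fp, table.fn, table.tn], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    tp, fp, fn, tn = cells
    est = (tp * tn) / (fp * fn)
    se = math.sqrt((1 / cells).sum())
    lo, hi = math.exp(math.log(est) - Z95 * se), math.exp(math.log(est) + Z95 * se)
    return OddsRatioResult(or_estimate=float(est), ci95=(lo, hi), correction_applied=corrected)


def fisher_exact(table: ContingencyTable2x2, sided: str = "two-sided") -> float:
    """Fisher exact p-value by hypergeometric enumeration over the margin-
    fixed support.

    ``sided``: "two-sided" (probability-mass criterion), "greater" (upper
    tail in tp: association of prediction-positive with reference-positive),
    or "less".
    """
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    n = table.total
    row1 = tp + fp  # prediction-positive margin
    col1 = tp + fn  # reference-positive margin
    rv = stats.hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    if sided == "greater":
        p = pmf[support >= tp].sum()
    elif sided == "less":
        p = pmf[support <= tp].sum()
    elif sided == "two-sided":
        # tables no more probable than the observed one (with a relative
        # epsilon guarding against floating-point ties on the pmf)
        p_obs = rv.pmf(tp)
        p = pmf[pmf <= p_obs * (1 + 1e-7)].sum()
    else:
        raise InputError(f"unknown sidedness {sided!r}")
    return float(min(1.0, p))


def chi_square(table: ContingencyTable2x2) -> Tuple[float, float]:
    """Pearson chi-square (no continuity correction, 1 df) -> (stat, p).

    Returns (nan, nan) when any margin is zero (statistic undefined).
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return (math.nan, math.nan)
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float


def cohens_kappa(ratings_a: Sequence, ratings_b: Sequence) -> KappaResult:
    """Chance-corrected agreement between two paired categorical ratings.

    po is the observed agreement fraction; pe the product-of-marginals
    chance agreement.  kappa = (po - pe) / (1 - pe).  Degenerate marginals
    (pe = 1) yield kappa = 1 when agreement is perfect and are otherwise an
    error.
    """
    a = pd.Series(list(ratings_a))
    b = pd.Series(list(ratings_b))
    if len(a) != len(b):
        raise InputError(f"rating vectors differ in length: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise InputError("rating vectors are empty")
    n = len(a)
    po = float((a.values == b.values).mean())
    labels = sorted(set(a) | set(b), key=str)
    pe = float(
        sum(
            (a == lab).sum() / n * (b == lab).sum() / n
            for lab in labels
        )
    )
    if pe >= 1.0 - 1e-12:
        if po >= 1.0 - 1e-12:
            return KappaResult(1.0, po, pe)
        raise InputError(
            "degenerate marginals (chance agreement = 1) with imperfect agreement"
        )
    return KappaResult(kappa=(po - pe) / (1 - pe), observed_agreement=po, expected_agreement=pe)


def concordance_count(calls: pd.Series, reference: pd.Series) -> int:
    """Number of patients whose call matches the reference label (aligned ids)."""
    calls, reference = pd.Series(calls), pd.Series(reference)
    call_ids, ref_ids = set(calls.index), set(reference.index)
    if call_ids != ref_ids:
        raise AlignmentError(call_ids - ref_ids, ref_ids - call_ids)
    reference = reference.loc[calls.index]
    return int((calls.values == reference.values).sum())
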