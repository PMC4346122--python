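"""Orchestration: modality-by-statistic diagnostic reports and predictor
combination.

``run_report`` takes a per-patient table of variant calls (one column per
assessment modality, values "tpv"/"fv"/NA) and a boolean amyloid-status
reference, and produces one report row per modality: N, cell counts,
accuracy, sensitivity/specificity/PPV/NPV with exact 95% CIs, odds ratio
and Fisher p.  Patients missing a modality are excluded pairwise for that
modality only, with a logged count — never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence

import pandas as pd
import yaml

from .errors import AlignmentError, InputError
from .kinetics import DEFAULT_T_STAR
from .metrics import (
    ContingencyTable2x2,
    build_contingency,
    fisher_exact,
    odds_ratio,
    performance,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat configuration for a full pipeline run."""

    features: Optional[str] = None
    uptake: Optional[str] = None
    controls: Optional[str] = None
    labels: Optional[str] = None
    tacs: Optional[str] = None
    t_star: float = DEFAULT_T_STAR
    dvr_threshold: float = 1.20
    positive_label: str = "tpv"
    ci_method: str = "clopper-pearson"
    round_percents: bool = False
    out_dir: str = "."
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from a flat key: value text file (YAML subset)."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def combine_predictors(
    calls_a: pd.Series, calls_b: pd.Series, rule: str = "both_positive"
) -> pd.Series:
    """Conjunction of two per-patient binary predictors (aligned ids):
    positive iff both are positive."""
    if rule != "both_positive":
        raise InputError(f"unknown combination rule {rule!r}")
    a, b = pd.Series(calls_a).astype(bool), pd.Series(calls_b).astype(bool)
    ids_a, ids_b = set(a.index), set(b.index)
    if ids_a != ids_b:
        raise AlignmentError(ids_a - ids_b, ids_b - ids_a)
    return a & b.loc[a.index]


def run_report(
    calls: pd.DataFrame,
    reference: pd.Series,
    modalities: Optional[Sequence[str]] = None,
    positive_label: str = "tpv",
    ci_method: str = "clopper-pearson",
    audit: bool = False,
):
    """Diagnostic-performance report, one row per modality.

    Parameters
    ----------
    calls : DataFrame indexed by patient id; each modality column holds the
        categorical call (``positive_label`` = predicted reference-positive)
        or NA when the modality was not acquired for that patient.
    reference : boolean Series indexed by patient id (True = PIB+).
    audit : also return ``{modality: {cell: [patient ids]}}`` so every
        report cell is traceable to its contributing patients.
    """
    reference = pd.Series(reference).astype(bool)
    if modalities is None:
        modalities = [c for c in calls.columns if c != "pib_positive"]
    rows = []
    trace: Dict[str, Dict[str, list]] = {}
    for modality in modalities:
        col = calls[modality]
        present = col.notna() & col.index.isin(reference.index)
        n_dropped = int((~col.notna()).sum())
        if n_dropped:
            logger.info(
                "%s: dropped %d patient(s) without this modality: %s",
                modality,
                n_dropped,
                list(col.index[~col.notna()]),
            )
        pred = col[present] == positive_label
        if pred.empty:
            raise InputError(
                f"modality {modality!r}: no patients overlap the reference"
            )
        ref = reference.loc[pred.index]
        table = build_contingency(pred, ref)
        rows.append(_report_row(modality, table, ci_method))
        if audit:
            trace[modality] = {
                "tp": sorted(pred.index[pred & ref]),
                "fp": sorted(pred.index[pred & ~ref]),
                "fn": sorted(pred.index[~pred & ref]),
                "tn": sorted(pred.index[~pred & ~ref]),
            }
    report = pd.DataFrame(rows).set_index("modality")
    return (report, trace) if audit else report


def _report_row(modality: str, t: ContingencyTable2x2, ci_method: str) -> dict:
    perf = performance(t, ci_method=ci_method)
    orr = odds_ratio(t)
    row = {
        "modality": modality,
        "n": t.total,
        "tn": t.tn,
        "tp": t.tp,
        "fn": t.fn,
        "fp": t.fp,
    }
    for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
        est = getattr(perf, name)
        row[name] = est.point
        row[f"{name}_ci_low"] = est.lower
        row[f"{name}_ci_high"] = est.upper
    row["odds_ratio"] = orr.or_estimate
    row["or_ci_low"], row["or_ci_high"] = orr.ci95
    row["or_corrected"] = orr.correction_applied
    row["fisher_p"] = fisher_exact(t, sided="two-sided")
    return row
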