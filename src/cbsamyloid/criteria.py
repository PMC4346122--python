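"""Rule-based clinical variant classification for corticobasal syndrome (CBS).

The engine screens patients against core CBS research criteria (progressive
course, >= 3 of 5 motor/sensory features, six absent exclusion features) and
splits eligible patients into a frontal variant (fvCBS) and a
temporoparietal variant (tpvCBS).  Each variant is met when at least one of
its characteristic features is present; a patient meeting both is
adjudicated deterministically, with the relative cognitive-impairment
profile (executive-predominant vs memory/visuospatial-predominant) as the
dominant tie-breaker, then the feature-count majority, then a frontal
default (non-AD pathology is the prior majority in CBS).

Every call carries a 1–5 confidence rating: 1 is the highest-confidence
frontal call, 5 the highest-confidence temporoparietal call, 3 the
maximally ambiguous default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import (
    CoreIneligibleError,
    ExclusivityError,
    MissingFieldError,
    NoVariantError,
)

FV = "fv"
TPV = "tpv"

CORE_FEATURES = (
    "parkinsonism",
    "dystonia",
    "myoclonus",
    "impaired_voluntary_limb_control",
    "cortical_sensory_deficit",
)
EXCLUSION_FEATURES = (
    "visual_hallucinations",
    "rbd",
    "cerebellar_ataxia",
    "autonomic_dysfunction",
    "fluctuating_alertness",
    "rest_tremor",
)
FV_FEATURES = (
    "nonfluent_or_motor_speech",
    "behavioral_change",
    "lower_extremity_apraxia",
    "executive_worse_than_mem_visuospatial",
)
TPV_FEATURES = (
    "logopenic_aphasia",
    "gerstmann_or_balint",
    "mem_visuospatial_worse_than_executive",
)
#: the two mutually exclusive cognitive-profile indicators
FV_COGNITIVE = "executive_worse_than_mem_visuospatial"
TPV_COGNITIVE = "mem_visuospatial_worse_than_executive"

FEATURE_COLUMNS = (
    ("progressive_course",)
    + CORE_FEATURES
    + EXCLUSION_FEATURES
    + FV_FEATURES
    + TPV_FEATURES
)

_BOOL_VALUES = {0: False, 1: True, False: False, True: True, "0": False, "1": True}


def _as_bool(value, field: str) -> bool:
    try:
        if isinstance(value, float) and np.isnan(value):
            raise KeyError
        return _BOOL_VALUES[value]
    except (KeyError, TypeError):
        raise MissingFieldError(
            field, f"value {value!r} is not a 0/1 indicator"
        ) from None


@dataclass(frozen=True)
class ClinicalFeatureSet:
    """One patient's criterion indicators; every field must be explicit."""

    patient_id: str
    progressive_course: bool
    parkinsonism: bool
    dystonia: bool
    myoclonus: bool
    impaired_voluntary_limb_control: bool
    cortical_sensory_deficit: bool
    visual_hallucinations: bool
    rbd: bool
    cerebellar_ataxia: bool
    autonomic_dysfunction: bool
    fluctuating_alertness: bool
    rest_tremor: bool
    nonfluent_or_motor_speech: bool
    behavioral_change: bool
    lower_extremity_apraxia: bool
    executive_worse_than_mem_visuospatial: bool
    logopenic_aphasia: bool
    gerstmann_or_balint: bool
    mem_visuospatial_worse_than_executive: bool

    def __post_init__(self):
        if (
            self.executive_worse_than_mem_visuospatial
            and self.mem_visuospatial_worse_than_executive
        ):
            raise ExclusivityError(
                f"patient {self.patient_id!r}: the executive-predominant and "
                "memory/visuospatial-predominant indicators are mutually "
                "exclusive but both set"
            )

    @classmethod
    def from_mapping(cls, row: Mapping) -> "ClinicalFeatureSet":
        """Build from a dict/Series; missing or non-0/1 fields are hard errors."""
        if "patient_id" not in row or pd.isna(row["patient_id"]):
            raise MissingFieldError("patient_id")
        kwargs = {"patient_id": str(row["patient_id"])}
        for name in FEATURE_COLUMNS:
            if name not in row:
                raise MissingFieldError(name, f"patient {row['patient_id']!r}")
            kwargs[name] = _as_bool(row[name], name)
        return cls(**kwargs)


@dataclass(frozen=True)
class CoreEligibility:
    eligible: bool
    n_core_features_met: int
    failed_exclusions: tuple


@dataclass(frozen=True)
class VariantCall:
    label: str  # "fv" | "tpv"
    met_fv: bool
    met_tpv: bool
    n_fv_met: int
    n_tpv_met: int
    adjudication_rule: str  # single_variant | cognitive_dominance | count_majority | default
    confidence: int  # 1 (highest-confidence fv) .. 5 (highest-confidence tpv)


def check_core(features: ClinicalFeatureSet) -> CoreEligibility:
    """Screen against core CBS criteria.

    Eligible iff the course is progressive, at least three of the five core
    motor/sensory features are present, and all six exclusion features are
    absent.
    """
    n_core = sum(getattr(features, f) for f in CORE_FEATURES)
    failed = tuple(f for f in EXCLUSION_FEATURES if getattr(features, f))
    eligible = features.progressive_course and n_core >= 3 and not failed
    return CoreEligibility(eligible, n_core, failed)


def evaluate_variants(features: ClinicalFeatureSet):
    """Count variant features; each variant is met when >= 1 is present.

    Raises :class:`CoreIneligibleError` if the patient fails core screening.
    """
    if not check_core(features).eligible:
        raise CoreIneligibleError(
            f"patient {features.patient_id!r} does not meet core CBS criteria"
        )
    n_fv = sum(getattr(features, f) for f in FV_FEATURES)
    n_tpv = sum(getattr(features, f) for f in TPV_FEATURES)
    return n_fv >= 1, n_fv, n_tpv >= 1, n_tpv


# (rule, label) -> confidence on the 1 (confident fv) .. 5 (confident tpv) scale
_CONFIDENCE = {
    ("single_variant", FV): 1,
    ("single_variant", TPV): 5,
    ("cognitive_dominance", FV): 2,
    ("cognitive_dominance", TPV): 4,
    ("count_majority", FV): 2,
    ("count_majority", TPV): 4,
    ("default", FV): 3,
}


def adjudicate(
    met_fv: bool,
    n_fv_met: int,
    met_tpv: bool,
    n_tpv_met: int,
    features: ClinicalFeatureSet,
) -> VariantCall:
    """Resolve the variant label deterministically.

    Precedence when both variants are met: the cognitive-profile criterion
    (dominant, being the only individually predictive feature class), then
    the majority of met features, then a frontal default at confidence 3.
    """
    if not (met_fv or met_tpv):
        raise NoVariantError(
            f"patient {features.patient_id!r} meets neither variant; no call possible"
        )
    if met_fv != met_tpv:
        rule = "single_variant"
        label = FV if met_fv else TPV
    elif getattr(features, FV_COGNITIVE) != getattr(features, TPV_COGNITIVE):
        rule = "cognitive_dominance"
        label = FV if getattr(features, FV_COGNITIVE) else TPV
    elif n_fv_met != n_tpv_met:
        rule = "count_majority"
        label = FV if n_fv_met > n_tpv_met else TPV
    else:
        rule = "default"
        label = FV
    return VariantCall(
        label=label,
        met_fv=met_fv,
        met_tpv=met_tpv,
        n_fv_met=n_fv_met,
        n_tpv_met=n_tpv_met,
        adjudication_rule=rule,
        confidence=_CONFIDENCE[(rule, label)],
    )


def classify_patient(features: ClinicalFeatureSet) -> VariantCall:
    """check_core -> evaluate_variants -> adjudicate, for one patient."""
    met_fv, n_fv, met_tpv, n_tpv = evaluate_variants(features)
    return adjudicate(met_fv, n_fv, met_tpv, n_tpv, features)


class CBSVariantClassifier(BaseEstimator, ClassifierMixin):
    """Deterministic fv/tpv classifier over a criterion-indicator table.

    A rule-based classifier with no learned state: ``fit`` only validates
    the column manifest so the estimator composes with sklearn pipelines.

    Parameters
    ----------
    on_ineligible : {"raise", "na"}
        Whether a row failing core CBS screening aborts ``predict`` or is
        emitted as a missing call (``predict_detail`` only; ``predict``
        always raises on ineligible rows since it must return labels).
    """

    def __init__(self, on_ineligible: str = "raise"):
        self.on_ineligible = on_ineligible

    def fit(self, X: pd.DataFrame, y=None):
        self._validate_columns(X)
        self.classes_ = np.array([FV, TPV])
        self.feature_names_in_ = np.asarray(list(FEATURE_COLUMNS), dtype=object)
        self.n_features_in_ = len(FEATURE_COLUMNS)
        return self

    @staticmethod
    def _validate_columns(X: pd.DataFrame):
        for name in ("patient_id",) + FEATURE_COLUMNS:
            if name not in X.columns:
                raise MissingFieldError(name, "column absent from feature table")

    def _rows(self, X: pd.DataFrame) -> Iterable[ClinicalFeatureSet]:
        self._validate_columns(X)
        for _, row in X.iterrows():
            yield ClinicalFeatureSet.from_mapping(row)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Variant label per row; ineligible rows raise."""
        return np.array([classify_patient(f).label for f in self._rows(X)])

    def predict_detail(self, X: pd.DataFrame) -> pd.DataFrame:
        """Full per-patient trace: eligibility, rule flags, counts, confidence."""
        records = []
        for feats in self._rows(X):
            core = check_core(feats)
            rec = {
                "patient_id": feats.patient_id,
                "core_eligible": core.eligible,
                "n_core_features_met": core.n_core_features_met,
                "failed_exclusions": ";".join(core.failed_exclusions),
            }
            call = None
            if core.eligible:
                try:
                    call = classify_patient(feats)
                except NoVariantError:
                    if self.on_ineligible != "na":
                        raise
            if call is not None:
                rec.update(
                    label=call.label,
                    met_fv=call.met_fv,
                    met_tpv=call.met_tpv,
                    n_fv_met=call.n_fv_met,
                    n_tpv_met=call.n_tpv_met,
                    adjudication_rule=call.adjudication_rule,
                    confidence=call.confidence,
                )
            elif self.on_ineligible == "na":
                rec.update(label=pd.NA, adjudication_rule=pd.NA, confidence=pd.NA)
            elif not core.eligible:
                raise CoreIneligibleError(
                    f"patient {feats.patient_id!r} does not meet core CBS criteria"
                )
            records.append(rec)
        return pd.DataFrame(records)

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.requires_fit = False
        return tags
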