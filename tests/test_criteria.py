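"""Clinical variant rule engine: core screening, variant evaluation and
deterministic adjudication, checked against an independent brute-force
oracle over every admissible variant-feature combination."""

import itertools

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cbsamyloid.criteria import (
    CBSVariantClassifier,
    CORE_FEATURES,
    ClinicalFeatureSet,
    EXCLUSION_FEATURES,
    FV_FEATURES,
    TPV_FEATURES,
    adjudicate,
    check_core,
    classify_patient,
    evaluate_variants,
)
from cbsamyloid.errors import (
    CoreIneligibleError,
    ExclusivityError,
    MissingFieldError,
    NoVariantError,
)

from conftest import make_features, variant_vectors


def fs(**overrides) -> ClinicalFeatureSet:
    return ClinicalFeatureSet.from_mapping(make_features(**overrides))


# --------------------------------------------------------------------------
# independent oracle: the adjudication contract restated as a flat decision
# list, evaluated without reusing any package code


def oracle_label(vec: dict) -> str:
    fv_set = [f for f in FV_FEATURES if vec[f]]
    tpv_set = [f for f in TPV_FEATURES if vec[f]]
    met_fv, met_tpv = bool(fv_set), bool(tpv_set)
    assert met_fv or met_tpv
    if met_fv and not met_tpv:
        return "fv"
    if met_tpv and not met_fv:
        return "tpv"
    exec_cog = vec["executive_worse_than_mem_visuospatial"]
    mem_cog = vec["mem_visuospatial_worse_than_executive"]
    if exec_cog and not mem_cog:
        return "fv"
    if mem_cog and not exec_cog:
        return "tpv"
    if len(fv_set) > len(tpv_set):
        return "fv"
    if len(tpv_set) > len(fv_set):
        return "tpv"
    return "fv"  # frontal default


# --------------------------------------------------------------------------
# core screening


def test_core_eligible_three_features():
    core = check_core(fs())
    assert core.eligible and core.n_core_features_met == 3
    assert core.failed_exclusions == ()


def test_core_threshold_boundary_two_features():
    row = make_features()
    row[CORE_FEATURES[2]] = 0
    core = check_core(ClinicalFeatureSet.from_mapping(row))
    assert not core.eligible and core.n_core_features_met == 2


def test_core_exclusion_feature_blocks():
    row = make_features(visual_hallucinations=1, **{f: 1 for f in CORE_FEATURES})
    core = check_core(ClinicalFeatureSet.from_mapping(row))
    assert not core.eligible
    assert core.failed_exclusions == ("visual_hallucinations",)
    assert core.n_core_features_met == 5


def test_core_requires_progressive_course():
    assert not check_core(fs(progressive_course=0)).eligible


def test_missing_field_is_named():
    row = make_features()
    del row["dystonia"]
    with pytest.raises(MissingFieldError, match="dystonia"):
        ClinicalFeatureSet.from_mapping(row)


def test_non_binary_value_rejected():
    with pytest.raises(MissingFieldError, match="myoclonus"):
        ClinicalFeatureSet.from_mapping(make_features(myoclonus=2))


def test_cognitive_profiles_mutually_exclusive():
    with pytest.raises(ExclusivityError):
        fs(
            executive_worse_than_mem_visuospatial=1,
            mem_visuospatial_worse_than_executive=1,
        )


# --------------------------------------------------------------------------
# variant evaluation


@pytest.mark.parametrize(
    "overrides, expect",
    [
        ({"logopenic_aphasia": 1}, (False, 0, True, 1)),
        ({"behavioral_change": 1}, (True, 1, False, 0)),
        (
            {"behavioral_change": 1, "mem_visuospatial_worse_than_executive": 1},
            (True, 1, True, 1),
        ),
    ],
)
def test_evaluate_variants_counts(overrides, expect):
    assert evaluate_variants(fs(**overrides)) == expect


def test_evaluate_variants_requires_core_eligibility():
    with pytest.raises(CoreIneligibleError):
        evaluate_variants(fs(progressive_course=0, behavioral_change=1))


def test_adjudicate_refuses_no_variant():
    feats = fs(behavioral_change=1)
    with pytest.raises(NoVariantError):
        adjudicate(False, 0, False, 0, feats)


# --------------------------------------------------------------------------
# adjudication vs the exhaustive oracle


def test_adjudication_matches_oracle_exhaustively():
    """Every admissible variant-feature vector gets the oracle's label, a
    consistent rule trace and a confidence consistent with the label."""
    seen_rules = set()
    for vec in variant_vectors():
        if not any(vec.values()):
            continue
        call = classify_patient(fs(**vec))
        assert call.label == oracle_label(vec), vec
        assert call.met_fv == (call.n_fv_met >= 1)
        assert call.met_tpv == (call.n_tpv_met >= 1)
        if call.label == "fv":
            assert call.confidence <= 3
        else:
            assert call.confidence >= 3
        seen_rules.add(call.adjudication_rule)
    assert seen_rules == {
        "single_variant",
        "cognitive_dominance",
        "count_majority",
        "default",
    }


@pytest.mark.parametrize(
    "overrides, label, rule, confidence",
    [
        ({"logopenic_aphasia": 1}, "tpv", "single_variant", 5),
        ({"behavioral_change": 1}, "fv", "single_variant", 1),
        (
            {"behavioral_change": 1, "mem_visuospatial_worse_than_executive": 1},
            "tpv",
            "cognitive_dominance",
            4,
        ),
        (
            {
                "behavioral_change": 1,
                "nonfluent_or_motor_speech": 1,
                "logopenic_aphasia": 1,
            },
            "fv",
            "count_majority",
            2,
        ),
        (
            {"behavioral_change": 1, "logopenic_aphasia": 1},
            "fv",
            "default",
            3,
        ),
    ],
)
def test_adjudication_examples(overrides, label, rule, confidence):
    call = classify_patient(fs(**overrides))
    assert (call.label, call.adjudication_rule, call.confidence) == (
        label,
        rule,
        confidence,
    )


def test_cognitive_criterion_dominates_tiebreak():
    """On a both-met patient, flipping only the cognitive profile flips the
    label: it outranks the count majority."""
    base = {
        "behavioral_change": 1,
        "nonfluent_or_motor_speech": 1,
        "logopenic_aphasia": 1,
    }
    fv_call = classify_patient(
        fs(executive_worse_than_mem_visuospatial=1, **base)
    )
    tpv_call = classify_patient(
        fs(mem_visuospatial_worse_than_executive=1, **base)
    )
    assert (fv_call.label, tpv_call.label) == ("fv", "tpv")
    # count majority alone would say fv (3 fv features vs 2 tpv)
    assert tpv_call.adjudication_rule == "cognitive_dominance"


def test_monotonicity_exhaustive():
    """Adding one more tpv feature never flips a tpv call to fv, and
    symmetrically for fv."""
    for vec in variant_vectors():
        if not any(vec.values()):
            continue
        label = classify_patient(fs(**vec)).label
        pool = TPV_FEATURES if label == "tpv" else FV_FEATURES
        blocker = (
            "executive_worse_than_mem_visuospatial"
            if label == "tpv"
            else "mem_visuospatial_worse_than_executive"
        )
        for feat in pool:
            if vec[feat] or vec[blocker] and feat in (
                "mem_visuospatial_worse_than_executive",
                "executive_worse_than_mem_visuospatial",
            ):
                continue
            assert classify_patient(fs(**{**vec, feat: 1})).label == label


@settings(derandomize=True, max_examples=200)
@given(bits=st.tuples(*[st.booleans()] * 13))
def test_determinism_and_totality(bits):
    """Identical inputs give identical calls; every core-eligible patient
    with at least one variant feature gets a call without raising."""
    core_bits = dict(zip(CORE_FEATURES, bits[:5]))
    variant_bits = dict(zip(FV_FEATURES + TPV_FEATURES, bits[5:12]))
    if (
        variant_bits["executive_worse_than_mem_visuospatial"]
        and variant_bits["mem_visuospatial_worse_than_executive"]
    ):
        variant_bits["mem_visuospatial_worse_than_executive"] = 0
    row = make_features(progressive_course=int(bits[12]), **core_bits, **variant_bits)
    row.update(core_bits)
    feats = ClinicalFeatureSet.from_mapping(row)
    core = check_core(feats)
    if not core.eligible:
        with pytest.raises(CoreIneligibleError):
            evaluate_variants(feats)
        return
    if not any(variant_bits.values()):
        with pytest.raises(NoVariantError):
            classify_patient(feats)
        return
    assert classify_patient(feats) == classify_patient(feats)
    assert classify_patient(feats).label in ("fv", "tpv")


# --------------------------------------------------------------------------
# sklearn estimator surface


def test_classifier_predict_and_detail(features_frame):
    clf = CBSVariantClassifier().fit(features_frame)
    assert list(clf.predict(features_frame)) == ["fv", "tpv", "tpv"]
    detail = clf.predict_detail(features_frame)
    assert list(detail["adjudication_rule"]) == [
        "single_variant",
        "single_variant",
        "cognitive_dominance",
    ]
    assert list(detail["confidence"]) == [1, 5, 4]


def test_classifier_na_mode_for_ineligible(features_frame):
    df = features_frame.copy()
    df.loc[0, "progressive_course"] = 0
    detail = CBSVariantClassifier(on_ineligible="na").fit(df).predict_detail(df)
    assert pd.isna(detail.loc[0, "label"]) and not detail.loc[0, "core_eligible"]
    with pytest.raises(CoreIneligibleError):
        CBSVariantClassifier(on_ineligible="raise").fit(df).predict_detail(df)


def test_classifier_sklearn_params_roundtrip(features_frame):
    clf = CBSVariantClassifier(on_ineligible="na")
    assert clf.get_params() == {"on_ineligible": "na"}
    clf.set_params(on_ineligible="raise")
    assert clf.on_ineligible == "raise"
    assert list(clf.fit(features_frame).classes_) == ["fv", "tpv"]
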