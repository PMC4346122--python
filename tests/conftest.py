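import itertools

import pandas as pd
import pytest

from cbsamyloid.criteria import (
    CORE_FEATURES,
    EXCLUSION_FEATURES,
    FEATURE_COLUMNS,
    FV_FEATURES,
    TPV_FEATURES,
)


def make_features(patient_id="p1", **overrides):
    """A fully explicit criterion-indicator mapping: progressive, three core
    features, everything else absent, unless overridden."""
    row = {name: 0 for name in FEATURE_COLUMNS}
    row["patient_id"] = patient_id
    row["progressive_course"] = 1
    for f in CORE_FEATURES[:3]:
        row[f] = 1
    row.update(overrides)
    return row


def variant_vectors():
    """All 2^7 fv/tpv feature combinations that satisfy the cognitive-profile
    exclusivity constraint (96 vectors)."""
    names = FV_FEATURES + TPV_FEATURES
    for bits in itertools.product((0, 1), repeat=len(names)):
        vec = dict(zip(names, bits))
        if (
            vec["executive_worse_than_mem_visuospatial"]
            and vec["mem_visuospatial_worse_than_executive"]
        ):
            continue
        yield vec


@pytest.fixture(scope="session")
def small_cohort():
    from cbsamyloid.simulate import CohortSpec, generate_cohort

    return generate_cohort(
        CohortSpec(n_pib_pos=8, n_pib_neg=10, n_controls=12, seed=7),
        include_tacs=True,
    )


@pytest.fixture
def features_frame():
    rows = [
        make_features("a", behavioral_change=1),
        make_features("b", logopenic_aphasia=1),
        make_features("c", behavioral_change=1, mem_visuospatial_worse_than_executive=1),
    ]
    return pd.DataFrame(rows)
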