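"""Reference fixtures: published summary counts for a 25-patient CBS cohort.

These are the group-level results the validation suite reproduces — the
per-modality contingency counts of variant calls against amyloid (PIB) PET
status, APOE-e4 carrier counts, and the eight-patient histopathology
subset.  Patient-level call vectors are reconstructed from the counts:
within each amyloid stratum individual assignments are exchangeable, so
any assignment reproducing the counts yields identical downstream
statistics; the reconstruction here is deterministic.
"""

from __future__ import annotations

from typing import Dict

import pandas as pd

from .metrics import ContingencyTable2x2

#: variant-call vs PIB-status counts per assessment modality
#: (tp = tpv call in a PIB+ patient, tn = fv call in a PIB- patient)
MODALITY_TABLES: Dict[str, ContingencyTable2x2] = {
    "criteria": ContingencyTable2x2(tp=9, fp=4, fn=2, tn=10),
    "fdg_visual": ContingencyTable2x2(tp=10, fp=6, fn=1, tn=6),
    "fdg_quant": ContingencyTable2x2(tp=9, fp=5, fn=1, tn=7),
    "mri": ContingencyTable2x2(tp=8, fp=7, fn=3, tn=6),
}

#: APOE-e4 carriage vs PIB status in the genotyped subset (10 + 10):
#: 6/10 PIB+ carriers, 1/10 PIB- carriers
APOE_TABLE = ContingencyTable2x2(tp=6, fp=1, fn=4, tn=9)

N_PIB_POS = 11
N_PIB_NEG = 14


def modality_calls() -> pd.DataFrame:
    """Per-patient call table consistent with every modality's counts.

    Returns one row per patient: ``patient_id``, ``pib_positive`` (bool)
    and one column per modality holding "tpv", "fv" or NA (modality not
    acquired).  Cross-tabulating any modality column against
    ``pib_positive`` reproduces :data:`MODALITY_TABLES` exactly.
    """
    ids = [f"p{i:02d}" for i in range(1, N_PIB_POS + N_PIB_NEG + 1)]
    pib = [True] * N_PIB_POS + [False] * N_PIB_NEG
    df = pd.DataFrame({"patient_id": ids, "pib_positive": pib}).set_index(
        "patient_id"
    )
    pos_ids = df.index[df["pib_positive"]]
    neg_ids = df.index[~df["pib_positive"]]
    for name, t in MODALITY_TABLES.items():
        n_pos, n_neg = t.tp + t.fn, t.fp + t.tn
        col = pd.Series(pd.NA, index=df.index, dtype="object")
        # earliest ids get the modality; within stratum, tpv calls first
        col[pos_ids[: t.tp]] = "tpv"
        col[pos_ids[t.tp : n_pos]] = "fv"
        col[neg_ids[: t.fp]] = "tpv"
        col[neg_ids[t.fp : n_neg]] = "fv"
        df[name] = col
    return df


def pathology_cohort() -> pd.DataFrame:
    """The eight patients with autopsy (7) or biopsy (1) confirmation.

    ``ad_pathology`` groups the histological diagnosis into AD-containing
    vs non-AD.  Calls are "tpv"/"fv"; one MRI entry is missing.
    """
    rows = [
        ("pt02", False, "CBD", False, "fv", "tpv", "tpv", "fv"),
        ("pt03", False, "CBD", False, "fv", "fv", "fv", "fv"),
        ("pt08", False, "CBD", False, "tpv", "tpv", "tpv", pd.NA),
        ("pt10", False, "PSP", False, "fv", "fv", "fv", "tpv"),
        ("pt14", False, "Pick's + DLB", False, "tpv", "fv", "fv", "fv"),
        ("pt13", True, "AD + CBD", True, "tpv", "tpv", "tpv", "tpv"),
        ("pt18", True, "AD + DLB", True, "tpv", "tpv", "tpv", "tpv"),
        ("pt19", True, "AD + DLB", True, "tpv", "tpv", "tpv", "fv"),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "pib_positive",
            "pathology",
            "ad_pathology",
            "criteria",
            "fdg_visual",
            "fdg_quant",
            "mri",
        ],
    ).set_index("patient_id")
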