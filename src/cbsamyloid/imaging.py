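"""Quantitative PET measures: SUVR, control-referenced Z-scores,
Z-difference, lateralization index and amyloid-positivity thresholding.

FDG uptake in each cortical region of interest (ROI) is expressed as a
standardized uptake value ratio (SUVR) against mean pons activity, then
converted to a Z-score against a normal-control cohort.  Hypometabolism is
negative; "lowest Z" means most negative.  A patient is classified as
temporoparietal-variant when the bilateral temporoparietal Z lies below the
bilateral frontal Z, frontal-variant otherwise (exact ties resolve to
frontal, consistent with the clinical engine's default).  Hemispheric
asymmetry is summarized per ROI as the lateralization index
``|right/left - 1| * 100`` (percent).

Amyloid (PIB) status from a global distribution volume ratio uses the
conventional inclusive threshold DVR >= 1.20.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from .errors import (
    DegenerateReferenceError,
    InputError,
    InvalidReferenceError,
    InvalidUptakeError,
    MissingFieldError,
)

ROIS = ("frontal", "temporoparietal", "common")
SIDES = ("left", "right")
REFERENCE_ROI = "pons"
#: default global PIB DVR cutoff for amyloid positivity (inclusive)
PIB_DVR_THRESHOLD = 1.20

UPTAKE_COLUMNS = ("patient_id", "roi", "side", "mean_uptake")


def compute_suvr(roi_mean: float, pons_mean: float) -> float:
    """Standardized uptake value ratio: regional mean over pons mean."""
    if pons_mean <= 0:
        raise InvalidReferenceError(f"pons mean must be > 0, got {pons_mean}")
    if roi_mean <= 0:
        raise InvalidUptakeError(f"ROI mean must be > 0, got {roi_mean}")
    return roi_mean / pons_mean


def compute_z(suvr: float, control_mean: float, control_sd: float) -> float:
    """Control-referenced Z-score; negative = hypometabolic vs controls."""
    if control_sd <= 0:
        raise DegenerateReferenceError(
            f"control SD must be > 0, got {control_sd}"
        )
    return (suvr - control_mean) / control_sd


def z_difference(z_frontal: float, z_temporoparietal: float) -> float:
    """Z(frontal) - Z(temporoparietal); positive = temporoparietal-predominant
    hypometabolism."""
    return z_frontal - z_temporoparietal


def classify_fdg_quant(z_frontal: float, z_temporoparietal: float) -> str:
    """"tpv" iff the temporoparietal Z is strictly lower (more hypometabolic)
    than the frontal Z, else "fv" (ties -> "fv")."""
    return "tpv" if z_temporoparietal < z_frontal else "fv"


def lateralization_index(right: float, left: float) -> float:
    """Percent hemispheric asymmetry, ``|right/left - 1| * 100``.

    Note the ratio is anchored on the left side: LI(right, left) and
    LI(left, right) differ in general (e.g. 1.1/1.0 -> 10.0 but
    1.0/1.1 -> 9.09).
    """
    if right <= 0 or left <= 0:
        raise InvalidUptakeError(
            f"uptakes must be > 0, got right={right}, left={left}"
        )
    return abs(right / left - 1.0) * 100.0


@dataclass(frozen=True)
class PibCall:
    """Amyloid status for one patient, from a visual read or a DVR cutoff."""

    patient_id: str
    positive: bool
    source: str  # "visual_input" | "dvr_threshold"
    global_dvr: Optional[float] = None


def classify_pib_quant(
    patient_id: str, global_dvr: float, threshold: float = PIB_DVR_THRESHOLD
) -> PibCall:
    """Positive iff global DVR >= threshold (inclusive boundary)."""
    if global_dvr <= 0:
        raise InvalidUptakeError(f"global DVR must be > 0, got {global_dvr}")
    return PibCall(
        patient_id=patient_id,
        positive=bool(global_dvr >= threshold),
        source="dvr_threshold",
        global_dvr=global_dvr,
    )


# ---------------------------------------------------------------------------
# Tabular containers


def _validate_long_table(df: pd.DataFrame, what: str) -> pd.DataFrame:
    for col in UPTAKE_COLUMNS:
        if col not in df.columns:
            raise MissingFieldError(col, f"{what} table")
    bad_roi = set(df["roi"]) - set(ROIS) - {REFERENCE_ROI}
    if bad_roi:
        raise InputError(f"{what} table: unknown ROI names {sorted(bad_roi)}")
    if (df["mean_uptake"] <= 0).any() or df["mean_uptake"].isna().any():
        offenders = df.loc[
            (df["mean_uptake"] <= 0) | df["mean_uptake"].isna(), "patient_id"
        ].unique()
        raise InvalidUptakeError(
            f"{what} table: non-positive/missing uptake for patients {list(offenders)}"
        )
    return df


def suvr_table(long_df: pd.DataFrame, what: str = "uptake") -> pd.DataFrame:
    """Long (patient_id, roi, side, mean_uptake) table -> wide per-patient SUVR.

    Output: one row per patient, columns ``{roi}_{side}`` and
    ``{roi}_bilateral`` (mean of left and right SUVR) for the three cortical
    ROIs, normalized to each patient's mean pons activity.
    """
    long_df = _validate_long_table(long_df, what)
    out = {}
    for pid, grp in long_df.groupby("patient_id", sort=True):
        pons_rows = grp.loc[grp["roi"] == REFERENCE_ROI, "mean_uptake"]
        if pons_rows.empty:
            raise MissingFieldError(
                REFERENCE_ROI, f"patient {pid!r} has no pons reference row"
            )
        pons = float(pons_rows.mean())
        row: Dict[str, float] = {}
        for roi in ROIS:
            for side in SIDES:
                sel = grp.loc[
                    (grp["roi"] == roi) & (grp["side"] == side), "mean_uptake"
                ]
                if sel.empty:
                    raise MissingFieldError(
                        f"{roi}/{side}", f"patient {pid!r} uptake row absent"
                    )
                row[f"{roi}_{side}"] = compute_suvr(float(sel.mean()), pons)
            row[f"{roi}_bilateral"] = (
                row[f"{roi}_left"] + row[f"{roi}_right"]
            ) / 2.0
        out[str(pid)] = row
    wide = pd.DataFrame.from_dict(out, orient="index")
    wide.index.name = "patient_id"
    return wide


@dataclass(frozen=True)
class ControlReference:
    """Per-ROI, per-side control SUVR mean and SD (sample SD, ddof=1)."""

    stats: pd.DataFrame  # index: roi_side column labels; columns: mean, sd
    n_controls: int

    def __post_init__(self):
        if self.n_controls < 2:
            raise DegenerateReferenceError(
                f"need >= 2 controls, got {self.n_controls}"
            )
        if (self.stats["sd"] <= 0).any():
            bad = self.stats.index[self.stats["sd"] <= 0].tolist()
            raise DegenerateReferenceError(f"zero-variance control ROI(s): {bad}")

    @classmethod
    def from_table(cls, control_long_df: pd.DataFrame) -> "ControlReference":
        wide = suvr_table(control_long_df, what="control")
        stats = pd.DataFrame(
            {"mean": wide.mean(axis=0), "sd": wide.std(axis=0, ddof=1)}
        )
        return cls(stats=stats, n_controls=len(wide))

    def zscore(self, suvr_wide: pd.DataFrame) -> pd.DataFrame:
        """Z-score a wide SUVR table column-by-column against the reference."""
        missing = [c for c in suvr_wide.columns if c not in self.stats.index]
        if missing:
            raise MissingFieldError(
                ", ".join(missing), "no control statistics for these ROIs"
            )
        mu = self.stats.loc[suvr_wide.columns, "mean"]
        sd = self.stats.loc[suvr_wide.columns, "sd"]
        return (suvr_wide - mu) / sd


@dataclass(frozen=True)
class ZProfile:
    """One patient's Z-scores, Z-difference, asymmetry and quantitative label."""

    patient_id: str
    z: Mapping[Tuple[str, str], float]  # (roi, side|bilateral) -> Z
    z_diff: float
    li: Mapping[str, float]  # roi -> percent asymmetry
    quant_label: str  # "fv" | "tpv"


class FDGQuantClassifier(BaseEstimator, ClassifierMixin, TransformerMixin):
    """Control-referenced ROI Z-score classifier for FDG-PET.

    ``fit`` learns per-ROI, per-hemisphere control SUVR statistics from a
    long-format control uptake table; ``transform`` converts patient uptake
    tables to Z-profiles (Z per ROI/side, Z-difference, lateralization
    indices); ``predict`` labels each patient "tpv" when the bilateral
    temporoparietal Z is below the bilateral frontal Z, else "fv".  The
    peri-rolandic "common" ROI is profiled but excluded from the variant
    decision (it is by definition shared across variants).
    """

    def fit(self, X: pd.DataFrame, y=None):
        """X: long control uptake table (patient_id, roi, side, mean_uptake)."""
        self.control_reference_ = ControlReference.from_table(X)
        self.classes_ = np.array(["fv", "tpv"])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-patient Z-profile table.

        Columns: ``z_{roi}_{left,right,bilateral}`` for the three ROIs,
        ``z_difference`` (bilateral frontal minus bilateral temporoparietal)
        and ``li_{roi}`` percent asymmetry.
        """
        self._check_fitted()
        suvr = suvr_table(X)
        z = self.control_reference_.zscore(suvr)
        out = z.rename(columns=lambda c: f"z_{c}")
        out["z_difference"] = z["frontal_bilateral"] - z["temporoparietal_bilateral"]
        for roi in ROIS:
            out[f"li_{roi}"] = [
                lateralization_index(r, l)
                for r, l in zip(suvr[f"{roi}_right"], suvr[f"{roi}_left"])
            ]
        return out

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        zp = self.transform(X)
        return np.array(
            [
                classify_fdg_quant(zf, zt)
                for zf, zt in zip(
                    zp["z_frontal_bilateral"], zp["z_temporoparietal_bilateral"]
                )
            ]
        )

    def zprofiles(self, X: pd.DataFrame) -> Dict[str, ZProfile]:
        """Structured :class:`ZProfile` per patient (keyed by patient_id)."""
        zp = self.transform(X)
        profiles = {}
        for pid, row in zp.iterrows():
            zmap = {
                (roi, side): float(row[f"z_{roi}_{side}"])
                for roi in ROIS
                for side in ("left", "right", "bilateral")
            }
            profiles[pid] = ZProfile(
                patient_id=str(pid),
                z=zmap,
                z_diff=float(row["z_difference"]),
                li={roi: float(row[f"li_{roi}"]) for roi in ROIS},
                quant_label=classify_fdg_quant(
                    zmap[("frontal", "bilateral")],
                    zmap[("temporoparietal", "bilateral")],
                ),
            )
        return profiles

    def _check_fitted(self):
        if not hasattr(self, "control_reference_"):
            raise RuntimeError(
                "FDGQuantClassifier must be fit on a control table first"
            )
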