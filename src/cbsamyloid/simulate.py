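"""Synthetic cohorts for end-to-end validation of the pipeline.

The generator emulates the data structure the analysis assumes — a patient
cohort split into amyloid-positive (PIB+) and amyloid-negative (PIB-)
groups plus a normal-control imaging cohort — without modelling images:

* ROI Z-scores are drawn per group directly in control-SD units (Gaussian,
  independent across ROIs) and inverted to uptake values against the
  *generated* control reference, so re-running the quantification pipeline
  recovers the drawn Z exactly.  Default group means/SDs are the published
  group-level FDG ROI Z statistics for CBS-PIB+ and CBS-PIB- cohorts.
* Hemispheric asymmetry is injected by splitting each bilateral SUVR into
  left/right at a half-normal percent-asymmetry magnitude with a random
  lateralized side, preserving the bilateral mean exactly.
* Clinical criterion indicators are Bernoulli draws at per-group
  prevalences (the defaults are synthetic design choices, not published
  rates), with the two mutually exclusive cognitive-profile indicators
  drawn from a single three-way categorical.  Every patient is
  core-eligible by construction.
* Time-activity-curve pairs with known ground-truth DVR come from a
  one-tissue compartment model driven by a bi-exponential reference curve,
  solved in closed form, so the Logan estimator can be validated against
  exact kinetics.

All randomness flows through a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import SpecError
from .imaging import ControlReference, ROIS
from .kinetics import TimeActivityCurve

#: published group-level ROI Z-score (mean, SD) in control-SD units
DEFAULT_Z_PARAMS: Dict[str, Dict[str, Tuple[float, float]]] = {
    "pib_pos": {
        "frontal": (-1.26, 0.91),
        "temporoparietal": (-2.76, 1.65),
        "common": (-1.89, 0.81),
    },
    "pib_neg": {
        "frontal": (-1.06, 1.61),
        "temporoparietal": (-0.93, 1.65),
        "common": (-1.69, 1.37),
    },
}

#: published group-mean percent lateralization index per ROI
DEFAULT_LI_MEANS: Dict[str, Dict[str, float]] = {
    "pib_pos": {"frontal": 6.53, "temporoparietal": 13.10, "common": 10.42},
    "pib_neg": {"frontal": 10.52, "temporoparietal": 8.45, "common": 8.82},
    "control": {"frontal": 1.70, "temporoparietal": 2.00, "common": 2.83},
}

#: control pons-normalized FDG SUVR (mean, SD) per ROI — synthetic choice,
#: cortical FDG uptake runs somewhat above pons
DEFAULT_CONTROL_SUVR: Dict[str, Tuple[float, float]] = {
    "frontal": (1.45, 0.10),
    "temporoparietal": (1.40, 0.10),
    "common": (1.50, 0.10),
}

#: per-group clinical-feature prevalences — synthetic design choices (no
#: published per-criterion rates exist); the memory/visuospatial-predominant
#: cognitive profile is enriched in PIB+ and the executive-predominant
#: profile in PIB-, so the criteria engine's discrimination is exercised.
DEFAULT_PREVALENCES: Dict[str, Dict[str, float]] = {
    "pib_pos": {
        "nonfluent_or_motor_speech": 0.20,
        "behavioral_change": 0.30,
        "lower_extremity_apraxia": 0.20,
        "executive_worse_than_mem_visuospatial": 0.15,
        "logopenic_aphasia": 0.40,
        "gerstmann_or_balint": 0.40,
        "mem_visuospatial_worse_than_executive": 0.60,
    },
    "pib_neg": {
        "nonfluent_or_motor_speech": 0.45,
        "behavioral_change": 0.55,
        "lower_extremity_apraxia": 0.30,
        "executive_worse_than_mem_visuospatial": 0.55,
        "logopenic_aphasia": 0.20,
        "gerstmann_or_balint": 0.25,
        "mem_visuospatial_worse_than_executive": 0.15,
    },
}

_CORE = (
    "parkinsonism",
    "dystonia",
    "myoclonus",
    "impaired_voluntary_limb_control",
    "cortical_sensory_deficit",
)
_EXCLUSIONS = (
    "visual_hallucinations",
    "rbd",
    "cerebellar_ataxia",
    "autonomic_dysfunction",
    "fluctuating_alertness",
    "rest_tremor",
)
_FV_COG = "executive_worse_than_mem_visuospatial"
_TPV_COG = "mem_visuospatial_worse_than_executive"


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters for one synthetic cohort."""

    n_pib_pos: int = 11
    n_pib_neg: int = 14
    n_controls: int = 26
    z_params: Mapping = field(default_factory=lambda: DEFAULT_Z_PARAMS)
    li_means: Mapping = field(default_factory=lambda: DEFAULT_LI_MEANS)
    control_suvr: Mapping = field(default_factory=lambda: DEFAULT_CONTROL_SUVR)
    prevalences: Mapping = field(default_factory=lambda: DEFAULT_PREVALENCES)
    core_prevalence: float = 0.7
    pons_mean: float = 100.0  # raw tracer units; cancels in SUVR
    pons_sd: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_pib_pos, self.n_pib_neg) < 0 or self.n_controls < 2:
            raise SpecError("group sizes must be >= 0 (>= 2 controls)")
        for grp, prev in self.prevalences.items():
            for name, p in prev.items():
                if not 0 <= p <= 1:
                    raise SpecError(f"{grp}/{name}: prevalence {p} outside [0, 1]")
            if prev[_FV_COG] + prev[_TPV_COG] > 1:
                raise SpecError(
                    f"{grp}: prevalences of the mutually exclusive cognitive "
                    "profiles sum above 1"
                )
        for grp, rois in self.z_params.items():
            for roi, (_, sd) in rois.items():
                if sd <= 0:
                    raise SpecError(f"{grp}/{roi}: Z SD must be > 0")


@dataclass
class SyntheticCohort:
    features: pd.DataFrame  # per-patient criterion indicators
    uptake: pd.DataFrame  # long patient ROI uptake table
    controls: pd.DataFrame  # long control ROI uptake table
    labels: pd.DataFrame  # patient_id, group, pib_positive, global_dvr
    control_reference: ControlReference
    true_z: pd.DataFrame  # drawn bilateral Z per ROI (ground truth)
    tacs: Optional[Dict[str, Tuple[TimeActivityCurve, TimeActivityCurve, float]]] = None

    def write_csvs(self, out_dir) -> None:
        """Write features.csv / uptake.csv / controls.csv / labels.csv (and
        tacs/<patient>.csv) in the schemas the pipeline readers expect."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.features.to_csv(out / "features.csv", index=False)
        self.uptake.to_csv(out / "uptake.csv", index=False)
        self.controls.to_csv(out / "controls.csv", index=False)
        self.labels.to_csv(out / "labels.csv", index=False)
        if self.tacs:
            tac_dir = out / "tacs"
            tac_dir.mkdir(exist_ok=True)
            for pid, (target, reference, true_dvr) in self.tacs.items():
                df = pd.DataFrame(
                    {
                        "mid_time_min": target.times,
                        "target_activity": target.activity,
                        "reference_activity": reference.activity,
                    }
                )
                df.attrs["true_dvr"] = true_dvr
                df.to_csv(tac_dir / f"{pid}.csv", index=False)


def _split_bilateral(rng, bilateral: float, li_mean_pct: float) -> Tuple[float, float]:
    """Split a bilateral mean into (left, right) with half-normal percent
    asymmetry of the given mean magnitude and a random lateralized side."""
    li = abs(rng.normal(0.0, li_mean_pct * np.sqrt(np.pi / 2))) / 100.0
    ratio = 1.0 + li  # right/left
    if rng.random() < 0.5:
        ratio = 1.0 / ratio
    left = 2.0 * bilateral / (1.0 + ratio)
    return left, left * ratio


def _uptake_rows(pid: str, suvr_by_roi_side: Mapping, pons: float):
    rows = [
        {"patient_id": pid, "roi": "pons", "side": "left", "mean_uptake": pons},
        {"patient_id": pid, "roi": "pons", "side": "right", "mean_uptake": pons},
    ]
    for (roi, side), suvr in suvr_by_roi_side.items():
        rows.append(
            {"patient_id": pid, "roi": roi, "side": side, "mean_uptake": suvr * pons}
        )
    return rows


def _draw_features(rng, pid: str, prev: Mapping) -> Dict:
    rec: Dict = {"patient_id": pid, "progressive_course": 1}
    for name in _EXCLUSIONS:
        rec[name] = 0
    # variant features; rejection-sample so every patient meets at least one
    # variant (the cohort structure the analysis assumes), keeping the
    # conditional feature distribution intact
    while True:
        # the two cognitive profiles share one categorical draw
        p_fv, p_tpv = prev[_FV_COG], prev[_TPV_COG]
        u = rng.random()
        rec[_FV_COG] = int(u < p_fv)
        rec[_TPV_COG] = int(p_fv <= u < p_fv + p_tpv)
        for name, p in prev.items():
            if name in (_FV_COG, _TPV_COG):
                continue
            rec[name] = int(rng.random() < p)
        if any(rec[name] for name in prev):
            return rec


def generate_cohort(spec: CohortSpec, include_tacs: bool = False) -> SyntheticCohort:
    """Draw one reproducible cohort from the study-condition spec."""
    rng = np.random.default_rng(spec.seed)

    # --- controls -----------------------------------------------------------
    control_rows = []
    for i in range(spec.n_controls):
        cid = f"c{i + 1:03d}"
        pons = max(1e-6, rng.normal(spec.pons_mean, spec.pons_sd))
        suvrs = {}
        for roi in ROIS:
            mu, sd = spec.control_suvr[roi]
            bilateral = rng.normal(mu, sd)
            if bilateral <= 0:
                raise SpecError(f"control SUVR draw non-positive for {roi}")
            left, right = _split_bilateral(rng, bilateral, spec.li_means["control"][roi])
            suvrs[(roi, "left")], suvrs[(roi, "right")] = left, right
        control_rows.extend(_uptake_rows(cid, suvrs, pons))
    controls = pd.DataFrame(control_rows)
    reference = ControlReference.from_table(controls)

    # --- patients -----------------------------------------------------------
    feature_rows, uptake_rows, label_rows, z_rows = [], [], [], []
    groups = [("pib_pos", spec.n_pib_pos, True), ("pib_neg", spec.n_pib_neg, False)]
    idx = 0
    for group, n, positive in groups:
        for _ in range(n):
            idx += 1
            pid = f"p{idx:04d}"
            # imaging: bilateral Z drawn per ROI, inverted to SUVR against the
            # generated control reference
            suvrs, zs = {}, {"patient_id": pid, "group": group}
            for roi in ROIS:
                mu, sd = spec.z_params[group][roi]
                z = rng.normal(mu, sd)
                ref_mu = reference.stats.loc[f"{roi}_bilateral", "mean"]
                ref_sd = reference.stats.loc[f"{roi}_bilateral", "sd"]
                bilateral = ref_mu + z * ref_sd
                if bilateral <= 0:
                    raise SpecError(
                        f"drawn Z {z:.2f} for {roi} implies non-positive SUVR; "
                        "spec infeasible against this control scale"
                    )
                left, right = _split_bilateral(
                    rng, bilateral, spec.li_means[group][roi]
                )
                suvrs[(roi, "left")], suvrs[(roi, "right")] = left, right
                zs[f"z_{roi}"] = z
            pons = max(1e-6, rng.normal(spec.pons_mean, spec.pons_sd))
            uptake_rows.extend(_uptake_rows(pid, suvrs, pons))
            z_rows.append(zs)

            # clinical features
            rec = _draw_features(rng, pid, spec.prevalences[group])
            core = [int(rng.random() < spec.core_prevalence) for _ in _CORE]
            while sum(core) < 3:  # core eligibility by construction
                core[rng.integers(len(core))] = 1
            rec.update(dict(zip(_CORE, core)))
            feature_rows.append(rec)

            # global amyloid DVR consistent with the group label (synthetic
            # scale around the 1.20 positivity threshold)
            if positive:
                global_dvr = 1.25 + 1.1 * rng.random()
            else:
                global_dvr = 0.95 + 0.20 * rng.random()
            label_rows.append(
                {
                    "patient_id": pid,
                    "group": group,
                    "pib_positive": int(positive),
                    "global_dvr": round(global_dvr, 4),
                }
            )

    cohort = SyntheticCohort(
        features=pd.DataFrame(feature_rows),
        uptake=pd.DataFrame(uptake_rows),
        controls=controls,
        labels=pd.DataFrame(label_rows),
        control_reference=reference,
        true_z=pd.DataFrame(z_rows),
    )
    if include_tacs and label_rows:
        tacs = {}
        for row in label_rows:
            true_dvr = 1.3 + 1.2 * rng.random() if row["pib_positive"] else 0.9 + 0.25 * rng.random()
            target, ref_tac, dvr = generate_tac_pair(true_dvr, rng=rng)
            tacs[row["patient_id"]] = (target, ref_tac, dvr)
        cohort.tacs = tacs
    return cohort


# ---------------------------------------------------------------------------
# Time-activity curves with known ground-truth DVR


def _frame_mid_times(duration_min: float, n_frames: int) -> np.ndarray:
    # quadratically spaced boundaries: short early frames while the input
    # function changes fast, long late frames (standard dynamic-PET style)
    i = np.arange(n_frames + 1, dtype=float)
    bounds = duration_min * (i / n_frames) ** 2
    return (bounds[:-1] + bounds[1:]) / 2.0


def generate_tac_pair(
    true_dvr: float,
    duration_min: float = 90.0,
    n_frames: int = 30,
    noise_sd: float = 0.0,
    k2: float = 0.1,
    ref_amplitudes: Tuple[float, float] = (8.0, 1.5),
    ref_decay: Tuple[float, float] = (0.25, 0.012),
    rng=None,
) -> Tuple[TimeActivityCurve, TimeActivityCurve, float]:
    """Reference + target curve pair whose true Logan slope is ``true_dvr``.

    The reference is a bi-exponential decay
    ``C_ref(t) = sum_i A_i exp(-lambda_i t)``; the target follows a
    one-tissue compartment model ``dC_t/dt = K1 C_ref - k2 C_t`` with
    ``K1 = true_dvr * k2``, solved in closed form, so the Logan plot of the
    pair is exactly linear with slope ``true_dvr`` and intercept ``-1/k2``
    (only trapezoidal integration error remains).  Optional additive
    Gaussian noise (absolute activity units) perturbs both curves.
    """
    if true_dvr <= 0:
        raise SpecError(f"true DVR must be > 0, got {true_dvr}")
    if n_frames < 6:
        raise SpecError(f"need >= 6 frames, got {n_frames}")
    t = _frame_mid_times(duration_min, n_frames)
    amps, lams = np.asarray(ref_amplitudes, float), np.asarray(ref_decay, float)
    if np.any(np.isclose(lams, k2)):
        raise SpecError("reference decay constants must differ from k2")
    c_ref = (amps[None, :] * np.exp(-lams[None, :] * t[:, None])).sum(axis=1)
    k1 = true_dvr * k2
    c_tgt = (
        k1
        * amps[None, :]
        * (np.exp(-lams[None, :] * t[:, None]) - np.exp(-k2 * t[:, None]))
        / (k2 - lams[None, :])
    ).sum(axis=1)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        c_tgt = np.clip(c_tgt + rng.normal(0, noise_sd, c_tgt.shape), 1e-9, None)
        c_ref = np.clip(c_ref + rng.normal(0, noise_sd, c_ref.shape), 1e-9, None)
    target = TimeActivityCurve(times=t, activity=c_tgt, role="target")
    ref = TimeActivityCurve(times=t, activity=c_ref, role="reference")
    return target, ref, float(true_dvr)
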