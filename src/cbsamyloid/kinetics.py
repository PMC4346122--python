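"""Logan graphical analysis with a reference-tissue input function.

For a reversible tracer, plotting

    y(T) = int_0^T C_target dt / C_target(T)
against
    x(T) = int_0^T C_ref dt / C_target(T)

becomes linear after an equilibration time t*; the late-time slope
estimates the distribution volume ratio (DVR) of target to reference
tissue.  Integrals are cumulative trapezoids from time zero, with an
implicit (0, 0) point prepended to the frame grid.  The pure
reference-ratio form is used (no k2' perfusion correction term).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .errors import InputError, InsufficientDataError, InvalidUptakeError

#: default equilibration start time for the linear fit window (minutes)
DEFAULT_T_STAR = 35.0


@dataclass(frozen=True)
class TimeActivityCurve:
    """Tracer concentration sampled at frame mid-times (minutes)."""

    times: np.ndarray  # frame mid-times, strictly increasing, > 0
    activity: np.ndarray  # tracer concentration, >= 0
    role: str = "target"  # "target" | "reference"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.activity, dtype=float)
        if t.ndim != 1 or a.shape != t.shape:
            raise InputError("times and activity must be 1-D arrays of equal length")
        if len(t) < 4:
            raise InsufficientDataError(f"need >= 4 frames, got {len(t)}")
        if (np.diff(t) <= 0).any() or t[0] <= 0:
            raise InputError("frame mid-times must be strictly increasing and > 0")
        if (a < 0).any():
            raise InvalidUptakeError("activity must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "activity", a)

    @classmethod
    def from_frames(cls, frame_start, frame_end, activity, role="target"):
        """Build from frame start/end times; mid-time = frame midpoint."""
        mid = (np.asarray(frame_start, float) + np.asarray(frame_end, float)) / 2.0
        return cls(times=mid, activity=np.asarray(activity, float), role=role)

    def cumulative_integral(self) -> np.ndarray:
        """Trapezoidal int_0^T activity dt at each frame mid-time, anchored
        at the implicit (0, 0) point."""
        t = np.concatenate([[0.0], self.times])
        a = np.concatenate([[0.0], self.activity])
        return integrate.cumulative_trapezoid(a, t)


@dataclass(frozen=True)
class LoganFit:
    dvr: float  # slope of the Logan plot
    intercept: float  # minutes
    t_star: float  # fit-window start, minutes
    n_fit_points: int
    r_squared: float


def logan_dvr(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    t_star: float = DEFAULT_T_STAR,
) -> LoganFit:
    """Estimate DVR as the Logan-plot slope over frames with mid-time >= t*.

    Requires the two curves to share a frame grid, at least 3 frames at or
    after t*, and strictly positive target activity in the fit window.
    """
    if target.times.shape != reference.times.shape or not np.allclose(
        target.times, reference.times
    ):
        raise InputError("target and reference curves must share a frame grid")
    window = target.times >= t_star
    n_fit = int(window.sum())
    if n_fit < 3:
        raise InsufficientDataError(
            f"need >= 3 frames with mid-time >= t*={t_star} min, got {n_fit}"
        )
    ct = target.activity[window]
    if (ct <= 0).any():
        raise InvalidUptakeError(
            "target activity must be > 0 on all fit-window frames"
        )
    int_t = target.cumulative_integral()[window]
    int_r = reference.cumulative_integral()[window]
    x = int_r / ct
    y = int_t / ct
    fit = stats.linregress(x, y)
    return LoganFit(
        dvr=float(fit.slope),
        intercept=float(fit.intercept),
        t_star=float(t_star),
        n_fit_points=n_fit,
        r_squared=float(fit.rvalue**2),
    )
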