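"""Stopping-phase detection within pirouettes.

A stopping phase is a maximal frame window in which the ant has stopped
moving forward and holds a constant gaze: every frame's forward speed is
at or below a threshold, and every in-window heading lies within a
tolerance of the window's circular-mean heading (default ±10°) for at
least a minimum duration (default 100 ms).  Constancy is defined against
the window mean rather than frame-to-frame increments, which makes the
criterion order-independent and directly checkable by brute force.

Durations count inter-frame spans: a window of frames [s, e] lasts
(e − s)/fps seconds, so at 50 fps the 100 ms minimum requires six frames.

The longest stopping phase of a pirouette carries the gaze direction used
in the goal-directedness analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import kinematics
from .trackmodel import PirouetteAnnotation, Track

__all__ = [
    "StopCriteria",
    "StoppingPhase",
    "detect_stopping_phases",
    "longest_stopping_phase",
    "phase_gaze",
]


@dataclass(frozen=True)
class StopCriteria:
    """Thresholds defining a stopping phase.

    The forward-speed cap is not part of the published criterion wording
    and defaults to 0.5 cm/s; ``max_angular_speed_dps`` optionally adds an
    explicit rotational-stop cap (off by default — gaze constancy already
    bounds rotation).
    """

    gaze_tol_deg: float = 10.0
    min_duration_ms: float = 100.0
    max_forward_speed: float = 0.5
    max_angular_speed_dps: float | None = None

    def __post_init__(self) -> None:
        if self.gaze_tol_deg <= 0 or self.min_duration_ms <= 0 \
                or self.max_forward_speed <= 0:
            raise ValueError("stop criteria must be positive")
        if self.max_angular_speed_dps is not None and self.max_angular_speed_dps <= 0:
            raise ValueError("angular speed cap must be positive")

    def min_frames(self, fps: float) -> int:
        """Smallest window length (frames) meeting the duration minimum."""
        return int(math.ceil(self.min_duration_ms * fps / 1000.0 - 1e-9)) + 1


@dataclass(frozen=True)
class StoppingPhase:
    """A detected stopping phase; frame indices are inclusive and refer to
    the whole track."""

    start_index: int
    end_index: int
    duration_ms: float
    gaze_mean_deg: float
    max_dev_deg: float

    @property
    def n_frames(self) -> int:
        return self.end_index - self.start_index + 1


def _circ_mean_deg(h_deg: np.ndarray) -> float:
    rad = np.radians(h_deg)
    m = float(np.degrees(np.arctan2(np.sin(rad).sum(), np.cos(rad).sum())) % 360.0)
    return 0.0 if m >= 360.0 else m


def detect_stopping_phases(track: Track, pirouette: PirouetteAnnotation,
                           criteria: StopCriteria | None = None
                           ) -> list[StoppingPhase]:
    """All maximal stopping phases within a pirouette.

    A window qualifies when (i) every frame's forward speed is within the
    cap, (ii) every heading lies within ±gaze_tol of the window's circular
    mean, and (iii) it spans at least the minimum duration.  Returned
    windows are maximal: no qualifying window strictly contains another
    returned one.  Degenerate frames (no body axis) cannot belong to a
    phase.  A pirouette too short for the minimum duration yields an empty
    list.
    """
    criteria = criteria or StopCriteria()
    if not (0 <= pirouette.start_index < pirouette.end_index < len(track)):
        raise ValueError("pirouette out of track bounds")
    fps = track.fps
    minlen = criteria.min_frames(fps)
    ps, pe = pirouette.start_index, pirouette.end_index
    if pe - ps + 1 < minlen:
        return []

    speeds = kinematics.forward_speeds(track)
    headings = kinematics.heading_azimuths(track)
    eligible = (speeds[ps:pe + 1] <= criteria.max_forward_speed) \
        & ~np.isnan(headings[ps:pe + 1])
    if criteria.max_angular_speed_dps is not None:
        om = kinematics.angular_speeds(track)[ps:pe + 1]
        eligible &= ~np.isnan(om) & (np.abs(om) <= criteria.max_angular_speed_dps)

    tol = criteria.gaze_tol_deg
    qualifying: list[tuple[int, int, float, float]] = []

    # maximal eligible runs
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([0], breaks + 1))
    run_ends = np.concatenate((breaks, [idx.size - 1]))

    for rs, re in zip(run_starts, run_ends):
        a, b = int(idx[rs]) + ps, int(idx[re]) + ps
        if b - a + 1 < minlen:
            continue
        h = headings[a:b + 1]
        rad = np.radians(h)
        cs = np.concatenate(([0.0], np.cumsum(np.cos(rad))))
        sn = np.concatenate(([0.0], np.cumsum(np.sin(rad))))
        L = b - a + 1
        for s in range(L - minlen + 1):
            # necessary condition: any qualifying window's headings lie
            # pairwise within 2*tol, in particular within 2*tol of h[s]
            far = np.abs(kinematics.wrap_signed(h[s:] - h[s])) > 2.0 * tol
            cap = int(np.argmax(far)) - 1 if far.any() else L - s - 1
            e_hi = s + cap  # last end index (run-local) worth checking
            if e_hi - s + 1 < minlen:
                continue
            ends = np.arange(s + minlen - 1, e_hi + 1)
            C = cs[ends + 1] - cs[s]
            S = sn[ends + 1] - sn[s]
            means = np.degrees(np.arctan2(S, C)) % 360.0
            seg = h[s:e_hi + 1]
            dev = np.abs(kinematics.wrap_signed(seg[None, :] - means[:, None]))
            # mask out frames beyond each candidate end
            within = np.arange(s, e_hi + 1)[None, :] <= ends[:, None]
            maxdev = np.where(within, dev, -np.inf).max(axis=1)
            for k in np.flatnonzero(maxdev <= tol):
                e = int(ends[k])
                qualifying.append((a + s, a + e, float(means[k]), float(maxdev[k])))

    if not qualifying:
        return []
    # keep only maximal windows: sort by (start asc, end desc); a window is
    # contained iff some earlier-sorted window reaches at least as far
    qualifying.sort(key=lambda w: (w[0], -w[1]))
    phases: list[StoppingPhase] = []
    best_end = -1
    dt = 1000.0 / fps
    for s, e, mu, dv in qualifying:
        if e > best_end:
            phases.append(StoppingPhase(s, e, (e - s) * dt, mu, dv))
            best_end = e
    phases.sort(key=lambda p: (p.start_index, p.end_index))
    return phases


def longest_stopping_phase(phases: list[StoppingPhase]) -> StoppingPhase | None:
    """Longest phase by duration; ties go to the earliest start."""
    if not phases:
        return None
    return min(phases, key=lambda p: (-p.duration_ms, p.start_index))


def phase_gaze(track: Track, phase: StoppingPhase,
               goal: tuple[float, float]) -> float:
    """Circular mean of the per-frame relative gaze over a phase.

    Degenerate frames are skipped; raises if no frame in the phase has a
    body axis.
    """
    vals = []
    for i in range(phase.start_index, phase.end_index + 1):
        frame = track.frames[i]
        if frame.is_degenerate():
            continue
        vals.append(kinematics.relative_gaze(frame, goal))
    if not vals:
        raise ValueError("phase contains no frame with a defined gaze")
    return _circ_mean_deg(np.array(vals))
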