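"""Headings, bearings, relative gaze, fictive-nest construction and
pirouette selection.

Conventions: arena coordinates x east / y north in cm; azimuths clockwise
from +y (north) in [0, 360).  The gaze direction is the azimuth of the
thorax→mandible body axis.  Relative gaze expresses the gaze with respect
to the bearing from the mandible position to a goal, mapped so that an ant
fixating the goal reads 180°:

    rel = (heading − bearing(mandible → goal) + 180) mod 360

The fictive nest is the point where the nest "should" be under a
horizontal-field alteration of θ: the mandible→nest vector at the coil
switch-on moment, rotated clockwise (viewed from above) by θ about the
mandible position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trackmodel import CoilEvent, PirouetteAnnotation, Track, TrackFrame

__all__ = [
    "DegenerateFrameError",
    "heading_azimuth",
    "heading_azimuths",
    "bearing",
    "relative_gaze",
    "fictive_nest",
    "forward_speed",
    "forward_speeds",
    "angular_speed",
    "angular_speeds",
    "PirouetteSelection",
    "select_pirouettes",
    "detect_pirouettes",
    "wrap_signed",
]

Point = tuple[float, float]


class DegenerateFrameError(ValueError):
    """Raised when a heading is requested for a frame without a body axis."""


def wrap_signed(deg):
    """Wrap degrees to (−180, 180] (scalar or array)."""
    w = (np.asarray(deg) + 180.0) % 360.0 - 180.0
    w = np.where(w == -180.0, 180.0, w)
    return float(w) if np.ndim(deg) == 0 else w


def _azimuth(dx: float, dy: float) -> float:
    a = math.degrees(math.atan2(dx, dy)) % 360.0
    return 0.0 if a >= 360.0 else a


def heading_azimuth(frame: TrackFrame) -> float:
    """Azimuth of the thorax→mandible axis, clockwise from north."""
    if frame.is_degenerate():
        raise DegenerateFrameError(f"frame {frame.index}: mandible = thorax")
    return _azimuth(frame.mandible[0] - frame.thorax[0],
                    frame.mandible[1] - frame.thorax[1])


def heading_azimuths(track: Track) -> np.ndarray:
    """Per-frame headings; NaN at degenerate frames."""
    d = track.mandibles - track.thoraxes
    with np.errstate(invalid="ignore"):
        h = np.degrees(np.arctan2(d[:, 0], d[:, 1])) % 360.0
    h[h >= 360.0] = 0.0
    h[np.hypot(d[:, 0], d[:, 1]) <= 1e-6] = np.nan
    return h


def bearing(from_pt: Point, to_pt: Point) -> float:
    """Azimuth of the line from ``from_pt`` to ``to_pt``."""
    dx, dy = to_pt[0] - from_pt[0], to_pt[1] - from_pt[1]
    if math.hypot(dx, dy) == 0.0:
        raise ValueError("bearing undefined for coincident points")
    return _azimuth(dx, dy)


def relative_gaze(frame: TrackFrame, goal: Point) -> float:
    """Gaze direction relative to the goal; perfect fixation -> 180°."""
    b = bearing(frame.mandible, goal)
    return (heading_azimuth(frame) - b + 180.0) % 360.0


def fictive_nest(mandible_at_switch: Point, nest: Point, theta_deg: float) -> Point:
    """Rotate the mandible→nest vector clockwise by θ about the mandible.

    Uses the same sign convention as the field alteration: θ > 0 turns
    magnetic north eastward, so the goal turns the same way.
    """
    vx = nest[0] - mandible_at_switch[0]
    vy = nest[1] - mandible_at_switch[1]
    if math.hypot(vx, vy) == 0.0:
        raise ValueError("fictive nest undefined: mandible coincides with nest")
    th = math.radians(theta_deg)
    # clockwise rotation viewed from above, x east / y north
    rx = vx * math.cos(th) + vy * math.sin(th)
    ry = -vx * math.sin(th) + vy * math.cos(th)
    return (mandible_at_switch[0] + rx, mandible_at_switch[1] + ry)


def forward_speeds(track: Track) -> np.ndarray:
    """Thorax speed per frame, cm/s: central differences, one-sided at the
    track ends.  Length-1 tracks return [0]."""
    th = track.thoraxes
    t = track.times
    n = len(track)
    if n == 0:
        return np.empty(0)
    if n == 1:
        return np.zeros(1)
    v = np.empty(n)
    d = np.hypot(*np.diff(th, axis=0).T)
    v[0] = d[0] / (t[1] - t[0])
    v[-1] = d[-1] / (t[-1] - t[-2])
    if n > 2:
        dd = np.hypot(th[2:, 0] - th[:-2, 0], th[2:, 1] - th[:-2, 1])
        v[1:-1] = dd / (t[2:] - t[:-2])
    return v


def forward_speed(track: Track, i: int) -> float:
    if len(track) < 2:
        raise ValueError("forward speed needs >= 2 frames")
    return float(forward_speeds(track)[i])


def angular_speeds(track: Track) -> np.ndarray:
    """Heading rate per frame, deg/s, using circular differences; NaN where
    a degenerate frame enters the stencil."""
    h = heading_azimuths(track)
    t = track.times
    n = len(track)
    if n < 2:
        return np.zeros(n)
    w = np.empty(n)
    dh = wrap_signed(np.diff(h))
    w[0] = dh[0] / (t[1] - t[0])
    w[-1] = dh[-1] / (t[-1] - t[-2])
    if n > 2:
        w[1:-1] = wrap_signed(h[2:] - h[:-2]) / (t[2:] - t[:-2])
    w[np.isnan(h)] = np.nan  # a frame without a body axis has no rate
    return w


def angular_speed(track: Track, i: int) -> float:
    return float(angular_speeds(track)[i])


@dataclass(frozen=True)
class PirouetteSelection:
    """Outcome of pirouette selection around a coil event.  Absent slots
    carry a reason instead of an exception."""

    before: PirouetteAnnotation | None
    after: PirouetteAnnotation | None
    before_reason: str | None = None
    after_reason: str | None = None


def _mean_mandible_dist(track: Track, ann: PirouetteAnnotation,
                        point: Point) -> float:
    m = track.mandibles[ann.start_index:ann.end_index + 1]
    return float(np.hypot(m[:, 0] - point[0], m[:, 1] - point[1]).mean())


def select_pirouettes(track: Track, annotations: list[PirouetteAnnotation],
                      event: CoilEvent, min_dist_cm: float = 5.0
                      ) -> PirouetteSelection:
    """Pick the analysis pirouettes around the coil switch-on.

    before: last annotated pirouette ending before switch-on whose mean
    mandible position is at least ``min_dist_cm`` from the nest.  after:
    first pirouette starting at/after switch-on under the same distance
    rule.  Missing candidates are reported, not raised.
    """
    t = track.times
    before_cands = [a for a in annotations if t[a.end_index] < event.switch_on_t]
    after_cands = [a for a in annotations if t[a.start_index] >= event.switch_on_t]

    def qualify(cands: list[PirouetteAnnotation]) -> list[PirouetteAnnotation]:
        return [a for a in cands
                if _mean_mandible_dist(track, a, track.nest) >= min_dist_cm]

    before_q = qualify(before_cands)
    after_q = qualify(after_cands)
    before = max(before_q, key=lambda a: a.end_index) if before_q else None
    after = min(after_q, key=lambda a: a.start_index) if after_q else None
    before_reason = None if before else (
        "no candidate before switch-on" if not before_cands
        else f"all pre-switch pirouettes closer than {min_dist_cm} cm to nest")
    after_reason = None if after else (
        "no candidate after switch-on" if not after_cands
        else f"all post-switch pirouettes closer than {min_dist_cm} cm to nest")
    return PirouetteSelection(before, after, before_reason, after_reason)


def detect_pirouettes(track: Track, min_total_turn_deg: float = 180.0,
                      max_net_disp_bl: float = 1.0) -> list[PirouetteAnnotation]:
    """Heuristic pirouette finder (convenience only; analysis pirouettes
    are expected to be manually annotated).

    Scans for maximal frame spans in which the thorax stays within
    ``max_net_disp_bl`` body lengths (median mandible–thorax distance) of
    the span start while the cumulative unsigned heading change reaches
    ``min_total_turn_deg``.
    """
    n = len(track)
    if n < 3:
        return []
    th = track.thoraxes
    h = heading_azimuths(track)
    bl = float(np.median(np.hypot(*(track.mandibles - th).T)))
    max_disp = max_net_disp_bl * bl if bl > 0 else 0.5
    out: list[PirouetteAnnotation] = []
    i = 0
    while i < n - 1:
        j = i
        turn = 0.0
        while j + 1 < n and math.hypot(th[j + 1, 0] - th[i, 0],
                                       th[j + 1, 1] - th[i, 1]) <= max_disp:
            if not (np.isnan(h[j + 1]) or np.isnan(h[j])):
                turn += abs(wrap_signed(h[j + 1] - h[j]))
            j += 1
        if j > i and turn >= min_total_turn_deg:
            out.append(PirouetteAnnotation(i, j, "unlabeled"))
            i = j + 1
        else:
            i += 1
    return out
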