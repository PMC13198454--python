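"""Data model and I/O for tracked learning walks.

A track is the per-frame digitization of one ant on the experimental
platform: the 2-D positions of the mandibles and of the thorax, in cm, in
arena coordinates (x east, y north, origin at the platform center where
the nest tube exits).  Azimuths throughout the package are measured
clockwise from +y (north), which makes arena bearings directly comparable
to magnetic declinations.

Tracks travel as a CSV (one row per frame) plus a JSON sidecar holding the
per-ant metadata: nest position, frame rate, the coil switch-on event and
manual pirouette annotations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrackFrame",
    "Track",
    "CoilEvent",
    "PirouetteAnnotation",
    "Finding",
    "TrackParseError",
    "read_track_csv",
    "write_track_csv",
    "validate_track",
    "read_sidecar",
    "write_sidecar",
    "load_ant",
    "DEGENERATE_TOL_CM",
]

DEGENERATE_TOL_CM = 1e-6

_CSV_COLUMNS = ["frame", "t_s", "mand_x_cm", "mand_y_cm", "thor_x_cm", "thor_y_cm"]


class TrackParseError(ValueError):
    """Structured parse failure; ``row`` is the offending 0-based data row
    (None for file-level problems)."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        super().__init__(message if row is None else f"row {row}: {message}")


@dataclass(frozen=True)
class TrackFrame:
    """One digitized video frame: mandible and thorax positions in cm."""

    index: int
    t: float
    mandible: tuple[float, float]
    thorax: tuple[float, float]

    def is_degenerate(self, tol: float = DEGENERATE_TOL_CM) -> bool:
        """True when mandible and thorax coincide (no body axis)."""
        return math.hypot(self.mandible[0] - self.thorax[0],
                          self.mandible[1] - self.thorax[1]) <= tol


@dataclass
class Track:
    """An ordered sequence of frames with the per-ant spatial reference.

    ``platform`` is the bounding box (xmin, ymin, xmax, ymax) in cm; the
    default is the 60 cm × 60 cm platform centered on the nest tube exit.
    """

    frames: list[TrackFrame]
    fps: float = 50.0
    ant_id: str = ""
    nest: tuple[float, float] = (0.0, 0.0)
    platform: tuple[float, float, float, float] = (-30.0, -30.0, 30.0, 30.0)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        t = self.times
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("frame times must be strictly increasing")
        pts = np.concatenate([self.mandibles.ravel(), self.thoraxes.ravel()]) \
            if self.frames else np.empty(0)
        if pts.size and not np.all(np.isfinite(pts)):
            raise ValueError("all track points must be finite")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.t for f in self.frames], dtype=float)

    @property
    def mandibles(self) -> np.ndarray:
        return np.array([f.mandible for f in self.frames], dtype=float).reshape(-1, 2)

    @property
    def thoraxes(self) -> np.ndarray:
        return np.array([f.thorax for f in self.frames], dtype=float).reshape(-1, 2)

    def degenerate_indices(self, tol: float = DEGENERATE_TOL_CM) -> list[int]:
        d = np.hypot(*(self.mandibles - self.thoraxes).T) if self.frames else np.empty(0)
        return [i for i in range(len(self.frames)) if d[i] <= tol]

    def frame_at_time(self, t: float) -> int:
        """Index of the first frame with time >= t."""
        idx = int(np.searchsorted(self.times, t, side="left"))
        if idx >= len(self.frames):
            raise ValueError(f"time {t} s beyond track end")
        return idx


@dataclass(frozen=True)
class CoilEvent:
    """Coil switch-on: time in seconds and the horizontal-field alteration
    angle θ in degrees (positive clockwise viewed from above)."""

    switch_on_t: float
    alteration_deg: float


@dataclass(frozen=True)
class PirouetteAnnotation:
    """Manually annotated pirouette as an inclusive frame range."""

    start_index: int
    end_index: int
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        if self.start_index >= self.end_index:
            raise ValueError("pirouette needs start_index < end_index")
        if self.label not in ("before", "after", "unlabeled"):
            raise ValueError(f"unknown pirouette label {self.label!r}")


@dataclass(frozen=True)
class Finding:
    """One validation finding on a track."""

    code: str
    message: str
    frame_index: int | None = None


def read_track_csv(path: str | Path, meta: Mapping[str, object] | None = None) -> Track:
    """Read a track CSV with columns frame, t_s, mand_x_cm, mand_y_cm,
    thor_x_cm, thor_y_cm.

    ``meta`` may provide ant_id, nest, fps and platform.  Degenerate frames
    (mandible = thorax) are kept, not dropped; use :func:`validate_track`
    to list them.  Malformed input raises :class:`TrackParseError` naming
    the offending data row.
    """
    meta = dict(meta or {})
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface as structured error
        raise TrackParseError(f"cannot read CSV {path}: {exc}") from exc
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TrackParseError(f"missing columns {missing} in {path}")
    vals = df[_CSV_COLUMNS].to_numpy(dtype=float, na_value=np.nan)
    bad = np.where(~np.isfinite(vals).all(axis=1))[0]
    if bad.size:
        raise TrackParseError("non-finite value", row=int(bad[0]))
    t = vals[:, 1]
    nonmono = np.where(np.diff(t) <= 0)[0]
    if nonmono.size:
        raise TrackParseError("time not strictly increasing", row=int(nonmono[0]) + 1)
    frames = [
        TrackFrame(index=int(v[0]), t=float(v[1]),
                   mandible=(float(v[2]), float(v[3])),
                   thorax=(float(v[4]), float(v[5])))
        for v in vals
    ]
    nest = meta.get("nest", (0.0, 0.0))
    platform = meta.get("platform", (-30.0, -30.0, 30.0, 30.0))
    return Track(frames=frames,
                 fps=float(meta.get("fps", 50.0)),  # type: ignore[arg-type]
                 ant_id=str(meta.get("ant_id", "")),
                 nest=(float(nest[0]), float(nest[1])),  # type: ignore[index]
                 platform=tuple(float(v) for v in platform))  # type: ignore[arg-type]


def write_track_csv(track: Track, path: str | Path) -> None:
    """Write a track to CSV (6-decimal fixed point, re-readable by
    :func:`read_track_csv`)."""
    df = pd.DataFrame(
        {
            "frame": [f.index for f in track.frames],
            "t_s": [f.t for f in track.frames],
            "mand_x_cm": [f.mandible[0] for f in track.frames],
            "mand_y_cm": [f.mandible[1] for f in track.frames],
            "thor_x_cm": [f.thorax[0] for f in track.frames],
            "thor_y_cm": [f.thorax[1] for f in track.frames],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def validate_track(track: Track) -> list[Finding]:
    """Diagnostic findings: irregular frame spacing (>10% off 1/fps),
    out-of-platform points, degenerate frames, and body-length outliers
    (mandible–thorax distance > 3× the track median)."""
    findings: list[Finding] = []
    t = track.times
    if t.size >= 2:
        dt = np.diff(t)
        for i in np.where(np.abs(dt - 1.0 / track.fps) > 0.1 / track.fps)[0]:
            findings.append(Finding("irregular_spacing",
                                    f"frame interval {dt[i]:.6f} s vs expected "
                                    f"{1.0 / track.fps:.6f} s", int(i) + 1))
    xmin, ymin, xmax, ymax = track.platform
    m, th = track.mandibles, track.thoraxes
    for i in range(len(track)):
        pts = (m[i], th[i])
        if any(not (xmin <= p[0] <= xmax and ymin <= p[1] <= ymax) for p in pts):
            findings.append(Finding("out_of_platform",
                                    f"point outside platform bounds at frame {i}", i))
    for i in track.degenerate_indices():
        findings.append(Finding("degenerate_frame",
                                "mandible coincides with thorax (no body axis)", i))
    if len(track) >= 2:
        bl = np.hypot(*(m - th).T)
        med = float(np.median(bl))
        if med > 0:
            for i in np.where(bl > 3.0 * med)[0]:
                findings.append(Finding("body_length_outlier",
                                        f"body length {bl[i]:.3f} cm > 3x median "
                                        f"{med:.3f} cm", int(i)))
    return findings


# ---------------------------------------------------------------------------
# Sidecar JSON: per-ant metadata, coil event, pirouette annotations
# ---------------------------------------------------------------------------

@dataclass
class Sidecar:
    ant_id: str
    nest: tuple[float, float]
    fps: float
    coil: CoilEvent | None
    pirouettes: list[PirouetteAnnotation] = field(default_factory=list)


def read_sidecar(path: str | Path) -> Sidecar:
    raw = json.loads(Path(path).read_text())
    coil = None
    if raw.get("coil") is not None:
        coil = CoilEvent(float(raw["coil"]["switch_on_t"]),
                         float(raw["coil"]["alteration_deg"]))
    anns = [
        PirouetteAnnotation(int(p["start"]), int(p["end"]),
                            str(p.get("label", "unlabeled")))
        for p in raw.get("pirouettes", [])
    ]
    nest = raw.get("nest", (0.0, 0.0))
    return Sidecar(ant_id=str(raw.get("ant_id", "")),
                   nest=(float(nest[0]), float(nest[1])),
                   fps=float(raw.get("fps", 50.0)),
                   coil=coil, pirouettes=anns)


def write_sidecar(sidecar: Sidecar, path: str | Path) -> None:
    raw: dict[str, object] = {
        "ant_id": sidecar.ant_id,
        "nest": list(sidecar.nest),
        "fps": sidecar.fps,
        "coil": None if sidecar.coil is None else {
            "switch_on_t": sidecar.coil.switch_on_t,
            "alteration_deg": sidecar.coil.alteration_deg,
        },
        "pirouettes": [
            {"start": p.start_index, "end": p.end_index, "label": p.label}
            for p in sidecar.pirouettes
        ],
    }
    Path(path).write_text(json.dumps(raw, indent=1, sort_keys=True) + "\n")


def load_ant(track_csv: str | Path, sidecar_json: str | Path
             ) -> tuple[Track, list[PirouetteAnnotation], CoilEvent | None]:
    """Load one ant's track plus its sidecar metadata."""
    sc = read_sidecar(sidecar_json)
    track = read_track_csv(track_csv,
                           {"ant_id": sc.ant_id, "nest": sc.nest, "fps": sc.fps})
    for p in sc.pirouettes:
        if p.end_index >= len(track):
            raise TrackParseError(
                f"pirouette [{p.start_index},{p.end_index}] exceeds track "
                f"length {len(track)}")
    return track, sc.pirouettes, sc.coil
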