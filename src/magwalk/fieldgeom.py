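"""Magnetic field vector algebra for horizontal-component alteration experiments.

A geomagnetic field (GMF) vector is represented either by orthogonal
components (``FieldXYZ``: x toward magnetic north, y toward magnetic east,
z vertical, positive downward, all in µT) or by the magnetometer-style
triple declination / inclination / total intensity (``FieldDIB``).

A Helmholtz coil superposes an artificial horizontal field on the GMF.  To
rotate the horizontal GMF component by an angle θ (positive clockwise /
eastward, viewed from above) while keeping its magnitude, the coil must
generate a horizontal field of magnitude

    B_coil = 2 · B_H · sin(|θ|/2)

directed along azimuth θ/2 + 90° (for θ > 0) relative to the horizontal
GMF direction: the GMF horizontal vector, the coil vector and the altered
horizontal vector form an isosceles triangle.  The two classic special
cases are θ = 180° (B_coil = 2·B_H, coil field pointing south) and
θ = +120° (B_coil = 2·cos 30°·B_H).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "FieldXYZ",
    "FieldDIB",
    "CoilPlan",
    "Check",
    "VerificationReport",
    "dib_from_xyz",
    "xyz_from_dib",
    "coil_field_for_alteration",
    "coil_vector",
    "superpose",
    "predict_altered_field",
    "verify_alteration",
    "read_field_records",
    "reference_readings",
]

_HORIZONTAL_EPS = 1e-12


def _wrap180(deg: float) -> float:
    """Wrap an angle in degrees to (−180, 180]."""
    w = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if w == -180.0 else w


@dataclass(frozen=True)
class FieldXYZ:
    """Magnetic field vector in µT: x north, y east, z down."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite field component {name!r}")

    @property
    def horizontal(self) -> float:
        """Magnitude of the horizontal component, µT."""
        return math.hypot(self.x, self.y)

    @property
    def intensity(self) -> float:
        """Total field magnitude, µT."""
        return math.sqrt(self.x * self.x + self.y * self.y + self.z * self.z)


@dataclass(frozen=True)
class FieldDIB:
    """Field as declination (° clockwise from north, in (−180, 180]),
    inclination (°, positive downward, in [−90, 90]) and intensity (µT).

    ``declination_defined`` is False for a purely vertical field, where the
    declination is geometrically meaningless (reported as 0.0 by convention
    but flagged rather than guessed).
    """

    declination_deg: float
    inclination_deg: float
    intensity_ut: float
    declination_defined: bool = True

    def __post_init__(self) -> None:
        if self.intensity_ut < 0:
            raise ValueError("intensity must be >= 0")
        if not -90.0 <= self.inclination_deg <= 90.0:
            raise ValueError("inclination must lie in [-90, 90]")


@dataclass(frozen=True)
class CoilPlan:
    """Required artificial field for a horizontal alteration of θ degrees.

    ``axis_azimuth_deg`` is the horizontal direction of the coil-generated
    field relative to the horizontal GMF direction.  ``axis_from_ns_deg``
    and ``frame_from_ns_deg`` translate that into the angle of the coil
    axis line, respectively the coil frame (winding plane), to the
    north–south line — the quantity one would set up in the field.
    """

    alteration_deg: float
    b_h_gmf: float
    b_coil: float
    axis_azimuth_deg: float
    axis_from_ns_deg: float
    frame_from_ns_deg: float


def dib_from_xyz(f: FieldXYZ) -> FieldDIB:
    """Convert component form to declination/inclination/intensity.

    declination = atan2(y, x), inclination = atan2(z, √(x²+y²)),
    intensity = √(x²+y²+z²).  A zero horizontal component yields
    inclination ±90° with the declination flagged undefined.
    """
    bh = f.horizontal
    b = f.intensity
    inc = math.degrees(math.atan2(f.z, bh))
    if bh <= _HORIZONTAL_EPS:
        return FieldDIB(0.0, inc, b, declination_defined=False)
    dec = _wrap180(math.degrees(math.atan2(f.y, f.x)))
    return FieldDIB(dec, inc, b)


def xyz_from_dib(f: FieldDIB) -> FieldXYZ:
    """Convert declination/inclination/intensity to components (inverse of
    :func:`dib_from_xyz` up to floating-point round-off)."""
    d = math.radians(f.declination_deg)
    i = math.radians(f.inclination_deg)
    bh = f.intensity_ut * math.cos(i)
    return FieldXYZ(bh * math.cos(d), bh * math.sin(d), f.intensity_ut * math.sin(i))


def coil_field_for_alteration(theta_deg: float, b_h_gmf: float) -> CoilPlan:
    """Design the coil field that rotates a horizontal GMF component of
    magnitude ``b_h_gmf`` by ``theta_deg`` without changing its magnitude.

    Raises ``ValueError`` for non-positive ``b_h_gmf`` or θ outside
    (−360, 360).
    """
    if b_h_gmf <= 0:
        raise ValueError("horizontal GMF magnitude must be > 0")
    if not -360.0 < theta_deg < 360.0:
        raise ValueError("alteration angle must lie in (-360, 360)")
    b_coil = 2.0 * b_h_gmf * math.sin(math.radians(abs(theta_deg)) / 2.0)
    if theta_deg == 0.0:
        axis = 90.0  # degenerate: zero coil field, direction immaterial
    else:
        axis = (theta_deg / 2.0 + math.copysign(90.0, theta_deg)) % 360.0
    line = axis % 180.0
    axis_from_ns = min(line, 180.0 - line)
    return CoilPlan(
        alteration_deg=theta_deg,
        b_h_gmf=b_h_gmf,
        b_coil=b_coil,
        axis_azimuth_deg=axis,
        axis_from_ns_deg=axis_from_ns,
        frame_from_ns_deg=90.0 - axis_from_ns,
    )


def coil_vector(plan: CoilPlan, gmf_declination_deg: float = 0.0) -> FieldXYZ:
    """Coil-generated field as a component vector, for a GMF whose
    horizontal component points along ``gmf_declination_deg``."""
    az = math.radians(plan.axis_azimuth_deg + gmf_declination_deg)
    return FieldXYZ(plan.b_coil * math.cos(az), plan.b_coil * math.sin(az), 0.0)


def superpose(a: FieldXYZ, b: FieldXYZ) -> FieldXYZ:
    """Vector addition of two fields."""
    return FieldXYZ(a.x + b.x, a.y + b.y, a.z + b.z)


def predict_altered_field(gmf: FieldXYZ, theta_deg: float) -> FieldXYZ:
    """Predict the total field when the coil for a θ-alteration is on.

    The result has the GMF's horizontal magnitude and vertical component,
    with the declination shifted by exactly θ.
    """
    bh = gmf.horizontal
    if bh <= _HORIZONTAL_EPS:
        raise ValueError("zero horizontal GMF component: alteration undefined")
    if theta_deg == 0.0:
        return gmf
    d0 = math.degrees(math.atan2(gmf.y, gmf.x))
    plan = coil_field_for_alteration(theta_deg, bh)
    return superpose(gmf, coil_vector(plan, gmf_declination_deg=d0))


@dataclass(frozen=True)
class Check:
    name: str
    observed: float
    expected: float
    deviation: float
    tolerance: float
    passed: bool


@dataclass(frozen=True)
class VerificationReport:
    checks: tuple[Check, ...]
    passed: bool

    def check(self, name: str) -> Check:
        for c in self.checks:
            if c.name == name:
                return c
        raise KeyError(name)


def verify_alteration(
    before: FieldXYZ,
    after: FieldXYZ,
    theta_deg: float,
    tol_deg: float,
    tol_ut: float,
) -> VerificationReport:
    """Compare a measured before/after field pair against an ideal
    θ-alteration: declination shift θ, horizontal magnitude, vertical
    component and total intensity all preserved.

    Angle deviations are compared against ``tol_deg``; magnitudes against
    ``tol_ut`` (absolute, µT).  Overall pass requires every check to pass.
    """
    if tol_deg <= 0 or tol_ut <= 0:
        raise ValueError("tolerances must be > 0")
    db = dib_from_xyz(before)
    da = dib_from_xyz(after)
    shift = (da.declination_deg - db.declination_deg) % 360.0
    dev_shift = abs(_wrap180(shift - theta_deg))
    checks = [
        Check("declination_shift", shift % 360.0, theta_deg % 360.0,
              dev_shift, tol_deg, dev_shift <= tol_deg),
    ]
    for name, obs, exp in (
        ("horizontal_magnitude", after.horizontal, before.horizontal),
        ("vertical_component", after.z, before.z),
        ("total_intensity", after.intensity, before.intensity),
    ):
        dev = abs(obs - exp)
        checks.append(Check(name, obs, exp, dev, tol_ut, dev <= tol_ut))
    return VerificationReport(tuple(checks), all(c.passed for c in checks))


# ---------------------------------------------------------------------------
# I/O: magnetometer records as CSV or JSON, component or D/I/B form
# ---------------------------------------------------------------------------

_XYZ_KEYS = ("x", "y", "z")
_DIB_KEYS = ("declination", "inclination", "intensity")


def _record_to_field(rec: Mapping[str, object]) -> FieldXYZ:
    low = {str(k).strip().lower(): v for k, v in rec.items()}
    if all(k in low for k in _XYZ_KEYS):
        return FieldXYZ(*(float(low[k]) for k in _XYZ_KEYS))  # type: ignore[arg-type]
    if all(k in low for k in _DIB_KEYS):
        return xyz_from_dib(
            FieldDIB(float(low["declination"]), float(low["inclination"]),
                     float(low["intensity"]))
        )
    raise ValueError(
        "field record needs keys x/y/z or declination/inclination/intensity; "
        f"got {sorted(low)}"
    )


def read_field_records(path: str | Path) -> dict[str, FieldXYZ]:
    """Read magnetometer readings from a JSON object/array or a CSV file.

    Each record may carry either ``x, y, z`` (µT) or ``declination,
    inclination, intensity`` (degrees, degrees, µT) keys, plus an optional
    ``label``.  Returns a mapping label -> :class:`FieldXYZ`; unlabeled
    records are numbered.
    """
    path = Path(path)
    records: Iterable[tuple[str, Mapping[str, object]]]
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        if isinstance(raw, Mapping):
            records = [(str(k), v) for k, v in raw.items()]
        else:
            records = [
                (str(rec.get("label", i)), rec) for i, rec in enumerate(raw)
            ]
    else:
        import pandas as pd

        df = pd.read_csv(path)
        records = [
            (str(row.get("label", i)), row.to_dict())
            for i, (_, row) in enumerate(df.iterrows())
        ]
    return {label: _record_to_field(rec) for label, rec in records}


def reference_readings() -> dict[str, dict[str, FieldXYZ | FieldDIB]]:
    """Bundled one-time magnetometer measurements taken at the platform
    center for the two field-alteration experiments (180° and +120°),
    before and after coil switch-on.

    Returns, per label, both the component vector (``xyz``) and the
    triple as displayed by the instrument (``displayed``); the two are
    redundant up to instrument display rounding, which makes the rows a
    consistency fixture for the conversion routines.
    """
    path = Path(__file__).parent / "data" / "magnetometer_readings.json"
    raw = json.loads(path.read_text())
    out: dict[str, dict[str, FieldXYZ | FieldDIB]] = {}
    for label, rec in raw.items():
        out[label] = {
            "xyz": FieldXYZ(rec["x"], rec["y"], rec["z"]),
            "displayed": FieldDIB(rec["declination"], rec["inclination"],
                                  rec["intensity"]),
        }
    return out
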