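"""Synthetic learning-walk generator with ground truth.

Emulates the statistical structure the analysis assumes: 50-fps tracks on
a 60 cm × 60 cm platform, each containing pirouettes (in-place rotations
with stopping phases) before and after a coil switch-on event.  In every
pirouette exactly one designated longest stop carries a goal-directed
gaze — its heading is the bearing from the mandible to the goal plus a
von Mises error of concentration κ — where the goal is the nest before
switch-on and the fictive nest afterwards.  Shorter decoy stops have
uniform random headings; the analysis makes no claim about them.

Between stops the heading sweeps rapidly (bounded step sizes with a
guaranteed ≥20° jump into and out of each stop), so the frame windows of
the designed stops are exactly the maximal constant-gaze windows a
detector should find; the emitted ground truth records them for
stop-detection fidelity and parameter-recovery tests.

All randomness flows through one ``numpy.random.Generator`` seeded from
``SimConfig.seed``; regeneration with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__, kinematics
from .pipeline import AntData
from .trackmodel import (CoilEvent, PirouetteAnnotation, Sidecar, Track,
                         TrackFrame, load_ant, write_sidecar, write_track_csv)

__all__ = [
    "SimConfig",
    "StopTruth",
    "AntTruth",
    "GroundTruth",
    "simulate_experiment",
    "write_dataset",
    "load_dataset",
]

Point = tuple[float, float]


@dataclass(frozen=True)
class SimConfig:
    """Simulator parameters.

    κ is the von Mises concentration of the designated-stop gaze error,
    settable per epoch; durations are in ms as (low, high) uniform ranges,
    with decoy stops strictly shorter than the designated longest stop.
    ``stop_jitter_cm`` is positional noise during stops, small enough to
    stay below the default forward-speed stop threshold at 50 fps.
    """

    n_ants: int = 15
    kappa_before: float = 2.0
    kappa_after: float = 2.0
    alteration_deg: float = 180.0
    switch_on_t: float = 6.0
    fps: float = 50.0
    platform_cm: float = 60.0
    nest: Point = (0.0, 0.0)
    pirouettes_per_epoch: int = 1
    stops_per_pirouette: int = 3
    longest_stop_ms: tuple[float, float] = (240.0, 360.0)
    decoy_stop_ms: tuple[float, float] = (120.0, 180.0)
    site_radius_cm: tuple[float, float] = (8.0, 20.0)
    walk_step_cm: float = 0.5
    walk_turn_kappa: float = 8.0
    stop_jitter_cm: float = 0.002
    heading_jitter_deg: float = 0.4
    body_length_cm: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ants < 1:
            raise ValueError("need n_ants >= 1")
        if self.kappa_before < 0 or self.kappa_after < 0:
            raise ValueError("kappa must be >= 0")
        if min(self.longest_stop_ms) <= 0 or min(self.decoy_stop_ms) <= 0:
            raise ValueError("stop durations must be > 0")
        if self.longest_stop_ms[1] < 100.0:
            raise ValueError(
                "longest stop cannot reach 100 ms: tracks would contain no "
                "detectable stopping phase")
        if self.decoy_stop_ms[1] >= self.longest_stop_ms[0]:
            raise ValueError(
                "decoy stops must be strictly shorter than the designated "
                "longest stop")
        if self.stops_per_pirouette < 1 or self.pirouettes_per_epoch < 1:
            raise ValueError("need at least one stop and one pirouette")


@dataclass(frozen=True)
class StopTruth:
    """One designed stop: global inclusive frame window plus, for the
    designated stop, the goal and the drawn gaze error."""

    epoch: str
    pirouette_index: int
    start_index: int
    end_index: int
    heading_deg: float
    designated: bool
    goal: Point | None = None
    true_bearing_deg: float | None = None
    gaze_error_deg: float | None = None


@dataclass
class AntTruth:
    ant_id: str
    fictive_nest: Point | None
    switch_index: int
    stops: list[StopTruth] = field(default_factory=list)

    def designated(self, epoch: str) -> list[StopTruth]:
        return [s for s in self.stops if s.designated and s.epoch == epoch]


@dataclass
class GroundTruth:
    config: SimConfig
    ants: list[AntTruth] = field(default_factory=list)


def _unit(azimuth_deg: float) -> tuple[float, float]:
    a = math.radians(azimuth_deg)
    return math.sin(a), math.cos(a)  # x east, y north


class _AntBuilder:
    """Accumulates frames for one ant: thorax position + heading per
    frame; mandible is one body length ahead of the thorax."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.thorax: list[tuple[float, float]] = []
        self.heading: list[float] = []

    def n(self) -> int:
        return len(self.thorax)

    def add(self, pos: tuple[float, float], heading_deg: float) -> None:
        self.thorax.append(pos)
        self.heading.append(heading_deg % 360.0)

    # -- locomotion segments ------------------------------------------------

    def walk_to(self, target: Point, max_frames: int = 400) -> None:
        cfg = self.cfg
        pos = self.thorax[-1] if self.thorax else (cfg.nest[0] + 0.5, cfg.nest[1])
        for _ in range(max_frames):
            dx, dy = target[0] - pos[0], target[1] - pos[1]
            dist = math.hypot(dx, dy)
            if dist <= cfg.walk_step_cm:
                break
            az = math.degrees(math.atan2(dx, dy))
            az += math.degrees(self.rng.vonmises(0.0, cfg.walk_turn_kappa))
            ux, uy = _unit(az)
            pos = (pos[0] + cfg.walk_step_cm * ux, pos[1] + cfg.walk_step_cm * uy)
            self.add(pos, az)

    def loiter_until(self, n_frames: int) -> None:
        """Correlated random walk in an annulus around the nest until the
        track holds ``n_frames`` frames."""
        cfg = self.cfg
        lo, hi = cfg.site_radius_cm
        while self.n() < n_frames:
            pos = self.thorax[-1]
            az = self.heading[-1] + math.degrees(
                self.rng.vonmises(0.0, cfg.walk_turn_kappa))
            ux, uy = _unit(az)
            nxt = (pos[0] + cfg.walk_step_cm * ux, pos[1] + cfg.walk_step_cm * uy)
            d = math.hypot(nxt[0] - cfg.nest[0], nxt[1] - cfg.nest[1])
            if d < lo or d > hi:
                az = kinematics.bearing(pos, cfg.nest)
                if d < lo:
                    az = (az + 180.0) % 360.0
                ux, uy = _unit(az)
                nxt = (pos[0] + cfg.walk_step_cm * ux,
                       pos[1] + cfg.walk_step_cm * uy)
            self.add(nxt, az)

    # -- pirouette ----------------------------------------------------------

    def _transition(self, site: Point, h_from: float, h_to: float) -> None:
        """Sweep the heading from h_from to h_to with intermediate steps of
        15–45° and a final jump of 20–45° into h_to, so neither endpoint's
        stop window can absorb a transition frame."""
        g = (h_to - h_from) % 360.0
        sign = 1.0
        if g > 180.0:
            g, sign = 360.0 - g, -1.0
        if g < 20.0:  # too close: go the long way round
            g, sign = 360.0 - g, -sign
        h = h_from
        while g > 45.0:
            step = 45.0 if g - 45.0 >= 20.0 else g - 30.0
            h += sign * step
            g -= step
            self.add(self._jitter_pos(site), h)
        # final jump of g in [20, 45] lands exactly on h_to (no frame here;
        # the stop itself provides the h_to frames)

    def _jitter_pos(self, site: Point) -> tuple[float, float]:
        s = self.cfg.stop_jitter_cm
        j = np.clip(self.rng.normal(0.0, s, 2), -3.0 * s, 3.0 * s)
        return (site[0] + float(j[0]), site[1] + float(j[1]))

    def _stop_frames(self, site: Point, heading: float, n_frames: int) -> tuple[int, int]:
        jh = self.cfg.heading_jitter_deg
        start = self.n()
        for _ in range(n_frames):
            dh = float(np.clip(self.rng.normal(0.0, jh), -3.0 * jh, 3.0 * jh))
            self.add(self._jitter_pos(site), heading + dh)
        return start, self.n() - 1

    def _designated_heading(self, site: Point, goal: Point,
                            err_deg: float) -> float:
        """Heading whose mandible-based relative gaze error is exactly
        ``err_deg``: fixed-point on heading -> bearing(mandible, goal)."""
        h = kinematics.bearing(site, goal) + err_deg
        L = self.cfg.body_length_cm
        for _ in range(40):
            ux, uy = _unit(h)
            mand = (site[0] + L * ux, site[1] + L * uy)
            h = kinematics.bearing(mand, goal) + err_deg
        return h % 360.0

    def pirouette(self, goal: Point, kappa: float, epoch: str,
                  pir_index: int, truth: list[StopTruth]
                  ) -> PirouetteAnnotation:
        cfg = self.cfg
        rng = self.rng
        site = self.thorax[-1]
        n_stops = cfg.stops_per_pirouette
        designated_slot = int(rng.integers(n_stops))
        err = math.degrees(rng.vonmises(0.0, kappa))  # kappa=0 -> uniform
        start = self.n()
        h_prev = self.heading[-1] if self.heading else 0.0
        for k in range(n_stops):
            if k == designated_slot:
                h_k = self._designated_heading(site, goal, err)
                lo, hi = cfg.longest_stop_ms
            else:
                h_k = float(rng.uniform(0.0, 360.0))
                lo, hi = cfg.decoy_stop_ms
            dur_ms = float(rng.uniform(lo, hi))
            n_frames = int(round(dur_ms * cfg.fps / 1000.0)) + 1
            self._transition(site, h_prev, h_k)
            s, e = self._stop_frames(site, h_k, n_frames)
            if k == designated_slot:
                L = cfg.body_length_cm
                ux, uy = _unit(h_k)
                mand = (site[0] + L * ux, site[1] + L * uy)
                truth.append(StopTruth(epoch, pir_index, s, e, h_k, True,
                                       goal=goal,
                                       true_bearing_deg=kinematics.bearing(mand, goal),
                                       gaze_error_deg=err))
            else:
                truth.append(StopTruth(epoch, pir_index, s, e, h_k, False))
            h_prev = h_k
        # exit sweep so the last stop cannot extend into the walk
        self._transition(site, h_prev, (h_prev + 150.0) % 360.0)
        self.add(self._jitter_pos(site), (h_prev + 150.0) % 360.0)
        return PirouetteAnnotation(start, self.n() - 1, epoch)

    # -- assembly -----------------------------------------------------------

    def to_track(self, ant_id: str) -> Track:
        cfg = self.cfg
        L = cfg.body_length_cm
        frames = []
        for i, (pos, h) in enumerate(zip(self.thorax, self.heading)):
            ux, uy = _unit(h)
            frames.append(TrackFrame(index=i, t=i / cfg.fps,
                                     mandible=(pos[0] + L * ux, pos[1] + L * uy),
                                     thorax=pos))
        half = cfg.platform_cm / 2.0
        return Track(frames=frames, fps=cfg.fps, ant_id=ant_id, nest=cfg.nest,
                     platform=(cfg.nest[0] - half, cfg.nest[1] - half,
                               cfg.nest[0] + half, cfg.nest[1] + half))


def _random_site(cfg: SimConfig, rng: np.random.Generator) -> Point:
    r = float(rng.uniform(*cfg.site_radius_cm))
    a = float(rng.uniform(0.0, 360.0))
    ux, uy = _unit(a)
    return (cfg.nest[0] + r * ux, cfg.nest[1] + r * uy)


def simulate_experiment(config: SimConfig | None = None
                        ) -> tuple[list[AntData], GroundTruth]:
    """Generate a full experiment dataset plus its ground truth.

    Raises ``ValueError`` when the before-epoch cannot fit in front of the
    switch-on time.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    switch_index = int(math.ceil(cfg.switch_on_t * cfg.fps - 1e-9))
    dataset: list[AntData] = []
    truth = GroundTruth(config=cfg)
    event = CoilEvent(cfg.switch_on_t, cfg.alteration_deg)

    for a in range(cfg.n_ants):
        ant_id = f"sim{a:03d}"
        b = _AntBuilder(cfg, rng)
        annotations: list[PirouetteAnnotation] = []
        stop_truth: list[StopTruth] = []
        # before epoch: goal is the real nest
        for p in range(cfg.pirouettes_per_epoch):
            b.walk_to(_random_site(cfg, rng))
            annotations.append(
                b.pirouette(cfg.nest, cfg.kappa_before, "before", p, stop_truth))
        if b.n() > switch_index:
            raise ValueError(
                f"before-epoch needs {b.n()} frames but the coil switches on "
                f"at frame {switch_index}; increase switch_on_t")
        b.loiter_until(switch_index + 1)
        # fictive nest from the mandible position at the switch-on frame
        L = cfg.body_length_cm
        ux, uy = _unit(b.heading[switch_index])
        mand_at_switch = (b.thorax[switch_index][0] + L * ux,
                          b.thorax[switch_index][1] + L * uy)
        if cfg.alteration_deg % 360.0 == 0.0:
            fictive: Point | None = cfg.nest
        else:
            fictive = kinematics.fictive_nest(mand_at_switch, cfg.nest,
                                              cfg.alteration_deg)
        # after epoch: goal is the fictive nest
        for p in range(cfg.pirouettes_per_epoch):
            b.walk_to(_random_site(cfg, rng))
            annotations.append(
                b.pirouette(fictive, cfg.kappa_after, "after", p, stop_truth))
        track = b.to_track(ant_id)
        dataset.append(AntData(track, tuple(annotations), event))
        truth.ants.append(AntTruth(ant_id, fictive, switch_index, stop_truth))
    return dataset, truth


def _config_hash(cfg: SimConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True).encode()).hexdigest()[:16]


def write_dataset(dataset: list[AntData], truth: GroundTruth,
                  outdir: str | Path) -> None:
    """Write the dataset in the track-CSV + sidecar-JSON layout the
    analysis reads, plus ground_truth.json and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for d in dataset:
        write_track_csv(d.track, outdir / f"track_{d.ant_id}.csv")
        write_sidecar(
            Sidecar(ant_id=d.ant_id, nest=d.track.nest, fps=d.track.fps,
                    coil=d.event, pirouettes=list(d.annotations)),
            outdir / f"meta_{d.ant_id}.json")
    gt = {
        "version": __version__,
        "seed": truth.config.seed,
        "config_hash": _config_hash(truth.config),
        "config": asdict(truth.config),
        "ants": [asdict(a) for a in truth.ants],
    }
    (outdir / "ground_truth.json").write_text(
        json.dumps(gt, indent=1, sort_keys=True) + "\n")


def load_dataset(datadir: str | Path) -> list[AntData]:
    """Load every track/sidecar pair from a directory."""
    datadir = Path(datadir)
    out = []
    for meta in sorted(datadir.glob("meta_*.json")):
        ant_id = meta.stem[len("meta_"):]
        track, anns, coil = load_ant(datadir / f"track_{ant_id}.csv", meta)
        if coil is None:
            raise ValueError(f"{meta}: no coil event")
        out.append(AntData(track, tuple(anns), coil))
    if not out:
        raise ValueError(f"no meta_*.json sidecars found in {datadir}")
    return out
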