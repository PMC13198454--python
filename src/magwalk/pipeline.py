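"""End-to-end analysis of a field-alteration experiment.

For each ant: select one pirouette before and one after the coil
switch-on (each at least a minimum distance from the nest), detect
stopping phases within each, take the longest, and read off its gaze
direction relative to the real nest and — for the after-pirouette — to
the fictive nest (the nest position rotated by the alteration angle about
the mandible position at switch-on).  Experiment level: circular
summaries of the four angle blocks (before/nest, after/nest,
after/fictive, plus before/fictive as a consistency control) and a
Mardia–Watson–Wheeler comparison of before vs after relative to the nest.

Ants that fail a stage are excluded from the affected blocks with a
machine-readable reason, never silently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__, circstats, kinematics, stops
from .circstats import CircSummary, MWWResult
from .stops import StopCriteria, StoppingPhase
from .trackmodel import CoilEvent, PirouetteAnnotation, Track

__all__ = [
    "AnalysisConfig",
    "AntData",
    "AntResult",
    "ExperimentReport",
    "analyze_experiment",
    "render_report",
    "load_report",
    "report_to_dict",
]

BLOCKS = ("before_nest", "after_nest", "after_fictive", "before_fictive")


@dataclass(frozen=True)
class AnalysisConfig:
    stop_criteria: StopCriteria = field(default_factory=StopCriteria)
    min_dist_cm: float = 5.0
    alpha: float = 0.05
    mww_method: str = "chi2"
    n_perm: int = 9999
    seed: int = 0
    bin_width_deg: float = 10.0


@dataclass(frozen=True)
class AntData:
    """One ant's inputs: track, manual pirouette annotations, coil event."""

    track: Track
    annotations: tuple[PirouetteAnnotation, ...]
    event: CoilEvent

    @property
    def ant_id(self) -> str:
        return self.track.ant_id


@dataclass
class AntResult:
    ant_id: str
    before_gaze_nest_deg: float | None = None
    after_gaze_nest_deg: float | None = None
    after_gaze_fictive_deg: float | None = None
    before_gaze_fictive_deg: float | None = None
    fictive_nest: tuple[float, float] | None = None
    before_phase: StoppingPhase | None = None
    after_phase: StoppingPhase | None = None
    exclusions: dict[str, str] = field(default_factory=dict)


@dataclass
class ExperimentReport:
    alteration_deg: float
    ants: list[AntResult]
    summaries: dict[str, CircSummary | None]
    mww_nest: MWWResult | None
    histograms: dict[str, list[int]]
    config: AnalysisConfig
    version: str = __version__
    seed: int = 0


def _analyze_ant(data: AntData, config: AnalysisConfig) -> AntResult:
    track, event = data.track, data.event
    res = AntResult(ant_id=data.ant_id)
    sel = kinematics.select_pirouettes(track, list(data.annotations), event,
                                       config.min_dist_cm)
    # fictive nest from the mandible position at the switch-on frame
    try:
        switch_idx = track.frame_at_time(event.switch_on_t)
        mand = tuple(track.frames[switch_idx].mandible)
        res.fictive_nest = kinematics.fictive_nest(mand, track.nest,
                                                   event.alteration_deg)
    except ValueError as exc:
        res.exclusions["fictive"] = str(exc)

    for side, ann, reason in (("before", sel.before, sel.before_reason),
                              ("after", sel.after, sel.after_reason)):
        if ann is None:
            res.exclusions[side] = reason or "no pirouette"
            continue
        phases = stops.detect_stopping_phases(track, ann, config.stop_criteria)
        longest = stops.longest_stopping_phase(phases)
        if longest is None:
            res.exclusions[side] = "no stopping phase meeting the criteria"
            continue
        try:
            gaze_nest = stops.phase_gaze(track, longest, track.nest)
        except ValueError as exc:
            res.exclusions[side] = str(exc)
            continue
        if side == "before":
            res.before_phase = longest
            res.before_gaze_nest_deg = gaze_nest
            if res.fictive_nest is not None:
                res.before_gaze_fictive_deg = stops.phase_gaze(
                    track, longest, res.fictive_nest)
        else:
            res.after_phase = longest
            res.after_gaze_nest_deg = gaze_nest
            if res.fictive_nest is not None:
                res.after_gaze_fictive_deg = stops.phase_gaze(
                    track, longest, res.fictive_nest)
            else:
                res.exclusions.setdefault("after_fictive",
                                          "fictive nest unavailable")
    return res


def analyze_experiment(dataset: Sequence[AntData | tuple],
                       config: AnalysisConfig | None = None
                       ) -> ExperimentReport:
    """Run the full analysis over a set of ants sharing one alteration
    angle.  Raises on an empty dataset or mixed alteration angles."""
    config = config or AnalysisConfig()
    ants = [d if isinstance(d, AntData) else AntData(d[0], tuple(d[1]), d[2])
            for d in dataset]
    if not ants:
        raise ValueError("empty dataset")
    thetas = {a.event.alteration_deg for a in ants}
    if len(thetas) != 1:
        raise ValueError(f"mixed alteration angles in dataset: {sorted(thetas)}")
    theta = thetas.pop()

    results = [_analyze_ant(a, config) for a in ants]

    angle_lists: dict[str, list[float]] = {
        "before_nest": [r.before_gaze_nest_deg for r in results
                        if r.before_gaze_nest_deg is not None],
        "after_nest": [r.after_gaze_nest_deg for r in results
                       if r.after_gaze_nest_deg is not None],
        "after_fictive": [r.after_gaze_fictive_deg for r in results
                          if r.after_gaze_fictive_deg is not None],
        "before_fictive": [r.before_gaze_fictive_deg for r in results
                           if r.before_gaze_fictive_deg is not None],
    }
    summaries = {
        k: circstats.rayleigh_test(v) if len(v) >= 2 else None
        for k, v in angle_lists.items()
    }
    histograms = {
        k: circstats.bin_angles(v, config.bin_width_deg).tolist()
        for k, v in angle_lists.items()
    }
    mww = None
    if len(angle_lists["before_nest"]) >= 2 and len(angle_lists["after_nest"]) >= 2:
        mww = circstats.mww_test(angle_lists["before_nest"],
                                 angle_lists["after_nest"],
                                 method=config.mww_method,
                                 n_perm=config.n_perm, seed=config.seed)
    return ExperimentReport(alteration_deg=theta, ants=results,
                            summaries=summaries, mww_nest=mww,
                            histograms=histograms, config=config,
                            seed=config.seed)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _clean(obj):
    if isinstance(obj, float):
        return None if np.isnan(obj) else obj
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    return obj


def report_to_dict(report: ExperimentReport) -> dict:
    d = {
        "alteration_deg": report.alteration_deg,
        "version": report.version,
        "seed": report.seed,
        "config": dataclasses.asdict(report.config),
        "ants": [dataclasses.asdict(a) for a in report.ants],
        "summaries": {k: (None if s is None else dataclasses.asdict(s))
                      for k, s in report.summaries.items()},
        "mww_nest": (None if report.mww_nest is None
                     else dataclasses.asdict(report.mww_nest)),
        "histograms": report.histograms,
    }
    return _clean(d)


def render_report(report: ExperimentReport, outdir: str | Path
                  ) -> tuple[Path, Path]:
    """Write report.json (full, machine-readable) and report.tsv (one row
    per ant followed by one row per summary block)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    jpath = outdir / "report.json"
    jpath.write_text(json.dumps(report_to_dict(report), indent=1,
                                sort_keys=True) + "\n")

    def fmt(v) -> str:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return "NA"
        if isinstance(v, float):
            return f"{v:.3f}"
        return str(v)

    cols = ["row_type", "id", "before_gaze_nest_deg", "after_gaze_nest_deg",
            "after_gaze_fictive_deg", "before_gaze_fictive_deg",
            "n", "r", "Z", "p", "mu_deg", "ci_lo_deg", "ci_hi_deg",
            "exclusions"]
    lines = ["\t".join(cols)]
    for a in report.ants:
        lines.append("\t".join(fmt(v) for v in (
            "ant", a.ant_id, a.before_gaze_nest_deg, a.after_gaze_nest_deg,
            a.after_gaze_fictive_deg, a.before_gaze_fictive_deg,
            None, None, None, None, None, None, None,
            ";".join(f"{k}:{v}" for k, v in a.exclusions.items()) or None)))
    for name in BLOCKS:
        s = report.summaries.get(name)
        vals = (None,) * 11 if s is None else (
            s.n, s.r, s.Z, s.p, s.mu_deg, s.ci_lo_deg, s.ci_hi_deg)
        if s is None:
            lines.append("\t".join(fmt(v) for v in (
                "summary", name, None, None, None, None,
                None, None, None, None, None, None, None, None)))
        else:
            lines.append("\t".join(fmt(v) for v in (
                "summary", name, None, None, None, None,
                s.n, s.r, s.Z, s.p, s.mu_deg, s.ci_lo_deg, s.ci_hi_deg,
                None)))
    tpath = outdir / "report.tsv"
    tpath.write_text("\n".join(lines) + "\n")
    return jpath, tpath


def load_report(path: str | Path) -> dict:
    """Read back a rendered JSON report as a plain dictionary."""
    return json.loads(Path(path).read_text())
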