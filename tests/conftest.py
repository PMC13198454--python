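import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from magwalk.trackmodel import Track, TrackFrame

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.filter_too_much],
)
settings.load_profile("suite")


def make_track(headings_deg, thorax=None, fps=50.0, body_len=0.6,
               nest=(0.0, 0.0), ant_id="t"):
    """Build a track from per-frame headings (degrees) and optional thorax
    positions (default: stationary at (10, 0))."""
    headings_deg = np.asarray(headings_deg, dtype=float)
    n = headings_deg.size
    if thorax is None:
        thorax = np.tile([10.0, 0.0], (n, 1))
    else:
        thorax = np.asarray(thorax, dtype=float).reshape(n, 2)
    frames = []
    for i in range(n):
        h = np.radians(headings_deg[i])
        mand = (thorax[i, 0] + body_len * np.sin(h),
                thorax[i, 1] + body_len * np.cos(h))
        frames.append(TrackFrame(index=i, t=i / fps, mandible=mand,
                                 thorax=tuple(thorax[i])))
    return Track(frames=frames, fps=fps, ant_id=ant_id, nest=nest)


def random_stop_track(rng, n_frames, fps=50.0):
    """Random track mixing still/moving thorax phases with constant-ish and
    rotating heading phases; occasionally a degenerate frame."""
    headings = np.empty(n_frames)
    h = rng.uniform(0, 360)
    still = True
    thorax = np.empty((n_frames, 2))
    pos = np.array([10.0, 5.0])
    for i in range(n_frames):
        if rng.uniform() < 0.08:
            still = not still
        if rng.uniform() < 0.1:
            h += rng.normal(0, 60)
        h += rng.normal(0, 1.2) if rng.uniform() < 0.6 else rng.normal(0, 25)
        headings[i] = h % 360
        if not still:
            pos = pos + rng.normal(0, 0.3, 2)
        else:
            pos = pos + rng.normal(0, 0.002, 2)
        thorax[i] = pos
    track = make_track(headings, thorax, fps=fps)
    if n_frames > 10 and rng.uniform() < 0.3:
        i = int(rng.integers(1, n_frames - 1))
        f = track.frames[i]
        track.frames[i] = TrackFrame(index=f.index, t=f.t, mandible=f.thorax,
                                     thorax=f.thorax)
    return track


@pytest.fixture(scope="session")
def sim180():
    """One simulated 180°-alteration experiment at high gaze concentration
    with its analysis report (shared across pipeline-level tests)."""
    from magwalk import pipeline, synthetic

    cfg = synthetic.SimConfig(n_ants=15, kappa_before=8.0, kappa_after=8.0,
                              alteration_deg=180.0, seed=11)
    dataset, truth = synthetic.simulate_experiment(cfg)
    report = pipeline.analyze_experiment(dataset)
    return cfg, dataset, truth, report
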