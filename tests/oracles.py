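"""Independent brute-force oracles used by the test suite.

Deliberately plain-Python transliterations of the definitions, sharing no
code path with the package implementation.
"""

import itertools
import math


def _heading(frame):
    dx = frame.mandible[0] - frame.thorax[0]
    dy = frame.mandible[1] - frame.thorax[1]
    if math.hypot(dx, dy) <= 1e-6:
        return None
    return math.degrees(math.atan2(dx, dy)) % 360.0


def _speeds(track):
    th = [f.thorax for f in track.frames]
    t = [f.t for f in track.frames]
    n = len(th)
    out = []
    for i in range(n):
        j, k = (0, 1) if i == 0 else ((n - 2, n - 1) if i == n - 1
                                      else (i - 1, i + 1))
        out.append(math.dist(th[j], th[k]) / (t[k] - t[j]))
    return out


def _wrap(d):
    w = (d + 180.0) % 360.0 - 180.0
    return 180.0 if w == -180.0 else w


def brute_force_stops(track, pirouette, criteria):
    """Enumerate every frame window in the pirouette, keep those whose
    frames are all slow and non-degenerate, whose headings all lie within
    the gaze tolerance of the window circular mean, and whose span meets
    the duration minimum; then reduce to windows contained in no other."""
    fps = track.fps
    speeds = _speeds(track)
    heads = [_heading(f) for f in track.frames]
    ps, pe = pirouette.start_index, pirouette.end_index
    ok = [speeds[i] <= criteria.max_forward_speed and heads[i] is not None
          for i in range(len(track.frames))]
    qualifying = []
    for s in range(ps, pe + 1):
        if not ok[s]:
            continue
        for e in range(s, pe + 1):
            if not ok[e]:
                break
            if (e - s) / fps * 1000.0 < criteria.min_duration_ms - 1e-6:
                continue
            window = heads[s:e + 1]
            c = sum(math.cos(math.radians(h)) for h in window)
            sn = sum(math.sin(math.radians(h)) for h in window)
            mean = math.degrees(math.atan2(sn, c)) % 360.0
            maxdev = max(abs(_wrap(h - mean)) for h in window)
            if maxdev <= criteria.gaze_tol_deg:
                qualifying.append((s, e))
    qualifying.sort(key=lambda w: (w[0], -w[1]))
    maximal, best_end = [], -1
    for s, e in qualifying:
        if e > best_end:
            maximal.append((s, e))
            best_end = e
    return sorted(maximal)


def midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def mww_w_from_scores(beta, labels, n1, n2):
    c1 = sum(math.cos(b) for b, l in zip(beta, labels) if l == 0)
    s1 = sum(math.sin(b) for b, l in zip(beta, labels) if l == 0)
    c2 = sum(math.cos(b) for b, l in zip(beta, labels) if l == 1)
    s2 = sum(math.sin(b) for b, l in zip(beta, labels) if l == 1)
    return 2.0 * ((c1 * c1 + s1 * s1) / n1 + (c2 * c2 + s2 * s2) / n2)


def exhaustive_mww_p(a, b):
    """Exact permutation p of the uniform-scores statistic by enumerating
    every assignment of the combined sample into groups of size n1/n2."""
    n1, n2 = len(a), len(b)
    combined = list(a) + list(b)
    N = n1 + n2
    beta = [2.0 * math.pi * r / N for r in midranks(combined)]
    obs = mww_w_from_scores(beta, [0] * n1 + [1] * n2, n1, n2)
    hits = total = 0
    for idx in itertools.combinations(range(N), n1):
        labels = [1] * N
        for i in idx:
            labels[i] = 0
        w = mww_w_from_scores(beta, labels, n1, n2)
        total += 1
        if w >= obs - 1e-12:
            hits += 1
    return obs, hits / total
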