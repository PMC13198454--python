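"""Circular statistics for gaze-direction samples.

Implements the battery used for goal-directedness analyses of angular
data: mean direction and resultant length, the Rayleigh uniformity test
(Z = n·r² with the classic exponential tail approximation), Zar's 95%
confidence interval for the mean direction, the Mardia–Watson–Wheeler
(uniform-scores) two-sample test, and fixed-width binning for rose plots.

All public angles are degrees in [0, 360); computation is done in double
precision radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "CircSummary",
    "MWWResult",
    "circ_mean_and_r",
    "rayleigh_test",
    "rayleigh_p",
    "ci95_mean",
    "mww_test",
    "mww_chi2_p",
    "bin_angles",
    "sample_with_resultant",
    "CHI2_1_95",
]

#: 95th percentile of chi-squared with 1 df (used by Zar's CI formula)
CHI2_1_95 = 3.841458820694124


@dataclass(frozen=True)
class CircSummary:
    """Summary of one circular sample.

    ``mu_deg`` is NaN when the resultant is numerically zero (mean
    direction undefined).  CI bounds are None when the interval is not
    reliable (low concentration: Rayleigh p >= 0.05 or the CI formula
    leaves its domain).
    """

    n: int
    R: float
    r: float
    Z: float
    p: float
    mu_deg: float
    ci_lo_deg: float | None
    ci_hi_deg: float | None
    ci_reliable: bool


@dataclass(frozen=True)
class MWWResult:
    """Mardia–Watson–Wheeler uniform-scores test result."""

    W: float
    p: float
    method: str
    n1: int
    n2: int
    degenerate: bool = False


def _to_rad(angles_deg: Sequence[float]) -> np.ndarray:
    a = np.asarray(angles_deg, dtype=float)
    if a.ndim != 1:
        a = a.ravel()
    if a.size and not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    return np.radians(a)


def circ_mean_and_r(angles_deg: Sequence[float]) -> tuple[float, float, float]:
    """Mean direction µ (degrees in [0,360)), mean resultant length r and
    resultant length R of a sample of angles.

    µ is NaN for a numerically zero resultant (e.g. a perfectly balanced
    sample), where the mean direction is undefined by convention.
    """
    rad = _to_rad(angles_deg)
    n = rad.size
    if n < 1:
        raise ValueError("need at least one angle")
    C, S = float(np.cos(rad).sum()), float(np.sin(rad).sum())
    R = math.hypot(C, S)
    if R < 1e-12:
        mu = math.nan
    else:
        mu = math.degrees(math.atan2(S, C)) % 360.0
        if mu >= 360.0:  # guard against -0.0-degree wrap artifacts
            mu = 0.0
    return mu, R / n, R


def rayleigh_p(Z: float, n: int) -> float:
    """Rayleigh uniformity p-value from the statistic Z = n·r².

    Uses the exponential approximation
    p = exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n)) with R² = n·Z, clipped to
    [0, 1]; accurate to three decimals over the sample sizes used here.
    """
    if Z < 0 or n < 2:
        raise ValueError("need Z >= 0 and n >= 2")
    R2 = n * Z
    p = math.exp(math.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - R2)) - (1.0 + 2.0 * n))
    return min(max(p, 0.0), 1.0)


def ci95_mean(angles_deg: Sequence[float]) -> tuple[float | None, float | None, bool]:
    """Zar's 95% confidence interval for the mean direction.

    Two-branch half-width d: for r <= 0.9,
    d = arccos(√(2n(2R² − n·χ²₁) / (R²(4n − χ²₁)))); for r > 0.9,
    d = arccos(√(n² − (n² − R²)·exp(χ²₁/n)) / R), χ²₁ = 3.841459.

    Returns (lo, hi, reliable); the bounds are suppressed (None, None,
    False) when the sample is not significantly directed at α = 0.05 or
    the arccos argument leaves [0, 1] — the low-concentration regime where
    the interval is not reliable.
    """
    mu, r, R = circ_mean_and_r(angles_deg)
    n = len(np.atleast_1d(np.asarray(angles_deg)))
    if n < 2:
        raise ValueError("CI needs n >= 2")
    if math.isnan(mu) or rayleigh_p(n * r * r, n) >= 0.05:
        return None, None, False
    if r <= 0.9:
        num = 2.0 * n * (2.0 * R * R - n * CHI2_1_95)
        den = R * R * (4.0 * n - CHI2_1_95)
        arg2 = num / den
        arg = math.sqrt(arg2) if arg2 >= 0 else math.nan
    else:
        inner = n * n - (n * n - R * R) * math.exp(CHI2_1_95 / n)
        arg = math.sqrt(inner) / R if inner >= 0 else math.nan
    if not (0.0 <= arg <= 1.0):
        return None, None, False
    d = math.degrees(math.acos(arg))
    return (mu - d) % 360.0, (mu + d) % 360.0, True


def rayleigh_test(angles_deg: Sequence[float]) -> CircSummary:
    """Rayleigh uniformity test with full sample summary (Z = n·r²,
    p-value, mean direction and Zar 95% CI with reliability flag)."""
    a = np.asarray(angles_deg, dtype=float)
    n = a.size
    if n < 2:
        raise ValueError("Rayleigh test needs n >= 2")
    mu, r, R = circ_mean_and_r(a)
    Z = n * r * r
    p = rayleigh_p(Z, n)
    lo, hi, reliable = ci95_mean(a)
    return CircSummary(n=n, R=R, r=r, Z=Z, p=p, mu_deg=mu,
                       ci_lo_deg=lo, ci_hi_deg=hi, ci_reliable=reliable)


def mww_chi2_p(W: float) -> float:
    """Large-sample tail of the uniform-scores statistic: chi-squared with
    2 df, p = exp(−W/2)."""
    if W < 0:
        raise ValueError("W must be >= 0")
    return min(1.0, math.exp(-W / 2.0))


def _mww_w(beta: np.ndarray, mask1: np.ndarray, n1: int, n2: int) -> float:
    c1 = float(np.cos(beta[mask1]).sum())
    s1 = float(np.sin(beta[mask1]).sum())
    c2 = float(np.cos(beta[~mask1]).sum())
    s2 = float(np.sin(beta[~mask1]).sum())
    return 2.0 * ((c1 * c1 + s1 * s1) / n1 + (c2 * c2 + s2 * s2) / n2)


def mww_test(a_deg: Sequence[float], b_deg: Sequence[float],
             method: str = "auto", n_perm: int = 9999,
             seed: int | np.random.Generator | None = 0) -> MWWResult:
    """Mardia–Watson–Wheeler two-sample test on uniform scores.

    The combined sample is ranked (midranks for ties) and mapped to
    uniform scores β = 2π·rank/N; W = 2[(C₁²+S₁²)/n₁ + (C₂²+S₂²)/n₂].
    ``method``: 'chi2' (p = exp(−W/2), 2 df), 'permutation' (Monte-Carlo
    over random relabelings, seeded) or 'auto' (chi2 when both samples
    have at least 10 observations, else permutation).

    A combined sample of identical angles is degenerate: reported as
    W = 0, p = 1 with the flag set.
    """
    a = np.asarray(a_deg, dtype=float) % 360.0
    b = np.asarray(b_deg, dtype=float) % 360.0
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need n >= 2")
    if method not in ("chi2", "permutation", "auto"):
        raise ValueError(f"unknown method {method!r}")
    if method == "auto":
        method = "chi2" if min(n1, n2) >= 10 else "permutation"
    combined = np.concatenate([a, b])
    if np.allclose(combined, combined[0], atol=1e-12):
        return MWWResult(0.0, 1.0, method, n1, n2, degenerate=True)
    ranks = rankdata(combined)  # midranks for ties
    beta = 2.0 * np.pi * ranks / (n1 + n2)
    mask1 = np.zeros(n1 + n2, dtype=bool)
    mask1[:n1] = True
    W = _mww_w(beta, mask1, n1, n2)
    if method == "chi2":
        return MWWResult(W, mww_chi2_p(W), "chi2", n1, n2)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n1 + n2)
        if _mww_w(beta[perm], mask1, n1, n2) >= W - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return MWWResult(W, p, "permutation", n1, n2)


def bin_angles(angles_deg: Sequence[float], width_deg: float = 10.0) -> np.ndarray:
    """Counts per half-open bin [k·w, (k+1)·w) over the full circle.

    ``width_deg`` must divide 360; angles are reduced modulo 360 first.
    """
    nb = 360.0 / width_deg
    if abs(nb - round(nb)) > 1e-9:
        raise ValueError("bin width must divide 360")
    nb = int(round(nb))
    a = np.asarray(angles_deg, dtype=float) % 360.0
    idx = np.floor(a / width_deg).astype(int) % nb
    return np.bincount(idx, minlength=nb)


def sample_with_resultant(n: int, r: float, mu_deg: float = 0.0) -> np.ndarray:
    """Deterministic n-angle sample with exact mean resultant length r and
    mean direction µ.

    One angle sits at µ and (n−1)/2 symmetric pairs at µ ± a with
    a = arccos((n·r − 1)/(n − 1)) (odd n), or n/2 pairs at µ ± arccos(r)
    (even n).  Useful for calibrating statistics against reported (n, r)
    pairs without the underlying raw data.
    """
    if n < 2 or not 0.0 <= r <= 1.0:
        raise ValueError("need n >= 2 and r in [0, 1]")
    if n % 2 == 0:
        a = math.degrees(math.acos(r))
        half = [mu_deg + a] * (n // 2) + [mu_deg - a] * (n // 2)
        return np.asarray(half, dtype=float) % 360.0
    c = (n * r - 1.0) / (n - 1.0)
    if not -1.0 <= c <= 1.0:
        raise ValueError(f"no symmetric sample with n={n}, r={r}")
    a = math.degrees(math.acos(c))
    k = (n - 1) // 2
    return np.asarray([mu_deg] + [mu_deg + a] * k + [mu_deg - a] * k,
                      dtype=float) % 360.0
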