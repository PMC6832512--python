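"""Independent brute-force implementations of the feature-function formulas.

Deliberately written from the printed formulas with explicit loops and
no reuse of the package's code paths, so they can serve as oracles for
the production feature bank.
"""

from __future__ import annotations

import math

import numpy as np


def o_mean(s):
    return sum(float(v) for v in s) / len(s)


def o_std(s):
    m = o_mean(s)
    return math.sqrt(sum((float(v) - m) ** 2 for v in s) / len(s))


def _median(vals):
    v = sorted(float(x) for x in vals)
    n = len(v)
    mid = n // 2
    return v[mid] if n % 2 else 0.5 * (v[mid - 1] + v[mid])


def o_mad(s):
    med = _median(s)
    return _median([abs(float(v) - med) for v in s])


def o_max(s):
    return max(float(v) for v in s)


def o_min(s):
    return min(float(v) for v in s)


def o_energy(s):
    return sum(float(v) ** 2 for v in s) / len(s)


def o_sma(s1, s2=None, s3=None):
    if s2 is None:
        return sum(abs(float(v)) for v in s1) / len(s1)
    total = 0.0
    for s in (s1, s2, s3):
        total += sum(abs(float(v)) for v in s) / len(s)
    return total / 3.0


def o_entropy(s):
    a = [abs(float(v)) for v in s]
    tot = sum(a)
    if tot == 0:
        return 0.0
    h = 0.0
    for v in a:
        p = v / tot
        if p > 0:
            h -= p * math.log(p)
    return h


def _quantile_linear(s, q):
    """Linear-interpolation quantile, coded from the definition."""
    v = sorted(float(x) for x in s)
    pos = q * (len(v) - 1)
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def o_iqr(s):
    return _quantile_linear(s, 0.75) - _quantile_linear(s, 0.25)


def o_burg(s, order=4):
    """Classic Burg lattice recursion; positive-AR-parameter convention."""
    x = np.asarray(s, float)
    if np.ptp(x) == 0:
        return np.zeros(order)
    a = np.array([1.0])
    ef = x[1:].copy()
    eb = x[:-1].copy()
    for _ in range(order):
        den = np.dot(ef, ef) + np.dot(eb, eb)
        k = -2.0 * np.dot(eb, ef) / den
        ef_new = ef + k * eb
        eb_new = eb + k * ef
        a = np.concatenate([a, [0.0]]) + k * np.concatenate([[0.0], a[::-1]])
        ef = ef_new[1:]
        eb = eb_new[:-1]
    return -a[1:]


def o_correlation(s1, s2):
    m1, m2 = o_mean(s1), o_mean(s2)
    cov = sum((float(a) - m1) * (float(b) - m2) for a, b in zip(s1, s2))
    v1 = sum((float(a) - m1) ** 2 for a in s1)
    v2 = sum((float(b) - m2) ** 2 for b in s2)
    if v1 == 0 or v2 == 0:
        return 0.0
    return cov / math.sqrt(v1 * v2)


def o_angle(u, v):
    ux, uy, uz = (float(x) for x in u)
    vx, vy, vz = (float(x) for x in v)
    cx = uy * vz - uz * vy
    cy = uz * vx - ux * vz
    cz = ux * vy - uy * vx
    cross = math.sqrt(cx * cx + cy * cy + cz * cz)
    dot = ux * vx + uy * vy + uz * vz
    if (ux == uy == uz == 0) or (vx == vy == vz == 0):
        return 0.0
    return math.atan2(cross, dot)


def o_range(s):
    return o_max(s) - o_min(s)


def o_rms(s):
    return math.sqrt(o_energy(s))


def o_skewness(s):
    m = o_mean(s)
    m2 = sum((float(v) - m) ** 2 for v in s) / len(s)
    if m2 == 0:
        return 0.0
    m3 = sum((float(v) - m) ** 3 for v in s) / len(s)
    return m3 / m2**1.5


def o_kurtosis(s):
    m = o_mean(s)
    m2 = sum((float(v) - m) ** 2 for v in s) / len(s)
    if m2 == 0:
        return 0.0
    m4 = sum((float(v) - m) ** 4 for v in s) / len(s)
    return m4 / m2**2


def o_max_freq_ind(s):
    best, arg = -math.inf, 0
    for i, v in enumerate(s):
        if float(v) > best:
            best, arg = float(v), i
    return arg


def o_mean_freq(s):
    tot = sum(float(v) for v in s)
    if tot == 0:
        return 0.0
    return sum((i + 1) * float(v) for i, v in enumerate(s)) / tot


def o_energy_band(s, a, b):
    vals = [float(s[i - 1]) ** 2 for i in range(a, b + 1)]
    return sum(vals) / (b - a + 1)
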