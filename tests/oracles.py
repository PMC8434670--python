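"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (plain loops,
quadrature, exact arithmetic) and shares no code with the package.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad


def centered_ma_bruteforce(y, window):
    """Centered moving average with symmetric truncation, plain loops."""
    y = list(map(float, y))
    n = len(y)
    half = window // 2
    out = []
    for i in range(n):
        k = min(half, i, n - 1 - i)
        vals = y[i - k : i + k + 1]
        out.append(sum(vals) / len(vals))
    return np.array(out)


def pav_antitonic_bruteforce(y):
    """Pool-adjacent-violators projection onto the non-increasing cone.

    Maintains blocks (sum, count); a violator (earlier block smaller than a
    later one) is pooled until the block means are non-increasing.
    """
    blocks = [[float(v), 1] for v in y]
    i = 0
    while i < len(blocks) - 1:
        if blocks[i][0] / blocks[i][1] < blocks[i + 1][0] / blocks[i + 1][1] - 1e-15 * abs(blocks[i][0]):
            s, c = blocks[i][0] + blocks[i + 1][0], blocks[i][1] + blocks[i + 1][1]
            blocks[i : i + 2] = [[s, c]]
            i = max(i - 1, 0)
        else:
            i += 1
    out = []
    for s, c in blocks:
        out.extend([s / c] * c)
    return np.array(out)


def smooth_bruteforce(y, window):
    """The full cleaning smoother: window average then antitonic projection."""
    return pav_antitonic_bruteforce(centered_ma_bruteforce(y, window))


def increase_runs_bruteforce(v):
    """All maximal runs of consecutive increases, as (i, j, gain)."""
    v = list(map(float, v))
    runs = []
    in_run = False
    for k in range(1, len(v)):
        if v[k] > v[k - 1]:
            if not in_run:
                i = k
                in_run = True
            j = k
        else:
            if in_run:
                runs.append((i, j, v[j] - v[i - 1]))
            in_run = False
    if in_run:
        runs.append((i, j, v[j] - v[i - 1]))
    return runs


def refills_bruteforce(v, threshold, halo=0):
    """Refill events: thresholded increase runs pinned to the largest raw
    single-interval increase within the run's halo neighbourhood."""
    v = list(map(float, v))
    events = {}
    for i, j, gain in increase_runs_bruteforce(v):
        if gain >= threshold:
            lo, hi = max(1, i - halo), min(len(v) - 1, j + halo)
            best, best_d = lo, v[lo] - v[lo - 1]
            for k in range(lo, hi + 1):
                d = v[k] - v[k - 1]
                if d > best_d:
                    best, best_d = k, d
            events[best] = gain
    return sorted(events.items())


def cone_cylinder_volume_quadrature(diameter, cone_height, body_height, fill_height, n=200_001):
    """Occupied volume by trapezoid integration of the cross-section area."""
    R = diameter / 2.0

    def radius(h):
        return np.where(h <= cone_height, R * h / cone_height, R)

    h = np.linspace(0.0, fill_height, n)
    area = np.pi * radius(h) ** 2
    return float(np.trapezoid(area, h))


def mixture_bin_count_quadrature(means, sds, ns, low, high):
    """Expected head count in [low, high) by quadrature of the mixture density."""

    def pdf(x):
        tot = 0.0
        for m, s, n in zip(means, sds, ns):
            tot += n * np.exp(-0.5 * ((x - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
        return tot

    val, _ = quad(pdf, low, high, limit=200)
    return val


def logistic_afi_highprecision(A, b, age, dps=50):
    """Arbitrary-precision evaluation of A / (1 + exp(-b*age)) via sympy."""
    import sympy as sp

    A_, b_, age_ = sp.Rational(str(A)), sp.Rational(str(b)), sp.Rational(str(age))
    val = A_ / (1 + sp.exp(-b_ * age_))
    return float(sp.N(val, dps))


def alerts_bruteforce(dev, threshold, consecutive, undeclared_weeks, data_check_first=True):
    """Exhaustive evaluation of the growth/verify alert rule.

    Returns (kind, first_week, magnitude) per qualifying maximal run.
    """
    dev = list(map(float, dev))
    n = len(dev)
    exceed = [abs(d) > threshold for d in dev]
    out = []
    k = 0
    while k < n:
        if exceed[k]:
            end = k
            while end + 1 < n and exceed[end + 1]:
                end += 1
            if end - k + 1 >= consecutive:
                bad = [w for w in undeclared_weeks if k <= w <= end]
                if data_check_first and bad:
                    out.append(("verify_refill_data", k, dev[k]))
                else:
                    out.append(("growth_deviation", k, dev[k]))
            k = end + 1
        else:
            k += 1
    return out
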