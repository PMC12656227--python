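"""Independent brute-force oracles used by the unit and acceptance suites.

These deliberately re-derive the detector and the ICC from first principles
with naive O(n^2) scans and explicit loops, sharing no code with the package
implementations they check.
"""
from __future__ import annotations

import numpy as np

from tapagree.signal_model import SampledSignal, TrialKey


def make_signal(values, rate=100.0, method="imu_acceleration", key=None) -> SampledSignal:
    values = np.asarray(values, dtype=float)
    key = key or TrialKey("SX", "preferred", 1)
    return SampledSignal(key, method, np.arange(values.size) / rate, values, rate)


def brute_force_local_maxima(x) -> list[int]:
    """Strict local maxima by direct scan; plateaus report their first sample."""
    x = np.asarray(x, dtype=float)
    n = x.size
    out = []
    i = 1
    while i < n - 1:
        if x[i] <= x[i - 1]:
            i += 1
            continue
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        if j < n - 1 and x[j + 1] < x[i]:
            out.append(i)
        i = j + 1
    return out


def brute_force_prominence(x, i) -> float:
    """Exact topographic prominence by full base search on each side."""
    x = np.asarray(x, dtype=float)
    h = x[i]
    mn = h
    k = i - 1
    while k >= 0 and x[k] <= h:
        if x[k] < mn:
            mn = x[k]
        k -= 1
    left_base = mn
    mn = h
    k = i + 1
    while k < x.size and x[k] <= h:
        if x[k] < mn:
            mn = x[k]
        k += 1
    right_base = mn
    return float(h - max(left_base, right_base))


def brute_force_find_peaks(
    times,
    values,
    min_distance=0.120,
    min_prominence_frac=0.20,
    polarity="maxima",
) -> list[float]:
    """Reference detector: enumeration + exact prominence + greedy filter.

    Candidates are ranked by descending prominence with earlier time breaking
    ties; each is kept iff it lies >= min_distance (minus 1 ns float slack)
    from everything already kept.  Returns the kept event times, sorted.
    """
    times = np.asarray(times, dtype=float)
    x = np.asarray(values, dtype=float)
    if polarity == "minima":
        x = -x
    amplitude = x.max() - x.min()
    cands = brute_force_local_maxima(x)
    scored = []
    for i in cands:
        p = brute_force_prominence(x, i)
        if p >= min_prominence_frac * amplitude:
            scored.append((p, times[i]))
    scored.sort(key=lambda pt: (-pt[0], pt[1]))
    kept: list[float] = []
    for _, t in scored:
        if all(abs(t - tk) >= min_distance - 1e-9 for tk in kept):
            kept.append(t)
    return sorted(kept)


def icc_a1_bruteforce(x) -> float:
    """ICC(A,1) from explicit sums of squares, no shared code paths."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = 0.0
    for i in range(n):
        for j in range(k):
            grand += x[i, j]
    grand /= n * k
    ssr = sum(k * (sum(x[i, j] for j in range(k)) / k - grand) ** 2 for i in range(n))
    ssc = sum(n * (sum(x[i, j] for i in range(n)) / n - grand) ** 2 for j in range(k))
    sst = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def random_detector_signal(rng: np.random.Generator, max_len=1000):
    """A random stream exercising plateaus, ties, noise and tonal structure."""
    n = int(rng.integers(10, max_len + 1))
    kind = rng.integers(0, 4)
    t = np.arange(n) / 100.0
    if kind == 0:
        v = rng.normal(0, 1, n)
    elif kind == 1:
        v = np.round(rng.normal(0, 1, n), 1)  # quantized: ties and plateaus
    elif kind == 2:
        f = rng.uniform(0.5, 8.0)
        v = np.sin(2 * np.pi * f * t) + rng.normal(0, 0.3, n)
    else:
        v = np.cumsum(rng.normal(0, 1, n))
    return t, v
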