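"""Independent brute-force reference implementations used only by tests.

Deliberately naive (python loops, direct DFT sums) and written without
reference to the package's vectorized code paths.
"""

import cmath
import math


def o_mean(x):
    return sum(x) / len(x)


def o_median(x):
    s = sorted(x)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2


def o_std(x):
    m = o_mean(x)
    return math.sqrt(sum((v - m) ** 2 for v in x) / len(x))


def o_sum_abs(x):
    return sum(abs(v) for v in x)


def o_ptp(x):
    return max(x) - min(x)


def o_rms(x):
    return math.sqrt(sum(v * v for v in x) / len(x))


def o_zcr(x):
    m = o_mean(x)
    c = [v - m for v in x]
    last = 0
    crossings = 0
    for v in c:
        s = int(v > 0) - int(v < 0)
        if s != 0:
            if last != 0 and s != last:
                crossings += 1
            last = s
    return crossings / (len(x) - 1)


def o_avg_variation(x):
    return sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1)) / (len(x) - 1)


def o_skew_kurt(x):
    m = o_mean(x)
    n = len(x)
    m2 = sum((v - m) ** 2 for v in x) / n
    if m2 < 1e-24:
        return 0.0, 0.0
    m3 = sum((v - m) ** 3 for v in x) / n
    m4 = sum((v - m) ** 4 for v in x) / n
    return m3 / m2 ** 1.5, m4 / m2 ** 2 - 3.0


def o_peaks(x):
    """Interior local maxima; plateau -> first index."""
    peaks = []
    n = len(x)
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    return peaks


def o_time_between_peaks(x, fs):
    p = o_peaks(x)
    if len(p) < 2:
        return 0.0
    gaps = [p[i + 1] - p[i] for i in range(len(p) - 1)]
    return sum(gaps) / len(gaps) / fs


def o_periodogram(x, fs):
    """One-sided boxcar density periodogram of the mean-removed signal."""
    n = len(x)
    m = o_mean(x)
    c = [v - m for v in x]
    out = []
    for k in range(n // 2 + 1):
        X = sum(c[t] * cmath.exp(-2j * math.pi * k * t / n) for t in range(n))
        p = abs(X) ** 2 / (fs * n)
        if 0 < k and not (n % 2 == 0 and k == n // 2):
            p *= 2
        out.append((k * fs / n, p))
    return out


def o_spectral(x, fs):
    grid = o_periodogram(x, fs)
    best = max(grid[1:], key=lambda fp: fp[1])  # max keeps FIRST maximum
    return best


def o_mann_whitney_count(g1, g2):
    """U of group 1 by exhaustive pairwise comparison."""
    u = 0.0
    for a in g1:
        for b in g2:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u
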