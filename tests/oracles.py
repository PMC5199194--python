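"""Independent brute-force oracles used to cross-check the pipeline.

Every function here recomputes a pipeline quantity by direct enumeration
or the textbook formula, sharing no code with the package.
"""

import numpy as np


def _reflect_pad(x, k):
    # (d c b a | a b c d | d c b a) reflection about the array edge
    left = x[k - 1::-1] if k > 0 else x[:0]
    right = x[:-k - 1:-1] if k > 0 else x[:0]
    return np.concatenate([left, x, right])


def median_filter_brute(x, n_window):
    """Running median, odd window, reflect padding, by explicit loop."""
    assert n_window % 2 == 1
    k = n_window // 2
    xp = _reflect_pad(np.asarray(x, float), k)
    return np.array([np.median(xp[i:i + n_window])
                     for i in range(len(x))])


def mean_filter_brute(x, n_window):
    """Running mean, reflect padding; even windows span
    [i - n//2, i + n - n//2)."""
    k = n_window // 2
    xp = _reflect_pad(np.asarray(x, float), n_window)
    out = np.empty(len(x))
    for i in range(len(x)):
        j = i + n_window - k  # start of window in padded coordinates
        out[i] = np.mean(xp[j:j + n_window])
    return out


def cycle_average_brute(trace, fs, onset, period, win_start, win_end,
                        n_cycles, adaptation_ratio):
    """Direct window extraction and both candidate averages."""
    n = int(round((win_end - win_start) * fs))
    wins = []
    for c in range(n_cycles):
        i0 = int(round((onset + c * period + win_start) * fs))
        wins.append(np.asarray(trace, float)[i0:i0 + n])
    wins = np.array(wins)
    amps = wins.max(axis=1) - wins.min(axis=1)
    if amps[2] < adaptation_ratio * 0.5 * (amps[0] + amps[1]):
        return wins[:2].mean(axis=0), 2
    return wins.mean(axis=0), 3


def ks_two_sample_brute(a, b):
    """Max ECDF gap over the pooled sample points."""
    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    pts = np.concatenate([a, b])
    d = 0.0
    for x in pts:
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        d = max(d, abs(fa - fb))
    return d


def ks_uniform_brute(d, hi=90.0):
    """One-sample K-S statistic against Uniform(0, hi) by enumeration."""
    d = np.sort(np.asarray(d, float))
    n = d.size
    stat = 0.0
    for i, x in enumerate(d, start=1):
        cdf = x / hi
        stat = max(stat, abs(i / n - cdf), abs((i - 1) / n - cdf))
    return stat


def paired_t_brute(a, b):
    """t = mean(d) / (sd(d)/sqrt(n)) with sample SD."""
    d = np.asarray(a, float) - np.asarray(b, float)
    n = d.size
    return np.mean(d) / (np.std(d, ddof=1) / np.sqrt(n))


def pearson_brute(a, b):
    """Covariance formula by direct summation."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return np.sum(am * bm) / np.sqrt(np.sum(am ** 2) * np.sum(bm ** 2))


def delta_orientation_brute(a, b):
    """Smallest rotation between two orientations on the 180-deg circle,
    by explicit minimization over equivalent representations."""
    cands = [abs((a + 180 * i) - (b + 180 * j))
             for i in (-1, 0, 1) for j in (-1, 0, 1)]
    return min(cands)


def orientation_vector_brute(directions, magnitudes):
    """Vector sum by explicit trigonometric accumulation."""
    r = np.clip(np.asarray(magnitudes, float), 0, None)
    sx = sum(ri * np.cos(2 * np.radians(th))
             for ri, th in zip(r, directions))
    sy = sum(ri * np.sin(2 * np.radians(th))
             for ri, th in zip(r, directions))
    s = r.sum()
    if s == 0:
        return 0.0, None
    gosi = np.hypot(sx, sy) / s
    if gosi == 0:
        return 0.0, None
    half = np.degrees(np.arctan2(sy, sx)) / 2.0
    pref = half - 90.0
    while pref < -90:
        pref += 180.0
    while pref >= 90:
        pref -= 180.0
    return gosi, pref
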