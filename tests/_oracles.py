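"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized code paths: densities are
direct per-position sums, maxima enumeration and the exclusion rule are
exhaustive, pairing scans every admissible couple, and statistics are
textbook loops.
"""

from __future__ import annotations

import math
from collections import Counter


def brute_density(tags, sigma, truncation=4.0):
    """pos -> sum of truncated Gaussian kernels, direct double loop."""
    h = math.ceil(truncation * sigma)
    dens = {}
    for t in tags:
        for p in range(t - h, t + h + 1):
            dens[p] = dens.get(p, 0.0) + math.exp(-((p - t) ** 2) / (2 * sigma * sigma))
    return dens


def _eq(a, b, tol=1e-9):
    return abs(a - b) <= tol * max(abs(a), abs(b))


def brute_local_maxima(dens):
    """Local maxima; near-ties (rel 1e-9) form plateaus, leftmost wins."""
    if not dens:
        return []
    lo, hi = min(dens), max(dens)
    out = []
    p = lo + 1
    while p < hi:
        v = dens.get(p, 0.0)
        prev = dens.get(p - 1, 0.0)
        if v > prev and not _eq(v, prev):
            q = p
            while q + 1 <= hi and _eq(dens.get(q + 1, 0.0), v):
                q += 1
            if q + 1 > hi or dens.get(q + 1, 0.0) < v:
                out.append((p, v))
            p = q + 1
        else:
            p += 1
    return out


def brute_call_peaks(tags, sigma=20.0, exclusion_zone=40, truncation=4.0):
    """Exhaustive greedy exclusion: (summit, height, tag_count) list."""
    tags = sorted(tags)
    if not tags:
        return []
    dens = brute_density(tags, sigma, truncation)
    cands = sorted(brute_local_maxima(dens), key=lambda sv: (-round(sv[1], 6), sv[0]))
    retained = []
    for summit, height in cands:
        if all(abs(summit - r) >= exclusion_zone for r, _ in retained):
            retained.append((summit, height))
    half = exclusion_zone // 2
    peaks = []
    for summit, height in sorted(retained):
        count = sum(1 for t in tags if summit - half <= t <= summit + half)
        if count >= 1:
            peaks.append((summit, height, count))
    return peaks


def brute_pair(w_peaks, c_peaks, max_span=80):
    """w_peaks/c_peaks: (summit, tag_count) lists. Applies the documented
    priority (span, -combined count, w summit) over all admissible couples."""
    cands = []
    for i, (w, wc) in enumerate(w_peaks):
        for j, (c, cc) in enumerate(c_peaks):
            if 0 <= c - w <= max_span:
                cands.append((c - w, -(wc + cc), w, i, j))
    used_w, used_c, out = set(), set(), []
    for span, negocc, w, i, j in sorted(cands):
        if i in used_w or j in used_c:
            continue
        used_w.add(i)
        used_c.add(j)
        out.append((w_peaks[i][0], c_peaks[j][0], -negocc))
    return sorted(out)


def brute_match(mids_a, mids_b, window):
    return [m for m in mids_a if any(abs(m - b) <= window for b in mids_b)]


def brute_mean(xs):
    return sum(xs) / len(xs)


def brute_sd(xs):
    m = brute_mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def brute_pearson(xs, ys):
    mx, my = brute_mean(xs), brute_mean(ys)
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = math.sqrt(sum((x - mx) ** 2 for x in xs) * sum((y - my) ** 2 for y in ys))
    return num / den


def brute_moving_average(xs, window):
    return [brute_mean(xs[i:i + window]) for i in range(len(xs) - window + 1)]


def mode_count(values):
    return Counter(values).most_common(1)[0]
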