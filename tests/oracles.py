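"""Independent brute-force oracles for the kinematic features and image ops.

Everything here is deliberately written the slow, obvious way — explicit
loops, normal equations, flood fill — and shares no code with the package,
so agreement between the two is evidence both are right.
"""

from __future__ import annotations

import math

import numpy as np


def quadratic_rmsd_oracle(x, y):
    """RMS residual of y about a least-squares quadratic in x, via the
    explicitly assembled 3x3 normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xs = (x - x.mean()) / max(x.std(), 1e-12)
    n = len(xs)
    # normal equations for [a, b, c] in a*x^2 + b*x + c
    S = np.zeros((3, 3))
    rhs = np.zeros(3)
    for xi, yi in zip(xs, y):
        basis = [xi**2, xi, 1.0]
        for i in range(3):
            rhs[i] += basis[i] * yi
            for j in range(3):
                S[i, j] += basis[i] * basis[j]
    a, b, c = np.linalg.solve(S, rhs)
    sse = 0.0
    for xi, yi in zip(xs, y):
        sse += (yi - (a * xi**2 + b * xi + c)) ** 2
    return math.sqrt(sse / n)


def accel_variance_oracle(x, y):
    """Two-pass variance of the speed first-difference."""
    speeds = [
        math.hypot(x[i + 1] - x[i], y[i + 1] - y[i]) for i in range(len(x) - 1)
    ]
    accel = [speeds[i + 1] - speeds[i] for i in range(len(speeds) - 1)]
    mean = sum(accel) / len(accel)
    return sum((a - mean) ** 2 for a in accel) / len(accel)


def histogram_feature_oracle(x, n_frames):
    """Brute-force 4-equal-width-bin histogram of x, (max - median) / n."""
    xmin, xmax = min(x), max(x)
    width = (xmax - xmin) / 4.0
    counts = [0, 0, 0, 0]
    for xi in x:
        b = int((xi - xmin) // width) if width > 0 else 0
        counts[min(b, 3)] += 1
    ordered = sorted(counts)
    h_med = 0.5 * (ordered[1] + ordered[2])
    return (max(counts) - h_med) / n_frames


def angular_count_oracle(x, y):
    """Per-step loop over atan2 angles in the vertical bands."""
    count = 0
    for i in range(1, len(x)):
        dx = x[i] - x[i - 1]
        dy = y[i] - y[i - 1]
        if dx == 0 and dy == 0:
            continue
        theta = math.degrees(math.atan2(dy, dx))
        if 30 < theta < 150 or -150 < theta < -30:
            count += 1
    return count


def transport_speed_oracle(x, window):
    """|diff| of an explicitly looped centered moving average of x."""
    n = len(x)
    w = max(1, min(window, n))
    half = w // 2
    sm = []
    for i in range(n):
        acc = 0.0
        for j in range(i - half, i - half + w):
            acc += x[min(max(j, 0), n - 1)]
        sm.append(acc / w)
    return [abs(sm[i + 1] - sm[i]) for i in range(n - 1)]


def segmentation_oracle(x, threshold, window, merge_gap, min_run):
    """Independent re-derivation of the moving/dwell structure.

    Returns (initial_lengths, return_lengths, touch_epochs) following the
    same contract definition: threshold on smoothed x speed, bridge short
    sub-threshold blips, drop short runs, erode by window//2, classify
    transit direction by the first run's sign, touch epochs from the
    un-eroded dwells nearest the target extreme.
    """
    speed = transport_speed_oracle(x, window)
    moving = [s > threshold for s in speed]

    def runs(mask):
        out = []
        i = 0
        while i < len(mask):
            j = i
            while j + 1 < len(mask) and mask[j + 1] == mask[i]:
                j += 1
            out.append((mask[i], i, j))
            i = j + 1
        return out

    rr = runs(moving)
    for k, (m, a, b) in enumerate(rr):
        if not m and 0 < k < len(rr) - 1 and (b - a + 1) < merge_gap:
            for t in range(a, b + 1):
                moving[t] = True
    for m, a, b in runs(moving):
        if m and (b - a + 1) < min_run:
            for t in range(a, b + 1):
                moving[t] = False
    cleaned = list(moving)
    erode = window // 2
    eroded = [False] * len(moving)
    for m, a, b in runs(moving):
        if m and (b - a + 1) > 2 * erode:
            for t in range(a + erode, b - erode + 1):
                eroded[t] = True

    initial, ret = [], []
    first_sign = 0
    nose_x = target_x = None
    for m, a, b in runs(eroded):
        if not m:
            continue
        dx = x[b + 1] - x[a]
        sign = 1 if dx > 0 else (-1 if dx < 0 else 1)
        if first_sign == 0:
            first_sign = sign
            nose_x, target_x = x[a], x[b + 1]
        (initial if sign == first_sign else ret).append(b - a + 1)

    touch = []
    for m, a, b in runs(cleaned):
        if m:
            continue
        vals = [x[t] for t in range(a, min(b + 2, len(x)))]
        mean_x = sum(vals) / len(vals)
        if abs(mean_x - target_x) < abs(mean_x - nose_x):
            touch.append((a, b + 1))
    return initial, ret, touch


def avg_travel_oracle(x, y, epochs):
    """Direct summation of per-frame displacement over two touch epochs."""
    (m1, m2), (m3, m4) = epochs[0], epochs[1]
    total = 0.0
    for lo, hi in ((m1, m2), (m3, m4)):
        for i in range(max(lo, 1), hi + 1):
            total += math.hypot(x[i] - x[i - 1], y[i] - y[i - 1])
    return total / ((m2 - m1) + (m4 - m3) + 2)


def centroid_oracle(mask):
    """Center of mass of a binary mask, returned as (x, y)."""
    ys, xs = np.nonzero(mask)
    return float(xs.mean()), float(ys.mean())


def flood_fill_count_oracle(mask):
    """Number of 8-connected components, by iterative flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    h, w = mask.shape
    count = 0
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                count += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr_, cc_ = r + dr, c + dc
                            if (
                                0 <= rr_ < h
                                and 0 <= cc_ < w
                                and mask[rr_, cc_]
                                and not seen[rr_, cc_]
                            ):
                                seen[rr_, cc_] = True
                                stack.append((rr_, cc_))
    return count


def zero_crossing_count(signal):
    """Sign changes of a 1-D signal about its mean."""
    s = np.asarray(signal, dtype=float)
    s = s - s.mean()
    signs = np.sign(s)
    signs[signs == 0] = 1
    return int(np.sum(signs[1:] != signs[:-1]))
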