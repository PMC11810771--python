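"""Independent brute-force oracles used by the test suite.

Everything here is written as straight-line, loop-based code, deliberately
ignorant of the package's internals, so that agreement with the package is
evidence of correctness rather than shared bugs.
"""

import math

import numpy as np


def conv2d_loops(img, ker):
    """Direct double-loop edge-clamped correlation."""
    H, W = img.shape
    K = ker.shape[0]
    c = K // 2
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            for u in range(K):
                for v in range(K):
                    ii = min(max(i + u - c, 0), H - 1)
                    jj = min(max(j + v - c, 0), W - 1)
                    out[i, j] += ker[u, v] * img[ii, jj]
    return out


def catmull_rom_weight(t):
    t = abs(t)
    if t <= 1.0:
        return 1.5 * t**3 - 2.5 * t**2 + 1.0
    if t <= 2.0:
        return -0.5 * t**3 + 2.5 * t**2 - 4.0 * t + 2.0
    return 0.0


def catmull_rom_loops(frame, m):
    """Scalar evaluation of the 4×4-tap separable weighted sum per output pixel."""
    H, W = frame.shape
    out = np.zeros((m * H, m * W))
    for oi in range(m * H):
        for oj in range(m * W):
            x = oi / m
            y = oj / m
            bi = math.floor(x)
            bj = math.floor(y)
            acc = 0.0
            for ty in range(-1, 3):
                for tx in range(-1, 3):
                    ii = min(max(bi + ty, 0), H - 1)
                    jj = min(max(bj + tx, 0), W - 1)
                    acc += (
                        catmull_rom_weight(x - (bi + ty))
                        * catmull_rom_weight(y - (bj + tx))
                        * frame[ii, jj]
                    )
            out[oi, oj] = acc
    return out


def nlm_loops(img, patch_size, patch_distance, sigma, h):
    """Quadruple-loop nonlocal means: every patch distance and weight explicit."""
    H, W = img.shape
    ps = patch_size if patch_size % 2 == 1 else patch_size + 1
    r = ps // 2
    out = np.zeros_like(img)
    for i in range(H):
        for j in range(W):
            num = 0.0
            den = 0.0
            for y in range(max(0, i - patch_distance), min(H, i + patch_distance + 1)):
                for x in range(max(0, j - patch_distance), min(W, j + patch_distance + 1)):
                    d2 = 0.0
                    for qy in range(-r, r + 1):
                        for qx in range(-r, r + 1):
                            a = img[min(max(i + qy, 0), H - 1), min(max(j + qx, 0), W - 1)]
                            b = img[min(max(y + qy, 0), H - 1), min(max(x + qx, 0), W - 1)]
                            d2 += (a - b) ** 2
                    d2 /= ps * ps
                    w = math.exp(-max(d2 - 2.0 * sigma**2, 0.0) / h**2)
                    num += w * img[y, x]
                    den += w
            out[i, j] = num / den
    return out


# --- straight-line re-implementations of the agent's closed forms -----------

def split_stats_lines(times):
    """Sort, halve (median to the fast half), mean + population stddev."""
    ts = sorted(float(t) for t in times)
    half = (len(ts) + 1) // 2
    fast, slow = ts[:half], ts[half:]

    def mean(v):
        return sum(v) / len(v)

    def std(v):
        m = mean(v)
        return math.sqrt(sum((x - m) ** 2 for x in v) / len(v))

    return mean(fast), std(fast), mean(slow), std(slow)


def detect_delay_line(measured, fast_average, fast_stddev):
    return measured > fast_average + 4 * fast_stddev


def delay_factor_line(measured, fast_average):
    return measured / fast_average


def adjusted_run_time_line(fast_average, factor, p):
    return fast_average * (1.0 - p) + fast_average * factor * p


def selection_probabilities_lines(adjusted):
    inv = {k: 1.0 / (t * t) for k, t in adjusted.items()}
    total = sum(inv.values())
    return {k: v / total for k, v in inv.items()}


def delay_over_line(measured, fast_average, fast_stddev, slow_average, slow_stddev):
    return (measured < slow_average - slow_stddev) or (
        measured < fast_average + fast_stddev
    )


def fuzzy_score_lines(query, candidate):
    total = 0.0
    for q, c in zip(query, candidate):
        if c == 0.0:
            total += 1.0 if q == 0.0 else 0.0
        else:
            total += max(0.0, 1.0 - abs(q - c) / abs(c))
    return total / len(query)
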