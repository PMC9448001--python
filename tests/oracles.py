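"""Independent brute-force oracles shared by the test suite."""

import numpy as np


def intermeans_fixed_points(h):
    """All t with partition low = bins <= s such that t = (m_low+m_high)/2
    lies in [s, s+1): the exhaustive fixed-point set of the intermeans map."""
    h = np.asarray(h, float)
    bins = np.arange(h.size)
    occ = np.nonzero(h)[0]
    out = []
    for s in range(occ[0], occ[-1]):
        low = bins <= s
        wl, wh = h[low].sum(), h[~low].sum()
        if wl == 0 or wh == 0:
            continue
        t = 0.5 * (np.sum(bins[low] * h[low]) / wl
                   + np.sum(bins[~low] * h[~low]) / wh)
        if s <= t < s + 1:
            out.append(t)
    return out


def triangle_exhaustive(h):
    """Naive per-bin perpendicular-distance scan, ties toward the peak."""
    h = np.asarray(h, float)
    occ = np.nonzero(h)[0]
    peak = int(np.argmax(h))
    left, right = occ[0], occ[-1]
    end = right if (right - peak) >= (peak - left) else left
    x0, y0, x1, y1 = float(peak), float(h[peak]), float(end), float(h[end])
    norm = np.hypot(x1 - x0, y1 - y0)
    candidates = range(peak, end + 1) if end > peak else range(peak, end - 1, -1)
    best, best_d = None, -1.0
    for x in candidates:
        d = abs((y1 - y0) * x - (x1 - x0) * h[x] + x1 * y0 - y1 * x0) / norm
        if d > best_d:
            best_d, best = d, x
    return best


def random_bimodal_histograms(n, seed):
    rng = np.random.default_rng(seed)
    x = np.arange(256)
    for _ in range(n):
        c1, c2 = rng.integers(10, 100), rng.integers(120, 240)
        s1, s2 = rng.uniform(3, 20), rng.uniform(3, 30)
        a1, a2 = rng.uniform(0.2, 1), rng.uniform(0.2, 1)
        yield np.round(1000 * (a1 * np.exp(-(x - c1) ** 2 / (2 * s1 ** 2))
                               + a2 * np.exp(-(x - c2) ** 2 / (2 * s2 ** 2))))
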