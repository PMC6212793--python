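"""Independent brute-force reference implementations used only by tests.

Each oracle is a literal, unoptimised transcription of the operation's
definition, kept deliberately separate from the library's vectorised code
paths.
"""

from __future__ import annotations

import math

import numpy as np


def median_filter_clipped(img: np.ndarray, radius: int) -> np.ndarray:
    """Per-pixel sort-and-middle median over the edge-clipped square window."""
    h, w = img.shape
    out = np.empty_like(img, dtype=float)
    for y in range(h):
        for x in range(w):
            vals = []
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w:
                        vals.append(img[yy, xx])
            vals.sort()
            n = len(vals)
            mid = n // 2
            out[y, x] = vals[mid] if n % 2 else 0.5 * (vals[mid - 1] + vals[mid])
    return out


def gaussian_blur_reflect(img: np.ndarray, sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Separable Gaussian convolution with reflect ('symmetric') padding."""
    r = int(truncate * sigma + 0.5)
    xs = np.arange(-r, r + 1)
    kernel = np.exp(-0.5 * (xs / sigma) ** 2)
    kernel /= kernel.sum()
    padded = np.pad(img, r, mode="symmetric")
    tmp = np.empty_like(padded, dtype=float)
    for row in range(padded.shape[0]):
        tmp[row] = np.convolve(padded[row], kernel, mode="same")
    for col in range(tmp.shape[1]):
        tmp[:, col] = np.convolve(tmp[:, col], kernel, mode="same")
    return tmp[r:-r, r:-r]


def median_and_mad(values) -> tuple[float, float]:
    """Sort-based median and MAD-derived robust SD."""
    vals = sorted(float(v) for v in values)
    n = len(vals)

    def med(sorted_vals):
        m = len(sorted_vals) // 2
        if len(sorted_vals) % 2:
            return sorted_vals[m]
        return 0.5 * (sorted_vals[m - 1] + sorted_vals[m])

    centre = med(vals)
    deviations = sorted(abs(v - centre) for v in vals)
    return centre, 1.4826 * med(deviations)


def detect_foci_literal(
    filtered: np.ndarray,
    labels: np.ndarray,
    fold_k: float,
    abs_min: float,
    min_focus_area: int,
    connectivity: int = 8,
    use_per_nucleus_sd: bool = False,
):
    """Pixel-by-pixel application of the two focus criteria.

    Returns a list of (nucleus_id, frozenset of (y, x) members) per kept
    focus.  Background statistics are recomputed here with sort-based
    median/MAD; the image-wide reference SD is the median of per-nucleus
    SDs.
    """
    h, w = filtered.shape
    n = int(labels.max())
    centres, sds = {}, {}
    for nid in range(1, n + 1):
        vals = [filtered[y, x] for y in range(h) for x in range(w) if labels[y, x] == nid]
        centres[nid], sds[nid] = median_and_mad(vals)
    global_sd = median_and_mad(sds.values())[0] if sds else 0.0

    if connectivity == 8:
        neigh = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    else:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]

    foci = []
    for nid in range(1, n + 1):
        sd = sds[nid] if use_per_nucleus_sd else global_sd
        thr = centres[nid] + fold_k * sd
        candidate = {
            (y, x)
            for y in range(h)
            for x in range(w)
            if labels[y, x] == nid and filtered[y, x] > thr and filtered[y, x] > abs_min
        }
        seen: set[tuple[int, int]] = set()
        for start in sorted(candidate):
            if start in seen:
                continue
            group = {start}
            queue = [start]
            while queue:
                y, x = queue.pop()
                for dy, dx in neigh:
                    nb = (y + dy, x + dx)
                    if nb in candidate and nb not in group:
                        group.add(nb)
                        queue.append(nb)
            seen |= group
            if len(group) > min_focus_area:
                foci.append((nid, frozenset(group)))
    return foci, global_sd


def cut_fraction_reference(t: float, t_lag: float, tau: float, p_max: float) -> float:
    if t <= t_lag:
        return 0.0
    return p_max * (1.0 - math.exp(-(t - t_lag) / tau))
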