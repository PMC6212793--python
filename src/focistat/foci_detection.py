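"""Per-nucleus damage-focus calling on the background-subtracted marker channel.

A focus is a connected group of pixels inside a nucleus whose
Difference-of-Gaussians-filtered intensity (i) exceeds the nuclear
background by a set multiple (typically 2-fold) of the median background
standard deviation of all nuclei in the image, and is above a user-defined
absolute minimum, and (ii) covers an area strictly larger than a defined
number of pixels (typically 16).

The "nuclear background signal" is estimated robustly: per-nucleus median
of the filtered signal, with spread 1.4826 x the median absolute deviation
(the Gaussian-consistent MAD); the image-level reference spread is the
median of the per-nucleus spreads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.stats import t as t_dist

__all__ = [
    "DetectionParams",
    "NucleusStats",
    "Focus",
    "FociResult",
    "ConditionSummary",
    "dog_filter",
    "background_stats",
    "detect_foci",
    "count_summary",
]

_MAD_SCALE = 1.4826  # consistency factor: MAD -> SD for a normal distribution


def _as_pixels(image) -> np.ndarray:
    from focistat.segmentation import ImageField

    return image.pixels if isinstance(image, ImageField) else np.asarray(image, dtype=float)


def _as_labels(labels) -> np.ndarray:
    from focistat.segmentation import LabelMap

    return labels.labels if hasattr(labels, "labels") else np.asarray(labels)


@dataclass(frozen=True)
class DetectionParams:
    """Focus-calling parameters.

    ``abs_min=None`` means "derive from the image": the 95th percentile of
    the filtered signal outside all nuclei.  ``use_per_nucleus_sd`` switches
    the intensity criterion from the image-wide median background SD to
    each nucleus's own SD (the alternative reading of the 2-fold rule).
    """

    dog_sigma_small: float = 2.0
    dog_sigma_large: float = 6.0
    fold_k: float = 2.0
    abs_min: float | None = None
    min_focus_area: int = 16
    connectivity: int = 8
    use_per_nucleus_sd: bool = False

    def __post_init__(self) -> None:
        if not self.dog_sigma_small < self.dog_sigma_large:
            raise ValueError("dog_sigma_small must be < dog_sigma_large")
        if self.fold_k <= 0:
            raise ValueError("fold_k must be > 0")
        if self.min_focus_area < 1:
            raise ValueError("min_focus_area must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class NucleusStats:
    nucleus_id: int
    bg_center: float
    bg_sd: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.bg_sd < 0:
            raise ValueError("bg_sd must be >= 0")


@dataclass(frozen=True)
class Focus:
    """One detected focus; centroid is (x=column, y=row), 0-based."""

    nucleus_id: int
    centroid: tuple[float, float]
    area: int
    mean_intensity: float
    max_intensity: float
    pixels: tuple[tuple[int, int], ...] = ()  # (y, x) members, only when requested


@dataclass(frozen=True)
class FociResult:
    foci: tuple[Focus, ...]
    counts: dict[int, int]  # nucleus_id -> focus count
    global_sd: float

    def count(self, nucleus_id: int) -> int:
        return self.counts[nucleus_id]


def dog_filter(marker, params: DetectionParams = DetectionParams()):
    """Difference-of-Gaussians band-pass: blur(sigma_small) - blur(sigma_large).

    Output may be negative; boundaries are handled by reflection.
    """
    px = _as_pixels(marker)
    lo = ndi.gaussian_filter(px, params.dog_sigma_small, mode="reflect")
    hi = ndi.gaussian_filter(px, params.dog_sigma_large, mode="reflect")
    return lo - hi


def background_stats(filtered, labels):
    """Robust per-nucleus background of the filtered image.

    Returns ``(stats, global_sd)``: per-nucleus medians and MAD-based SDs,
    and the median of those SDs across nuclei.
    """
    fpx = np.asarray(filtered, dtype=float)
    lab = _as_labels(labels)
    n = int(lab.max(initial=0))
    if n == 0:
        raise ValueError("empty label map: no nuclei to analyze")
    stats: list[NucleusStats] = []
    for nid in range(1, n + 1):
        values = fpx[lab == nid]
        med = float(np.median(values))
        mad = float(np.median(np.abs(values - med)))
        stats.append(NucleusStats(nid, med, _MAD_SCALE * mad, int(values.size)))
    global_sd = float(np.median([s.bg_sd for s in stats]))
    return stats, global_sd


def _resolve_abs_min(fpx: np.ndarray, lab: np.ndarray, params: DetectionParams) -> float:
    if params.abs_min is not None:
        return params.abs_min
    outside = fpx[lab == 0]
    if outside.size == 0:
        return -np.inf
    return float(np.percentile(outside, 95))


def detect_foci(
    filtered,
    labels,
    stats: Sequence[NucleusStats],
    global_sd: float,
    params: DetectionParams = DetectionParams(),
    keep_pixels: bool = False,
) -> FociResult:
    """Apply the two focus criteria per nucleus and emit detected foci.

    Candidate pixels in nucleus j satisfy
    ``filtered > bg_center_j + fold_k * sd`` (sd = image-wide median
    background SD, or nucleus j's own SD with ``use_per_nucleus_sd``) and
    ``filtered > abs_min``; candidates are grouped by ``connectivity`` and
    groups are kept only when strictly larger than ``min_focus_area``.
    Intensity summaries are measured on the filtered image.
    """
    fpx = np.asarray(filtered, dtype=float)
    lab = _as_labels(labels)
    by_id = {s.nucleus_id: s for s in stats}
    n = int(lab.max(initial=0))
    missing = [nid for nid in range(1, n + 1) if nid not in by_id]
    if missing:
        raise ValueError(f"missing background stats for label(s) {missing}")
    abs_min = _resolve_abs_min(fpx, lab, params)
    structure = (
        np.ones((3, 3), dtype=bool) if params.connectivity == 8 else ndi.generate_binary_structure(2, 1)
    )
    foci: list[Focus] = []
    counts: dict[int, int] = {}
    objects = ndi.find_objects(lab)
    for nid in range(1, n + 1):
        sl = objects[nid - 1]
        counts[nid] = 0
        if sl is None:
            continue
        st = by_id[nid]
        sd = st.bg_sd if params.use_per_nucleus_sd else global_sd
        thr = st.bg_center + params.fold_k * sd
        win_f = fpx[sl]
        win_m = lab[sl] == nid
        cand = win_m & (win_f > thr) & (win_f > abs_min)
        if not cand.any():
            continue
        groups, n_groups = ndi.label(cand, structure=structure)
        y_off, x_off = sl[0].start, sl[1].start
        for g in range(1, n_groups + 1):
            member = groups == g
            area = int(member.sum())
            if area <= params.min_focus_area:
                continue
            ys, xs = np.nonzero(member)
            vals = win_f[member]
            members = (
                tuple(sorted((int(y + y_off), int(x + x_off)) for y, x in zip(ys, xs)))
                if keep_pixels
                else ()
            )
            foci.append(
                Focus(
                    nucleus_id=nid,
                    centroid=(float(xs.mean() + x_off), float(ys.mean() + y_off)),
                    area=area,
                    mean_intensity=float(vals.mean()),
                    max_intensity=float(vals.max()),
                    pixels=members,
                )
            )
            counts[nid] += 1
    return FociResult(foci=tuple(foci), counts=counts, global_sd=float(global_sd))


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    n_nuclei: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    ci_defined: bool


def count_summary(results: Sequence[FociResult], condition_labels: Sequence[str]) -> list[ConditionSummary]:
    """Per-condition mean focus count with SD and a t-based 95% CI.

    Nuclei are pooled across all fields of a condition.  A condition with a
    single nucleus gets an explicitly undefined CI (NaN bounds,
    ``ci_defined=False``) rather than a silently zero-width one.
    """
    if len(results) != len(condition_labels):
        raise ValueError("one condition label per FociResult is required")
    pooled: dict[str, list[int]] = {}
    for res, cond in zip(results, condition_labels):
        pooled.setdefault(cond, []).extend(res.counts.values())
    out = []
    for cond, counts in pooled.items():
        if not counts:
            raise ValueError(f"condition {cond!r} has no nuclei")
        arr = np.asarray(counts, dtype=float)
        mean = float(arr.mean())
        if arr.size < 2:
            out.append(ConditionSummary(cond, arr.size, mean, float("nan"), float("nan"), float("nan"), False))
            continue
        sd = float(arr.std(ddof=1))
        half = float(t_dist.ppf(0.975, arr.size - 1) * sd / np.sqrt(arr.size))
        out.append(ConditionSummary(cond, arr.size, mean, sd, mean - half, mean + half, True))
    return out
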