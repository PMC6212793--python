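"""Nucleus segmentation from the DAPI channel.

The procedure mirrors the classic ImageJ-macro recipe for counting damage
foci: median-filter the DAPI signal, threshold it (Otsu by default), and
split touching nuclei with a watershed on the smoothed distance transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import relabel_sequential, watershed

logger = logging.getLogger(__name__)

__all__ = ["ImageField", "LabelMap", "SegmentationParams", "median_smooth", "segment_nuclei"]


@dataclass(frozen=True)
class ImageField:
    """A single-channel 2D intensity image with optional physical scale."""

    pixels: np.ndarray
    pixel_size: float | None = None  # micrometres per pixel

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels must be finite")
        if px.size and px.min() < 0:
            raise ValueError("pixels must be non-negative")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _as_pixels(image) -> np.ndarray:
    return image.pixels if isinstance(image, ImageField) else np.asarray(image)


@dataclass(frozen=True)
class LabelMap:
    """Integer nucleus labels per pixel; 0 is background.

    Labels are the contiguous set 1..n_labels and each label's pixel set is
    4-connected.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be 2D")
        if lab.size and lab.min() < 0:
            raise ValueError("labels must be non-negative")
        present = np.unique(lab)
        present = present[present > 0]
        n = int(lab.max(initial=0))
        if len(present) != n:
            raise ValueError("labels must form the contiguous set 1..n_labels")
        object.__setattr__(self, "labels", lab.astype(np.int32, copy=False))

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass(frozen=True)
class SegmentationParams:
    median_radius: int = 2
    threshold_method: str = "otsu"  # or "fixed"
    fixed_threshold: float = 0.0
    min_nucleus_area: int = 200
    watershed_smoothing_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.median_radius < 0:
            raise ValueError("median_radius must be >= 0")
        if self.min_nucleus_area < 0:
            raise ValueError("min_nucleus_area must be >= 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.watershed_smoothing_sigma < 0:
            raise ValueError("watershed_smoothing_sigma must be >= 0")


def median_smooth(image, radius: int):
    """Median filter with a (2r+1)x(2r+1) square window clipped at the edges.

    Edge pixels use only the in-image part of the window (no padding), so a
    corner pixel's median is taken over a (r+1)x(r+1) neighbourhood.
    Radius 0 returns the input unchanged.
    """
    px = _as_pixels(image).astype(float)
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0 or px.size == 0:
        out = px.copy()
    else:
        # stack every window offset as a NaN-padded shifted copy; nanmedian
        # then realises the clipped-window median exactly
        h, w = px.shape
        shifts = []
        for dy in range(-radius, radius + 1):
            for dx in range(-radius, radius + 1):
                shifted = np.full((h, w), np.nan)
                ys0, ys1 = max(0, -dy), min(h, h - dy)
                xs0, xs1 = max(0, -dx), min(w, w - dx)
                shifted[ys0:ys1, xs0:xs1] = px[ys0 + dy : ys1 + dy, xs0 + dx : xs1 + dx]
                shifts.append(shifted)
        out = np.nanmedian(np.stack(shifts), axis=0)
    if isinstance(image, ImageField):
        return ImageField(out, image.pixel_size)
    return out


def segment_nuclei(dapi, params: SegmentationParams = SegmentationParams()) -> LabelMap:
    """Threshold the median-smoothed DAPI image and watershed-split touching nuclei.

    Foreground pixels are those strictly above the threshold.  Watershed
    seeds are the local maxima of the Gaussian-smoothed Euclidean distance
    transform; components smaller than ``min_nucleus_area`` are discarded
    and labels relabelled contiguously.  An Otsu threshold on a blank image
    yields an empty label map with a logged warning rather than an error.
    """
    px = _as_pixels(dapi).astype(float)
    smoothed = median_smooth(px, params.median_radius)
    if params.threshold_method == "fixed":
        thr = params.fixed_threshold
    else:
        try:
            thr = threshold_otsu(smoothed)
        except ValueError:
            logger.warning("Otsu threshold undefined (constant image); returning empty label map")
            return LabelMap(np.zeros(px.shape, dtype=np.int32))
    fg = smoothed > thr
    if not fg.any():
        return LabelMap(np.zeros(px.shape, dtype=np.int32))

    dist = ndi.distance_transform_edt(fg)
    if params.watershed_smoothing_sigma > 0:
        dist_s = ndi.gaussian_filter(dist, params.watershed_smoothing_sigma)
    else:
        dist_s = dist
    # one seed per distance peak; min_distance keeps jitter peaks from
    # oversplitting a single nucleus
    min_dist = max(3, int(round(2 * params.watershed_smoothing_sigma)))
    coords = peak_local_max(dist_s, min_distance=min_dist, labels=fg, exclude_border=False)
    markers = np.zeros(px.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers = cc_label(fg, connectivity=1)
    lab = watershed(-dist_s, markers, mask=fg, connectivity=1)

    # enforce 4-connectivity per label, drop small components, relabel 1..n
    pieces = cc_label(lab > 0, connectivity=1)
    out = np.zeros(px.shape, dtype=np.int32)
    nxt = 0
    for region in range(1, pieces.max() + 1):
        region_mask = pieces == region
        for wl in np.unique(lab[region_mask]):
            piece = region_mask & (lab == wl)
            sub = cc_label(piece, connectivity=1)
            for s in range(1, sub.max() + 1):
                m = sub == s
                if m.sum() >= params.min_nucleus_area:
                    nxt += 1
                    out[m] = nxt
    out, _, _ = relabel_sequential(out)
    return LabelMap(out.astype(np.int32))
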