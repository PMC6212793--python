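"""File formats, configuration, and the end-to-end pipeline runner.

Images travel as 16-bit grayscale TIFF (one file per channel), tabular
outputs as CSV with documented headers, parameter specs as YAML, and
machine-readable summaries as JSON.  Coordinates are 0-based with
x = column and y = row; areas are in pixels and times in hours.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from focistat.break_model import CutKinetics, GuideTarget, IndelSpectrum
from focistat.foci_detection import DetectionParams, FociResult, background_stats, count_summary, detect_foci, dog_filter
from focistat.segmentation import LabelMap, SegmentationParams, segment_nuclei
from focistat.synthetic_data import FieldSpec, GroundTruth, generate_field, sample_focus_counts

logger = logging.getLogger(__name__)

__all__ = [
    "read_image",
    "write_image",
    "read_labels",
    "write_labels",
    "to_uint16",
    "write_truth_csv",
    "write_foci_csv",
    "write_counts_csv",
    "write_tracks_csv",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "load_field_spec",
    "load_detection_params",
    "load_segmentation_params",
    "RunConfig",
    "run_pipeline",
]

FOCI_CSV_COLUMNS = ["nucleus_id", "x", "y", "area_px", "mean_int", "max_int"]
TRUTH_CSV_COLUMNS = ["nucleus_id", "x", "y", "radius", "amplitude"]


def to_uint16(pixels: np.ndarray) -> np.ndarray:
    """Round and clip a float image onto the 16-bit camera range."""
    return np.clip(np.round(pixels), 0, 65535).astype(np.uint16)


def write_image(path, pixels: np.ndarray) -> None:
    """Write a 2D image as 16-bit grayscale TIFF (floats are rounded/clipped)."""
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D grayscale image, got shape {arr.shape}")
    tifffile.imwrite(str(path), to_uint16(arr))


def read_image(path) -> np.ndarray:
    """Read a 16-bit grayscale TIFF written by :func:`write_image`."""
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2D image, got shape {arr.shape}")
    if arr.dtype.kind not in "ui":
        raise ValueError(f"{path}: expected an unsigned-integer grayscale image, got dtype {arr.dtype}")
    return arr


def write_labels(path, labels: LabelMap | np.ndarray) -> None:
    lab = labels.labels if isinstance(labels, LabelMap) else np.asarray(labels)
    if lab.max(initial=0) > 65535:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit TIFF")
    write_image(path, lab)


def read_labels(path) -> LabelMap:
    return LabelMap(read_image(path).astype(np.int32))


def write_truth_csv(path, truth: GroundTruth) -> None:
    pd.DataFrame(
        [(r.nucleus_id, r.x, r.y, r.radius, r.amplitude) for r in truth.focus_records],
        columns=TRUTH_CSV_COLUMNS,
    ).to_csv(path, index=False)


def write_foci_csv(path, result: FociResult) -> None:
    pd.DataFrame(
        [
            (f.nucleus_id, f.centroid[0], f.centroid[1], f.area, f.mean_intensity, f.max_intensity)
            for f in result.foci
        ],
        columns=FOCI_CSV_COLUMNS,
    ).to_csv(path, index=False)


def write_counts_csv(path, result: FociResult) -> None:
    pd.DataFrame(
        sorted(result.counts.items()), columns=["nucleus_id", "n_foci"]
    ).to_csv(path, index=False)


def write_tracks_csv(path, tracks) -> None:
    """One row per (track, frame): track_id,nucleus_id,frame,x,y,area_px,mean_int,max_int."""
    rows = []
    for t in tracks:
        for i, fr in enumerate(t.frame_indices):
            rows.append(
                (
                    t.track_id,
                    t.nucleus_id,
                    fr,
                    t.centroids[i][0],
                    t.centroids[i][1],
                    t.areas[i],
                    t.mean_intensities[i],
                    t.max_intensities[i],
                )
            )
    pd.DataFrame(
        rows, columns=["track_id", "nucleus_id", "frame", "x", "y", "area_px", "mean_int", "max_int"]
    ).to_csv(path, index=False)


def write_spectrum_csv(path, spectrum: IndelSpectrum) -> None:
    rows = [
        (size, int(round(freq * spectrum.n_reads)))
        for size, freq in sorted(spectrum.frequencies.items())
    ]
    pd.DataFrame(rows, columns=["indel_size", "count"]).to_csv(path, index=False)


def read_spectrum_csv(path) -> IndelSpectrum:
    df = pd.read_csv(path)
    for col in ("indel_size", "count"):
        if col not in df.columns:
            raise ValueError(f"{path}: spectrum CSV must have columns indel_size,count")
    total = int(df["count"].sum())
    if total <= 0:
        raise ValueError(f"{path}: spectrum has no reads")
    freqs = {int(r.indel_size): r.count / total for r in df.itertuples()}
    return IndelSpectrum(frequencies=freqs, n_reads=total)


# ---------------------------------------------------------------------------
# YAML parameter specs


def _load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    return data


def load_field_spec(path) -> FieldSpec:
    data = _load_yaml(path)
    if "nucleus_radius_range" in data:
        data["nucleus_radius_range"] = tuple(data["nucleus_radius_range"])
    return FieldSpec(**data)


def load_detection_params(path) -> DetectionParams:
    return DetectionParams(**_load_yaml(path))


def load_segmentation_params(path) -> SegmentationParams:
    return SegmentationParams(**_load_yaml(path))


# ---------------------------------------------------------------------------
# pipeline


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full simulate -> segment -> detect -> summarise run.

    ``conditions`` maps condition name to the number of genomic target
    sites of its guide (0 emulates the guide-free control, which still
    shows background foci).  All randomness derives from ``seed``.
    """

    seed: int = 0
    out_dir: str = "focistat_run"
    conditions: Mapping[str, int] = field(default_factory=lambda: {"tracr": 0, "HS1": 1, "HS4": 4})
    n_fields: int = 3
    fix_time: float = 8.0  # hours post-transfection at fixation
    fraction_g1: float = 0.8
    background_foci: float = 3.0
    field_spec: FieldSpec = FieldSpec(
        width=360, height=360, n_nuclei=4, nucleus_radius_range=(20.0, 26.0)
    )
    segmentation: SegmentationParams = SegmentationParams()
    detection: DetectionParams = DetectionParams(abs_min=60.0)
    kinetics: CutKinetics = CutKinetics()
    log_level: str = "INFO"


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full pipeline and write per-stage outputs plus a JSON summary.

    For every condition and field: draw per-nucleus focus counts from the
    break-number model, render the field, segment nuclei from the DAPI
    channel, call foci on the DoG-filtered marker channel, and summarise
    per-condition counts (mean, SD, 95% CI).  Re-running the same config
    reproduces every output bit-identically.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: list[FociResult] = []
    labels_for: list[str] = []
    seed_seq = np.random.SeedSequence(config.seed)
    for cond_idx, (cond, n_sites) in enumerate(config.conditions.items()):
        guide = GuideTarget(cond, n_sites)
        for f_idx in range(config.n_fields):
            stage = f"{cond}/field{f_idx}"
            sub = int(seed_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
            try:
                counts = sample_focus_counts(
                    guide,
                    config.kinetics,
                    config.fix_time,
                    config.field_spec.n_nuclei,
                    seed=sub,
                    fraction_g1=config.fraction_g1,
                    background_mean=config.background_foci,
                )
                spec = FieldSpec(
                    **{
                        **{k: getattr(config.field_spec, k) for k in FieldSpec.__dataclass_fields__},
                        "foci_per_nucleus": counts,
                    }
                )
                dapi, marker, truth = generate_field(spec, seed=sub + 1)
                prefix = out / f"{cond}_field{f_idx}"
                write_image(f"{prefix}_dapi.tif", dapi)
                write_image(f"{prefix}_marker.tif", marker)
                write_labels(f"{prefix}_truth_labels.tif", truth.label_map)
                write_truth_csv(f"{prefix}_truth.csv", truth)
                labmap = segment_nuclei(dapi, config.segmentation)
                write_labels(f"{prefix}_labels.tif", labmap)
                filtered = dog_filter(marker, config.detection)
                stats, global_sd = background_stats(filtered, labmap)
                res = detect_foci(filtered, labmap, stats, global_sd, config.detection)
                write_foci_csv(f"{prefix}_foci.csv", res)
                write_counts_csv(f"{prefix}_counts.csv", res)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage failed at {stage}: {exc}") from exc
            results.append(res)
            labels_for.append(cond)
    summaries = count_summary(results, labels_for)
    summary = {
        "seed": config.seed,
        "fix_time_h": config.fix_time,
        "conditions": {
            s.condition: {
                "n_nuclei": s.n_nuclei,
                "mean_foci": s.mean,
                "sd": s.sd,
                "ci95": [s.ci_low, s.ci_high] if s.ci_defined else None,
            }
            for s in summaries
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
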