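"""Synthetic inputs with ground truth for every stage of the pipeline.

The generators emulate the four data streams of the break-counting
experiments:

* :func:`generate_field` -- two-channel fixed-cell images: ellipsoidal
  nuclei (optionally placed touching, to exercise watershed splitting) on a
  dark background in the DAPI channel, and Gaussian damage-marker foci
  planted inside nuclei in the marker channel, with Poisson photon noise
  plus Gaussian read noise.
* :func:`simulate_break_events` -- per-cell (site, allele) cut and repair
  times under the lagged-saturation cutting kinetics and exponential repair
  lifetimes.
* :func:`simulate_focus_movie` -- a time-lapse of detections for focus
  tracking, with known per-focus lifetimes.
* :func:`simulate_tracks` -- FUCCI-style single-cell cell-cycle timelines
  with a transient G2 delay, partial G1 arrest, and per-division
  micronucleation outcomes.
* :func:`sample_indel_spectrum` -- multinomial read counts over indel-size
  classes.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from focistat.break_model import CutKinetics, GuideTarget, IndelSpectrum, RepairModel, cut_fraction
from focistat.cycle_stats import CellTrack
from focistat.foci_detection import Focus

__all__ = [
    "PlacementError",
    "Uniform",
    "Fixed",
    "Exponential",
    "FieldSpec",
    "FocusRecord",
    "GroundTruth",
    "TrackCohortSpec",
    "IndelMixSpec",
    "BreakEvent",
    "CellBreaks",
    "FocusMovie",
    "DEFAULT_INDEL_MIX",
    "generate_field",
    "sample_focus_counts",
    "simulate_break_events",
    "simulate_tracks",
    "simulate_focus_movie",
    "sample_indel_spectrum",
]


class PlacementError(RuntimeError):
    """Objects could not be placed within the field bounds."""


# ---------------------------------------------------------------------------
# small distribution helpers (hours)


@dataclass(frozen=True)
class Uniform:
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.high < self.low:
            raise ValueError("high must be >= low")

    @property
    def minimum(self) -> float:
        return self.low

    @property
    def mean(self) -> float:
        return 0.5 * (self.low + self.high)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.low, self.high, size=n)


@dataclass(frozen=True)
class Fixed:
    value: float

    @property
    def minimum(self) -> float:
        return self.value

    @property
    def mean(self) -> float:
        return self.value

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.full(n, float(self.value))


@dataclass(frozen=True)
class Exponential:
    mean_: float

    def __post_init__(self) -> None:
        if self.mean_ <= 0:
            raise ValueError("mean must be > 0")

    @property
    def minimum(self) -> float:
        return 0.0

    @property
    def mean(self) -> float:
        return self.mean_

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.exponential(self.mean_, size=n)


# ---------------------------------------------------------------------------
# image fields


@dataclass(frozen=True)
class FieldSpec:
    """Geometry and intensity parameters of one synthetic two-channel field.

    Intensities are arbitrary units on the scale of a 16-bit camera.
    ``focus_radius`` is the Gaussian sigma of a planted focus in pixels; the
    default of 2.2 px puts >= 20 px above the focus half-maximum, so default
    foci comfortably clear a 16-px area criterion.  ``overlap_fraction`` is
    the fraction of nuclei placed as touching pairs (centre distance
    1.2-1.6x the mean radius) to force watershed separation.
    """

    width: int = 512
    height: int = 512
    n_nuclei: int = 8
    nucleus_radius_range: tuple[float, float] = (26.0, 34.0)
    overlap_fraction: float = 0.0
    nucleus_intensity: float = 1000.0
    background_level: float = 100.0
    noise_sd: float = 10.0
    foci_per_nucleus: int | Sequence[int] = 0
    focus_radius: float = 2.2
    focus_amplitude: float = 500.0
    marker_nucleus_fraction: float = 0.1  # dim nucleoplasmic marker signal relative to DAPI
    edge_sigma: float = 1.5  # Gaussian blur of nucleus edges
    min_focus_separation: float | None = None  # None -> 5x focus_radius

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("width and height must be > 0")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        rmin, rmax = self.nucleus_radius_range
        if rmin <= 0 or rmax < rmin:
            raise ValueError("nucleus_radius_range must satisfy 0 < min <= max")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.focus_radius <= 0:
            raise ValueError("focus_radius must be > 0")
        if self.focus_amplitude < 0 or self.nucleus_intensity < 0 or self.background_level < 0:
            raise ValueError("intensities must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        counts = self.focus_counts()
        if any(c < 0 for c in counts):
            raise ValueError("foci_per_nucleus entries must be >= 0")

    def focus_counts(self) -> list[int]:
        """Intended focus count per nucleus, expanded to one entry per nucleus."""
        if isinstance(self.foci_per_nucleus, (int, np.integer)):
            return [int(self.foci_per_nucleus)] * self.n_nuclei
        counts = [int(c) for c in self.foci_per_nucleus]
        if len(counts) != self.n_nuclei:
            raise ValueError(
                f"foci_per_nucleus has {len(counts)} entries for {self.n_nuclei} nuclei"
            )
        return counts


class FocusRecord(NamedTuple):
    """One planted focus: parent nucleus, centre (x=column, y=row), sigma, amplitude."""

    nucleus_id: int
    x: float
    y: float
    radius: float
    amplitude: float


@dataclass(frozen=True)
class GroundTruth:
    """Planted objects of a synthetic field.

    ``label_map`` assigns each pixel to a nucleus (0 = background); masks of
    distinct nuclei are disjoint by construction (pixels claimed by two
    touching ellipses go to the nearer centre).
    """

    label_map: np.ndarray
    focus_records: tuple[FocusRecord, ...]

    @property
    def n_nuclei(self) -> int:
        return int(self.label_map.max(initial=0))

    def nucleus_mask(self, nucleus_id: int) -> np.ndarray:
        return self.label_map == nucleus_id

    def focus_count(self, nucleus_id: int) -> int:
        return sum(1 for rec in self.focus_records if rec.nucleus_id == nucleus_id)


def _place_nuclei(spec: FieldSpec, rng: np.random.Generator):
    """Choose ellipse parameters (cx, cy, a, b) for every nucleus.

    Touching pairs are placed first (centre distance 1.2-1.6x mean radius),
    then isolated nuclei at a clearance of 2.4x the maximum radius.
    """
    rmin, rmax = spec.nucleus_radius_range
    margin = rmax + 3.0
    if spec.n_nuclei > 0 and (spec.width <= 2 * margin or spec.height <= 2 * margin):
        raise PlacementError(
            "field too small for requested nuclei: increase width/height or shrink "
            "nucleus_radius_range"
        )
    clearance = 2.4 * rmax
    n_pairs = int(round(spec.overlap_fraction * spec.n_nuclei / 2.0))
    n_paired = 2 * n_pairs
    placed: list[tuple[float, float, float, float]] = []

    def sample_axes():
        a = rng.uniform(rmin, rmax)
        b = a / rng.uniform(1.0, 1.5)  # eccentricity capped at 1.5
        return a, b

    def far_from_all(cx, cy, exclude_last=0):
        others = placed[: len(placed) - exclude_last]
        return all(math.hypot(cx - ox, cy - oy) >= clearance for ox, oy, _, _ in others)

    max_attempts = 500
    for _ in range(n_pairs):
        for attempt in range(max_attempts):
            a1, b1 = sample_axes()
            a2, b2 = sample_axes()
            cx1 = rng.uniform(margin, spec.width - margin)
            cy1 = rng.uniform(margin, spec.height - margin)
            mean_r = 0.5 * ((a1 + b1) / 2 + (a2 + b2) / 2)
            d = rng.uniform(1.2, 1.6) * mean_r
            theta = rng.uniform(0, 2 * math.pi)
            cx2 = cx1 + d * math.cos(theta)
            cy2 = cy1 + d * math.sin(theta)
            in_bounds = margin <= cx2 <= spec.width - margin and margin <= cy2 <= spec.height - margin
            if in_bounds and far_from_all(cx1, cy1) and far_from_all(cx2, cy2):
                placed.append((cx1, cy1, a1, b1))
                placed.append((cx2, cy2, a2, b2))
                break
        else:
            raise PlacementError(
                "could not place touching nucleus pair within bounds; "
                "overlap_fraction/n_nuclei too high for this field size"
            )
    for _ in range(spec.n_nuclei - n_paired):
        for attempt in range(max_attempts):
            a, b = sample_axes()
            cx = rng.uniform(margin, spec.width - margin)
            cy = rng.uniform(margin, spec.height - margin)
            if far_from_all(cx, cy):
                placed.append((cx, cy, a, b))
                break
        else:
            raise PlacementError(
                "could not place nucleus within bounds; n_nuclei too high for this field size"
            )
    return placed


def _rasterise_nuclei(spec: FieldSpec, nuclei) -> np.ndarray:
    """Label map from ellipse parameters; contested pixels go to the nearer centre."""
    labels = np.zeros((spec.height, spec.width), dtype=np.int32)
    score = np.full((spec.height, spec.width), np.inf)
    for idx, (cx, cy, a, b) in enumerate(nuclei, start=1):
        x0 = max(0, int(cx - a - 2))
        x1 = min(spec.width, int(cx + a + 3))
        y0 = max(0, int(cy - b - 2))
        y1 = min(spec.height, int(cy + b + 3))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        s = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
        inside = s <= 1.0
        win_score = score[y0:y1, x0:x1]
        claim = inside & (s < win_score)
        labels[y0:y1, x0:x1][claim] = idx
        win_score[claim] = s[claim]
    return labels


def _place_foci(spec: FieldSpec, nuclei, labels, rng) -> list[FocusRecord]:
    counts = spec.focus_counts()
    # default spacing floor of 5 sigma keeps planted foci above the
    # resolution limit of the connected-pixel criteria
    min_sep = (
        spec.min_focus_separation
        if spec.min_focus_separation is not None
        else 5.0 * spec.focus_radius
    )
    records: list[FocusRecord] = []
    for idx, ((cx, cy, a, b), n_foci) in enumerate(zip(nuclei, counts), start=1):
        centres: list[tuple[float, float]] = []
        for _ in range(n_foci):
            placed_one = False
            # best-effort separation: crowded nuclei progressively relax the
            # minimum spacing rather than fail (close pairs may then be
            # detected as one merged focus, as in a real image)
            for relax in (1.0, 0.7, 0.5, 0.25, 0.0):
                for attempt in range(500):
                    # sample within the 80%-scaled ellipse so the bump stays nuclear
                    r = math.sqrt(rng.uniform(0, 1)) * 0.8
                    phi = rng.uniform(0, 2 * math.pi)
                    fx = cx + r * a * math.cos(phi)
                    fy = cy + r * b * math.sin(phi)
                    px, py = int(round(fx)), int(round(fy))
                    if not (0 <= px < spec.width and 0 <= py < spec.height):
                        continue
                    if labels[py, px] != idx:
                        continue  # pixel ceded to a touching neighbour
                    if all(
                        math.hypot(fx - ox, fy - oy) >= min_sep * relax for ox, oy in centres
                    ):
                        centres.append((fx, fy))
                        placed_one = True
                        break
                if placed_one:
                    break
            if not placed_one:
                raise PlacementError(
                    f"could not place {n_foci} foci in nucleus {idx}: "
                    "foci_per_nucleus too high for the nucleus size"
                )
        records.extend(
            FocusRecord(idx, fx, fy, spec.focus_radius, spec.focus_amplitude)
            for fx, fy in centres
        )
    return records


def _render_foci(spec: FieldSpec, records: Sequence[FocusRecord]) -> np.ndarray:
    img = np.zeros((spec.height, spec.width))
    for rec in records:
        s = rec.radius
        ext = int(math.ceil(4 * s))
        x0 = max(0, int(rec.x) - ext)
        x1 = min(spec.width, int(rec.x) + ext + 1)
        y0 = max(0, int(rec.y) - ext)
        y1 = min(spec.height, int(rec.y) + ext + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += rec.amplitude * np.exp(
            -((xx - rec.x) ** 2 + (yy - rec.y) ** 2) / (2 * s * s)
        )
    return img


def generate_field(spec: FieldSpec, seed: int):
    """Render one synthetic field.

    Returns ``(dapi, marker, truth)``: two float arrays of shape
    (height, width) and the :class:`GroundTruth`.  Identical (spec, seed)
    give bit-identical output.
    """
    rng = np.random.default_rng(seed)
    nuclei = _place_nuclei(spec, rng)
    labels = _rasterise_nuclei(spec, nuclei)
    records = _place_foci(spec, nuclei, labels, rng)

    plateau = gaussian_filter((labels > 0).astype(float), spec.edge_sigma)
    dapi_clean = spec.background_level + spec.nucleus_intensity * plateau
    marker_clean = (
        spec.background_level
        + spec.marker_nucleus_fraction * spec.nucleus_intensity * plateau
        + _render_foci(spec, records)
    )
    dapi = rng.poisson(dapi_clean).astype(float)
    marker = rng.poisson(marker_clean).astype(float)
    if spec.noise_sd > 0:
        dapi += rng.normal(0.0, spec.noise_sd, dapi.shape)
        marker += rng.normal(0.0, spec.noise_sd, marker.shape)
    np.clip(dapi, 0, None, out=dapi)
    np.clip(marker, 0, None, out=marker)
    return dapi, marker, GroundTruth(label_map=labels, focus_records=tuple(records))


# ---------------------------------------------------------------------------
# break events


class BreakEvent(NamedTuple):
    site: int
    allele: int
    cut_time: float
    repair_time: float


class CellBreaks(NamedTuple):
    phase: str
    events: tuple[BreakEvent, ...]


def simulate_break_events(
    guide: GuideTarget,
    kinetics: CutKinetics,
    repair: RepairModel | None,
    cohort_size: int,
    phase_mix: Mapping[str, float],
    duration: float,
    step: float,
    seed: int,
) -> list[CellBreaks]:
    """Per-cell cut/repair timelines on a discrete time grid.

    Each (site, allele) pair is cut at most once; the cut time is the first
    grid time ``i*step`` at which the cumulative cut fraction exceeds the
    allele's uniform draw, so cut times respect the kinetics lag.  Repair
    times are cut time + an exponential lifetime (Cas9 retention);
    ``repair=None`` means breaks persist forever.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if step <= 0:
        raise ValueError("step must be > 0")
    if cohort_size < 0:
        raise ValueError("cohort_size must be >= 0")
    phases = list(phase_mix)
    probs = np.array([phase_mix[p] for p in phases], dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("phase_mix probabilities must be non-negative and sum to 1")
    alleles_per_phase = {"G1": guide.alleles_g1, "G2": guide.alleles_g2}
    for p in phases:
        if p not in alleles_per_phase:
            raise ValueError(f"unknown phase {p!r} (expected G1/G2)")

    rng = np.random.default_rng(seed)
    n_steps = int(math.ceil(duration / step - 1e-12))
    grid = step * np.arange(1, n_steps + 1)
    cum = np.asarray(cut_fraction(grid, kinetics))

    cells: list[CellBreaks] = []
    phase_draws = rng.choice(len(phases), size=cohort_size, p=probs)
    for ci in range(cohort_size):
        phase = phases[phase_draws[ci]]
        n_alleles = alleles_per_phase[phase]
        events: list[BreakEvent] = []
        n_pairs = guide.n_sites * n_alleles
        if n_pairs:
            u = rng.random(n_pairs)
            # first grid index where cum >= u; == n_steps means never cut
            idx = np.searchsorted(cum, u, side="left")
            lifetimes = (
                repair.sample_lifetimes(n_pairs, "cas9", rng)
                if repair is not None
                else np.full(n_pairs, np.inf)
            )
            k = 0
            for site in range(guide.n_sites):
                for allele in range(n_alleles):
                    if idx[k] < n_steps:
                        t_cut = float(grid[idx[k]])
                        events.append(BreakEvent(site, allele, t_cut, t_cut + float(lifetimes[k])))
                    k += 1
        cells.append(CellBreaks(phase, tuple(events)))
    return cells


# ---------------------------------------------------------------------------
# focus time-lapse


class FocusMovie(NamedTuple):
    """Per-frame detections plus the planted per-focus truth."""

    frames: list[list[Focus]]
    lifetimes: np.ndarray
    births: np.ndarray
    frame_interval: float


def simulate_focus_movie(
    n_foci: int,
    repair: RepairModel,
    kind: str,
    seed: int,
    frame_interval: float = 0.5,
    duration: float = 24.0,
    field_shape: tuple[int, int] = (768, 768),
    step_sd: float = 0.5,
) -> FocusMovie:
    """A time-lapse of well-separated, slowly drifting foci.

    Focus ``i`` is born at a uniform offset within the first frame interval
    and stays visible for an exponential lifetime from the ``kind``
    ('cas9' or 'ir') repair model; it is detected in every frame whose
    timestamp falls within [birth, birth + lifetime).  Positions follow an
    isotropic Gaussian random walk of per-frame sigma ``step_sd`` px.
    Spacing (>= 24 px) keeps nearest-neighbour linking unambiguous.
    """
    if n_foci < 0:
        raise ValueError("n_foci must be >= 0")
    if frame_interval <= 0 or duration <= 0:
        raise ValueError("frame_interval and duration must be > 0")
    rng = np.random.default_rng(seed)
    h, w = field_shape
    spacing = 24
    nx, ny = max(1, w // spacing), max(1, h // spacing)
    if n_foci > nx * ny:
        raise PlacementError(f"n_foci={n_foci} exceeds grid capacity {nx * ny} for field {field_shape}")
    cells = rng.choice(nx * ny, size=n_foci, replace=False)
    x0 = (cells % nx + 0.5) * spacing + rng.uniform(-4, 4, n_foci)
    y0 = (cells // nx + 0.5) * spacing + rng.uniform(-4, 4, n_foci)
    lifetimes = repair.sample_lifetimes(n_foci, kind, rng)
    births = rng.uniform(0.0, frame_interval, n_foci)
    n_frames = int(round(duration / frame_interval))
    frames: list[list[Focus]] = []
    x, y = x0.copy(), y0.copy()
    for fi in range(n_frames):
        t = fi * frame_interval
        if fi > 0 and n_foci:
            x = x + rng.normal(0.0, step_sd, n_foci)
            y = y + rng.normal(0.0, step_sd, n_foci)
        dets = [
            Focus(
                nucleus_id=i,
                centroid=(float(x[i]), float(y[i])),
                area=20,
                mean_intensity=400.0,
                max_intensity=600.0,
            )
            for i in range(n_foci)
            if births[i] <= t < births[i] + lifetimes[i]
        ]
        frames.append(dets)
    return FocusMovie(frames, lifetimes, births, frame_interval)


# ---------------------------------------------------------------------------
# cell-cycle tracks


@dataclass(frozen=True)
class TrackCohortSpec:
    """Parameters of a simulated FUCCI cohort.

    Times are hours post-transfection.  Damaged G2 cells enter mitosis at
    baseline + a drawn G2 delay (default Uniform(4, 6) h, the observed
    magnitude of the single-break checkpoint delay); when the checkpoint is
    abrogated pharmacologically the delay shrinks by
    ``abrogated_delay_factor``.  A fraction of damaged G1 cells (default
    0.2, matching the observed ~20% drop in cumulative S-phase entry)
    arrest and never enter S within the horizon.  Dividing cells pick up a
    micronucleus with probability 0.02 (intact checkpoint) or 0.10
    (abrogated) -- absolute baselines are model assumptions embodying the
    observed five-fold increase.
    """

    n_cells: int = 150
    phase_at_damage: Mapping[str, float] = field(
        default_factory=lambda: {"G1_early": 0.4, "G1_late": 0.4, "G2": 0.2}
    )
    baseline_entry_time: Uniform | Fixed | Exponential = Uniform(10.0, 14.0)
    g2_delay: Uniform | Fixed | Exponential = Uniform(4.0, 6.0)
    g1_arrest_fraction: float = 0.2
    horizon: float = 24.0
    checkpoint_intact: bool = True
    abrogated_delay_factor: float = 0.1
    micronucleation_prob_intact: float = 0.02
    micronucleation_prob_abrogated: float = 0.10
    damage: bool = True

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        probs = list(self.phase_at_damage.values())
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("phase_at_damage probabilities must be non-negative and sum to 1")
        for name in ("g1_arrest_fraction", "micronucleation_prob_intact", "micronucleation_prob_abrogated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.g2_delay.minimum < 0:
            raise ValueError("g2_delay support must be >= 0")
        if not 0.0 <= self.abrogated_delay_factor <= 1.0:
            raise ValueError("abrogated_delay_factor must lie in [0, 1]")


def simulate_tracks(spec: TrackCohortSpec, seed: int) -> list[CellTrack]:
    """Simulate one cohort of single-cell cell-cycle timelines.

    G2 cells head for mitosis, G1 cells for S phase; ``damage=False``
    cohorts follow the baseline entry distribution unchanged and are
    labelled ``phase_at_damage='undamaged'`` while retaining their true
    phase for curve building.
    """
    rng = np.random.default_rng(seed)
    phases = list(spec.phase_at_damage)
    probs = np.array([spec.phase_at_damage[p] for p in phases])
    phase_idx = rng.choice(len(phases), size=spec.n_cells, p=probs)
    baselines = spec.baseline_entry_time.sample(rng, spec.n_cells)
    delays = spec.g2_delay.sample(rng, spec.n_cells)
    arrest_draws = rng.random(spec.n_cells)
    mn_draws = rng.random(spec.n_cells)

    mn_prob = (
        spec.micronucleation_prob_intact
        if (spec.checkpoint_intact or not spec.damage)
        else spec.micronucleation_prob_abrogated
    )
    tracks: list[CellTrack] = []
    for i in range(spec.n_cells):
        phase = phases[phase_idx[i]]
        entry: float | None = float(baselines[i])
        if spec.damage:
            if phase == "G2":
                d = delays[i] if spec.checkpoint_intact else delays[i] * spec.abrogated_delay_factor
                entry = float(baselines[i] + d)
            elif arrest_draws[i] < spec.g1_arrest_fraction:
                entry = None  # arrested: no S entry within the horizon
        censored = entry is None or entry > spec.horizon
        divided = phase == "G2" and not censored
        micronucleated = bool(divided and mn_draws[i] < mn_prob)
        tracks.append(
            CellTrack(
                cell_id=i,
                phase=phase,
                phase_at_damage=phase if spec.damage else "undamaged",
                entry_time=None if censored else entry,
                censored=censored,
                divided=divided,
                micronucleated=micronucleated,
            )
        )
    return tracks


def sample_focus_counts(
    guide: GuideTarget,
    kinetics: CutKinetics,
    t: float,
    n_nuclei: int,
    seed: int,
    fraction_g1: float = 1.0,
    background_mean: float = 3.0,
) -> list[int]:
    """Draw per-nucleus focus counts under the break-number model.

    Each nucleus is G1 (2 alleles per site) with probability
    ``fraction_g1``, else G2 (4 alleles); induced breaks are binomial over
    site-allele pairs at the cut fraction reached by time ``t``, and
    spontaneous background foci are Poisson (default mean 3, the count
    seen in guide-free controls).
    """
    if not 0 <= fraction_g1 <= 1:
        raise ValueError("fraction_g1 must lie in [0, 1]")
    if background_mean < 0:
        raise ValueError("background_mean must be >= 0")
    rng = np.random.default_rng(seed)
    p_cut = cut_fraction(t, kinetics)
    g1 = rng.random(n_nuclei) < fraction_g1
    alleles = np.where(g1, guide.alleles_g1, guide.alleles_g2)
    induced = rng.binomial(guide.n_sites * alleles, p_cut)
    background = rng.poisson(background_mean, n_nuclei)
    return [int(c) for c in induced + background]


# ---------------------------------------------------------------------------
# indel spectra

#: Default repair-product class mixture: NHEJ-type small indels totalling
#: 0.30 and resection-dependent deletions totalling 0.70.
DEFAULT_INDEL_MIX: dict[int, float] = {
    +1: 0.10,
    +2: 0.03,
    -1: 0.07,
    -2: 0.05,
    -3: 0.03,
    -4: 0.02,
    -5: 0.40,
    -8: 0.30,
}


@dataclass(frozen=True)
class IndelMixSpec:
    """Class probabilities over signed indel sizes and a read depth."""

    class_probs: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_INDEL_MIX))
    n_reads: int = 10_000

    def __post_init__(self) -> None:
        if not self.class_probs:
            raise ValueError("class_probs must contain at least one indel class")
        probs = list(self.class_probs.values())
        if any(p < 0 for p in probs):
            raise ValueError("class probabilities must be non-negative")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be > 0")


def sample_indel_spectrum(mix: IndelMixSpec, seed: int) -> IndelSpectrum:
    """Multinomial draw of ``n_reads`` reads over the indel classes."""
    rng = np.random.default_rng(seed)
    sizes = list(mix.class_probs)
    probs = np.array([mix.class_probs[s] for s in sizes], dtype=float)
    probs = probs / probs.sum()
    counts = rng.multinomial(mix.n_reads, probs)
    freqs = {size: float(c) / mix.n_reads for size, c in zip(sizes, counts)}
    return IndelSpectrum(frequencies=freqs, n_reads=mix.n_reads)
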