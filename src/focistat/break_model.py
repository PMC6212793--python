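"""Quantitative model of Cas9 break numbers.

Three pieces:

* **Cutting kinetics** -- after guide-RNA delivery there is an onset lag of
  roughly two hours before the first breaks appear, after which the
  per-allele probability of having been cut rises and saturates.  We use a
  lagged saturating exponential,

  .. math:: F(t) = p_{max}\\,(1 - e^{-(t - t_{lag})/\\tau}), \\qquad t > t_{lag}

  with defaults calibrated so that half of all target alleles are cut at
  8 h post-transfection (``t_lag = 2`` h, ``p_max = 1``,
  ``tau = 6/ln 2`` h): F(8) = 1 - exp(-ln 2) = 1/2.

* **Expected foci per nucleus** -- a guide that matches ``n_sites`` genomic
  sites can break 2 alleles per site in G1 and 4 in G2.  For a cell
  population with a given G1/G2 mix the expected focus count at time t is
  background + n_sites * (f_G1 * 2 + f_G2 * 4) * F(t).

* **Indel classification** -- repair products partition into small
  NHEJ-type indels (+1, +2, -1, -2, -3, -4) and resection-dependent larger
  deletions (<= -5); the classifier reports both fractions plus a
  remainder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "GuideTarget",
    "CutKinetics",
    "RepairModel",
    "PhaseMix",
    "IndelSpectrum",
    "IndelClassification",
    "NHEJ_CLASSES",
    "cut_fraction",
    "expected_foci",
    "mc_concurrent_foci",
    "classify_indels",
]

#: Indel sizes attributed to classical non-homologous end joining.
NHEJ_CLASSES = frozenset({+1, +2, -1, -2, -3, -4})

#: Deletions at least this large are attributed to resection-dependent repair.
RESECTION_MAX_SIZE = -5


@dataclass(frozen=True)
class GuideTarget:
    """A guide RNA and the number of genomic sites it targets.

    ``alleles_g1``/``alleles_g2`` are chromatid copies per site: 2 before
    replication, 4 after.
    """

    name: str
    n_sites: int
    alleles_g1: int = 2
    alleles_g2: int = 4

    def __post_init__(self) -> None:
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        if self.alleles_g1 <= 0:
            raise ValueError("alleles_g1 must be positive")
        if self.alleles_g2 != 2 * self.alleles_g1:
            raise ValueError("alleles_g2 must equal 2 * alleles_g1 (pre- vs post-replication)")


@dataclass(frozen=True)
class CutKinetics:
    """Parameters of the lagged-saturation cut-fraction model.

    Defaults put break onset at 2 h and half-maximal cutting at 8 h
    post-transfection.
    """

    t_lag: float = 2.0
    tau: float = 6.0 / math.log(2.0)
    p_max: float = 1.0

    def __post_init__(self) -> None:
        if self.t_lag < 0:
            raise ValueError("t_lag must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if not 0.0 <= self.p_max <= 1.0:
            raise ValueError("p_max must lie in [0, 1]")


@dataclass(frozen=True)
class RepairModel:
    """Focus-lifetime (repair-time) distributions for Cas9 and IR breaks.

    Lifetimes are exponential by default.  The Cas9 mean is the IR mean
    plus 2 h: Cas9-induced breaks persist about two hours longer than
    radiation-induced ones, plausibly because Cas9 stays bound to the cut
    ends.  The IR baseline of 1 h is a model assumption.
    """

    mean_retention_cas9: float = 3.0
    mean_retention_ir: float = 1.0
    family: str = "exponential"

    def __post_init__(self) -> None:
        if self.mean_retention_cas9 <= 0 or self.mean_retention_ir <= 0:
            raise ValueError("mean retentions must be > 0")
        if self.family != "exponential":
            raise ValueError(f"unsupported lifetime family: {self.family!r}")

    def mean_retention(self, kind: str) -> float:
        if kind == "cas9":
            return self.mean_retention_cas9
        if kind == "ir":
            return self.mean_retention_ir
        raise ValueError(f"unknown break kind: {kind!r} (expected 'cas9' or 'ir')")

    def sample_lifetimes(self, n: int, kind: str, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` focus lifetimes in hours for break type ``kind``."""
        return rng.exponential(self.mean_retention(kind), size=n)


@dataclass(frozen=True)
class PhaseMix:
    """Cell-cycle composition of the population at the moment of damage.

    Default 80% G1 / 20% G2 is a stated model assumption, not a measured
    value.
    """

    fraction_g1: float = 0.8
    fraction_g2: float = 0.2

    def __post_init__(self) -> None:
        if self.fraction_g1 < 0 or self.fraction_g2 < 0:
            raise ValueError("phase fractions must be non-negative")
        if abs(self.fraction_g1 + self.fraction_g2 - 1.0) > 1e-9:
            raise ValueError("phase fractions must sum to 1")


@dataclass(frozen=True)
class IndelSpectrum:
    """Relative frequency of each signed indel size in a pool of reads."""

    frequencies: Mapping[int, float] = field(default_factory=dict)
    n_reads: int = 0

    def __post_init__(self) -> None:
        if self.frequencies:
            total = float(sum(self.frequencies.values()))
            if any(f < 0 for f in self.frequencies.values()):
                raise ValueError("frequencies must be non-negative")
            if total > 0 and abs(total - 1.0) > 1e-9:
                raise ValueError("frequencies must sum to 1")


@dataclass(frozen=True)
class IndelClassification:
    """Partition of an indel spectrum into repair-pathway classes.

    ``nhej_fraction`` + ``resection_fraction`` + ``other_fraction`` == 1 over
    all reads.  ``unedited_fraction`` (size 0, part of ``other_fraction``) is
    reported separately; ``nhej_of_repair``/``resection_of_repair`` are
    renormalised over repair products only (unedited and unclassified reads
    excluded), which is the denominator used when quoting "fraction of
    repair products".
    """

    nhej_fraction: float
    resection_fraction: float
    other_fraction: float
    unedited_fraction: float

    @property
    def nhej_of_repair(self) -> float:
        denom = self.nhej_fraction + self.resection_fraction
        if denom == 0:
            return float("nan")
        return self.nhej_fraction / denom

    @property
    def resection_of_repair(self) -> float:
        denom = self.nhej_fraction + self.resection_fraction
        if denom == 0:
            return float("nan")
        return self.resection_fraction / denom


def cut_fraction(t, kinetics: CutKinetics):
    """Per-allele probability of having been cut by time ``t`` (hours).

    Zero up to the onset lag, then saturates towards ``p_max``.  Accepts a
    scalar or an array of times.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    out = np.where(
        t_arr <= kinetics.t_lag,
        0.0,
        kinetics.p_max * -np.expm1(-(t_arr - kinetics.t_lag) / kinetics.tau),
    )
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def expected_foci(
    guide: GuideTarget,
    mix: PhaseMix,
    t: float,
    kinetics: CutKinetics,
    background: float = 0.0,
) -> float:
    """Closed-form expected focus count per nucleus at time ``t``.

    ``background`` is the mean count of spontaneous (non-Cas9) foci, assumed
    additive with induced breaks.
    """
    if background < 0:
        raise ValueError("background must be >= 0")
    alleles = mix.fraction_g1 * guide.alleles_g1 + mix.fraction_g2 * guide.alleles_g2
    return background + guide.n_sites * alleles * cut_fraction(t, kinetics)


def mc_concurrent_foci(
    guide: GuideTarget,
    mix: PhaseMix,
    kinetics: CutKinetics,
    repair: RepairModel | None,
    t: float,
    n_cells: int,
    seed: int,
    step: float = 0.25,
) -> float:
    """Monte-Carlo mean of foci simultaneously visible at time ``t``.

    A break contributes at ``t`` if it has been cut (cut_time <= t) but not
    yet repaired (repair_time > t).  ``repair=None`` disables repair
    (infinite retention), in which case the result converges to
    :func:`expected_foci` with zero background.
    """
    from focistat.synthetic_data import simulate_break_events

    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    phase_probs = {"G1": mix.fraction_g1, "G2": mix.fraction_g2}
    cells = simulate_break_events(
        guide=guide,
        kinetics=kinetics,
        repair=repair,
        cohort_size=n_cells,
        phase_mix=phase_probs,
        duration=max(t, step),
        step=step,
        seed=seed,
    )
    visible = [
        sum(1 for ev in events if ev.cut_time <= t < ev.repair_time)
        for _phase, events in cells
    ]
    return float(np.mean(visible))


def classify_indels(spectrum: IndelSpectrum) -> IndelClassification:
    """Partition an indel spectrum into NHEJ, resection, and other fractions.

    NHEJ: sizes in {+1, +2, -1, -2, -3, -4}.  Resection: deletions of 5 bp
    or more.  Everything else (unedited reads at size 0, insertions > +2)
    lands in ``other_fraction``.
    """
    if not spectrum.frequencies:
        raise ValueError("spectrum is empty: no indel classes to classify")
    total = float(sum(spectrum.frequencies.values()))
    if total <= 0:
        raise ValueError("spectrum has zero total frequency")
    nhej = sum(f for size, f in spectrum.frequencies.items() if size in NHEJ_CLASSES)
    resection = sum(
        f for size, f in spectrum.frequencies.items() if size <= RESECTION_MAX_SIZE
    )
    unedited = spectrum.frequencies.get(0, 0.0)
    nhej /= total
    resection /= total
    unedited /= total
    other = 1.0 - nhej - resection
    # clamp tiny negative residue from float summation
    other = max(other, 0.0)
    return IndelClassification(
        nhej_fraction=nhej,
        resection_fraction=resection,
        other_fraction=other,
        unedited_fraction=unedited,
    )
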