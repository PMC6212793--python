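"""Population-level checkpoint readouts from single-cell timelines.

Cumulative entry curves (fraction of a cohort that has entered S phase or
mitosis by each time point), the quantile-crossing delay between a damaged
and a control curve, the relative reduction in entry at a fixed time, the
micronucleation fold change with an exact test, and the two group-level
hypothesis tests used for figure statistics (Welch's t and one-way ANOVA
with Bonferroni-corrected pairwise comparisons).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "CellTrack",
    "EntryCurve",
    "MicronucleationResult",
    "ComparisonResult",
    "cumulative_entry",
    "delay_at_quantile",
    "reduction_at",
    "micronucleation_fold",
    "group_compare",
]

_PHASES = {"G1_early", "G1_late", "G2"}


@dataclass(frozen=True)
class CellTrack:
    """One cell's timeline around the damage event.

    ``phase`` is the true cell-cycle phase; ``phase_at_damage`` equals it
    for damaged cells and is ``'undamaged'`` for control cells.
    ``entry_time`` (hours post-transfection) is the time of the phase
    transition the cell is headed for (S entry from G1, M entry from G2);
    ``None`` with ``censored=True`` if it never happens within the
    observation horizon.
    """

    cell_id: int
    phase: str
    phase_at_damage: str
    entry_time: float | None
    censored: bool = False
    divided: bool = False
    micronucleated: bool = False

    def __post_init__(self) -> None:
        if self.phase not in _PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.phase_at_damage not in _PHASES | {"undamaged"}:
            raise ValueError(f"unknown phase_at_damage {self.phase_at_damage!r}")
        if self.entry_time is not None and self.entry_time < 0:
            raise ValueError("entry_time must be >= 0")
        if self.entry_time is None and not self.censored:
            raise ValueError("a cell without an entry time must be censored")
        if self.micronucleated and not self.divided:
            raise ValueError("micronucleation requires division")


@dataclass(frozen=True)
class EntryCurve:
    """Cumulative fraction of a cohort entered by each (relative) time point."""

    times: np.ndarray  # hours relative to t0
    fraction: np.ndarray
    n_cells: int

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fraction, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("times and fraction must be matching 1D arrays")
        if np.any(np.diff(t) < 0):
            raise ValueError("times must be sorted")
        if np.any(np.diff(f) < -1e-12):
            raise ValueError("cumulative fraction must be non-decreasing")
        if f.size and (f.min() < 0 or f.max() > 1 + 1e-12):
            raise ValueError("fraction must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fraction", f)

    def at(self, t: float) -> float:
        """Fraction entered at relative time ``t`` (grid point required)."""
        idx = np.nonzero(np.isclose(self.times, t))[0]
        if idx.size == 0:
            raise ValueError(f"t={t} is not on the curve's time grid")
        return float(self.fraction[idx[0]])


def cumulative_entry(
    tracks: Sequence[CellTrack],
    event: str,
    grid: Sequence[float],
    t0: float = 8.0,
) -> EntryCurve:
    """Cumulative fraction of cells having entered by each grid time.

    ``event`` selects the relevant sub-cohort: ``'S_entry'`` uses G1 cells,
    ``'M_entry'`` uses G2 cells (control cells by their true phase).
    ``grid`` and ``t0`` are hours post-transfection; curve times are
    reported relative to ``t0``.  Censored cells stay in the denominator
    and never count as entered.
    """
    if event not in ("S_entry", "M_entry"):
        raise ValueError("event must be 'S_entry' or 'M_entry'")
    wanted = {"G2"} if event == "M_entry" else {"G1_early", "G1_late"}
    cohort = [tr for tr in tracks if tr.phase in wanted]
    if not cohort:
        raise ValueError(f"no cells in the cohort are headed for {event}")
    grid_arr = np.asarray(list(grid), dtype=float)
    if np.any(np.diff(grid_arr) < 0):
        raise ValueError("grid must be sorted")
    entries = np.array(
        [tr.entry_time if tr.entry_time is not None else np.inf for tr in cohort]
    )
    frac = np.array([(entries <= t).mean() for t in grid_arr])
    return EntryCurve(times=grid_arr - t0, fraction=frac, n_cells=len(cohort))


def _first_crossing(curve: EntryCurve, q: float) -> float:
    """First time the curve reaches q, linearly interpolated; NaN if never."""
    f = curve.fraction
    t = curve.times
    idx = np.nonzero(f >= q)[0]
    if idx.size == 0:
        return math.nan
    i = int(idx[0])
    if i == 0 or f[i] == f[i - 1]:
        return float(t[i])
    return float(t[i - 1] + (q - f[i - 1]) / (f[i] - f[i - 1]) * (t[i] - t[i - 1]))


def delay_at_quantile(treated: EntryCurve, control: EntryCurve, q: float = 0.5) -> float:
    """Horizontal shift between the two curves at quantile ``q``.

    Returns (first time treated reaches q) - (first time control reaches
    q); NaN (explicitly not-estimable, distinct from 0) if either curve
    never reaches ``q``.
    """
    if not 0 < q <= 1:
        raise ValueError("q must lie in (0, 1]")
    tt = _first_crossing(treated, q)
    tc = _first_crossing(control, q)
    if math.isnan(tt) or math.isnan(tc):
        return math.nan
    return tt - tc


def reduction_at(treated: EntryCurve, control: EntryCurve, t: float) -> float:
    """Percent reduction of treated relative to control entry at time ``t``."""
    c = control.at(t)
    if c == 0:
        raise ValueError("control fraction is 0 at t: relative reduction undefined")
    return 100.0 * (c - treated.at(t)) / c


class MicronucleationResult(NamedTuple):
    fold: float  # NaN when not estimable
    p_value: float
    estimable: bool
    fold_lower_bound: float  # one-sided 97.5% lower bound on the fold


def micronucleation_fold(
    treated: tuple[int, int],
    control: tuple[int, int],
) -> MicronucleationResult:
    """Fold change in micronucleated-cell frequency per division.

    ``treated``/``control`` are (micronucleated, divided) counts.  The
    p-value is Fisher's exact test on the 2x2 table.  With zero control
    micronuclei the fold is reported as not estimable together with a
    conservative lower bound (control numerator replaced by its one-sided
    97.5% upper limit), never as infinity.
    """
    m_t, d_t = treated
    m_c, d_c = control
    if d_t <= 0 or d_c <= 0:
        raise ValueError("divided counts must be > 0")
    if m_t > d_t or m_c > d_c:
        raise ValueError("micronucleated count cannot exceed divided count")
    table = [[m_t, d_t - m_t], [m_c, d_c - m_c]]
    p = float(sps.fisher_exact(table)[1])
    rate_t = m_t / d_t
    if m_c == 0:
        # Clopper-Pearson upper limit for a zero numerator: 1 - alpha^(1/n)
        upper_c = 1.0 - 0.025 ** (1.0 / d_c)
        bound = rate_t / upper_c if upper_c > 0 else math.inf
        return MicronucleationResult(math.nan, p, False, bound)
    fold = rate_t / (m_c / d_c)
    return MicronucleationResult(fold, p, True, fold)


class ComparisonResult(NamedTuple):
    group_a: int
    group_b: int
    statistic: float
    p_raw: float
    p_adjusted: float
    degenerate: bool  # both groups constant with identical means


def _welch_pair(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, True
        return math.inf if a.mean() > b.mean() else -math.inf, 0.0, True
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), False


def group_compare(
    groups: Sequence[Sequence[float]],
    method: str = "welch_t",
) -> list[ComparisonResult]:
    """Pairwise group tests as used in figure legends.

    ``'welch_t'``: Welch's unequal-variance t-test per pair (no
    adjustment, p_adjusted == p_raw).  ``'anova_bonferroni'``: all-pairs
    Welch comparisons with Bonferroni adjustment
    (p_adj = min(1, p_raw x n_comparisons)); the one-way ANOVA F-test is
    reported by :func:`anova_f`.  Two groups that are both constant at the
    same value get p = 1 with a degeneracy flag.
    """
    if method not in ("welch_t", "anova_bonferroni"):
        raise ValueError("method must be 'welch_t' or 'anova_bonferroni'")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs n >= 2")
    pairs = list(combinations(range(len(arrs)), 2))
    n_comp = len(pairs) if method == "anova_bonferroni" else 1
    out = []
    for i, j in pairs:
        t, p, degen = _welch_pair(arrs[i], arrs[j])
        out.append(ComparisonResult(i, j, t, p, min(1.0, p * n_comp), degen))
    return out


def anova_f(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value across all groups."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    f, p = sps.f_oneway(*arrs)
    return float(f), float(p)
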