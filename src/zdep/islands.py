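"""Broad-island calling from windowed ChIP coverage and differential islands.

A deliberately simplified caller in the SICER family: per-window Poisson
eligibility against a library-scaled control expectation, gap-bridged
aggregation of eligible windows into islands, an island-level exact
conditional binomial test of the ChIP total against the control total
(which, unlike a plug-in Poisson test, accounts for sampling noise in the
control and keeps the false-discovery rate controlled under the null), and
Benjamini-Hochberg filtering at an island FDR.

Differential islands are tested on the union of islands from the two
conditions with an exact conditional binomial rate test on library-scaled
counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ._stats import bh_qvalues
from .io import CoverageTrack

__all__ = [
    "IslandParams",
    "Island",
    "DifferentialIsland",
    "call_islands",
    "call_differential",
    "merge_island_union",
]

SCORE_CAP = 300.0


@dataclass(frozen=True)
class IslandParams:
    window: int = 200
    gap: int = 200
    window_pvalue_cutoff: float = 0.2
    island_fdr: float = 0.01
    effective_genome_fraction: float = 0.8

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.gap < 0 or self.gap % self.window != 0:
            raise ValueError("gap must be a non-negative multiple of window")
        for name in ("window_pvalue_cutoff", "island_fdr"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if not (0 < self.effective_genome_fraction <= 1):
            raise ValueError("effective_genome_fraction must be in (0, 1]")


@dataclass(frozen=True)
class Island:
    chrom: str
    start: int
    end: int
    chip_count: float
    control_count: float
    score: float
    p_value: float
    q_value: float


@dataclass(frozen=True)
class DifferentialIsland:
    chrom: str
    start: int
    end: int
    count_a: float
    count_b: float
    direction: str  # increase/decrease of b relative to a
    p_value: float
    q_value: float


def _check_grids(a: CoverageTrack, b: CoverageTrack) -> None:
    if not a.same_grid(b):
        raise ValueError("coverage tracks are not on the same window grid")


def call_islands(chip: CoverageTrack, control: CoverageTrack,
                 params: IslandParams = IslandParams()) -> list[Island]:
    """Call enriched islands of ``chip`` over ``control``.

    Window eligibility: Poisson upper-tail p of the chip count against
    lambda = library-scaled control count, floored at the genome-average
    chip rate times ``effective_genome_fraction``; eligible iff
    p < ``window_pvalue_cutoff``.  Eligible windows separated by at most
    ``gap`` bp of ineligible windows merge into one island.  The island
    p-value is the upper tail of Binomial(chip_total + control_total, p0)
    at the chip total (bridged windows included), with p0 the chip share
    of the summed library sizes — the exact conditional rate test of chip
    vs control; BH across all islands keeps q < ``island_fdr``.
    """
    _check_grids(chip, control)
    chip_lib = chip.library_size
    if chip_lib <= 0:
        raise ValueError("chip library has zero depth")
    ctrl_lib = control.library_size
    scale = chip_lib / ctrl_lib if ctrl_lib > 0 else 0.0
    p0 = chip_lib / (chip_lib + ctrl_lib) if ctrl_lib > 0 else 1.0
    genome_avg = chip_lib / chip.n_windows
    lam_floor = genome_avg * params.effective_genome_fraction
    gap_windows = params.gap // params.window
    W = params.window

    candidates: list[tuple[str, int, int, float, float, float]] = []
    for chrom in sorted(chip.counts):
        c = chip.counts[chrom]
        lam = np.maximum(control.counts[chrom] * scale, lam_floor)
        pvals = stats.poisson.sf(np.round(c) - 1, lam)
        eligible = np.flatnonzero(pvals < params.window_pvalue_cutoff)
        if eligible.size == 0:
            continue
        # merge eligible windows bridged by <= gap_windows ineligible ones
        run_start = eligible[0]
        prev = eligible[0]
        for idx in np.append(eligible[1:], -1):
            if idx != -1 and idx - prev - 1 <= gap_windows:
                prev = idx
                continue
            chip_total = float(c[run_start:prev + 1].sum())
            ctrl_total = float(control.counts[chrom][run_start:prev + 1].sum())
            n_total = int(round(chip_total + ctrl_total))
            p = float(stats.binom.sf(round(chip_total) - 1, n_total, p0))
            candidates.append(
                (chrom, int(run_start) * W, int(prev + 1) * W, chip_total, ctrl_total, p)
            )
            if idx != -1:
                run_start = idx
                prev = idx

    if not candidates:
        return []
    # islands are data-selected seeds, so correct against the genome-wide
    # candidate space (every window), akin to SICER's genome E-value
    qvals = bh_qvalues([c[5] for c in candidates], n_tests=chip.n_windows)
    islands = []
    for (chrom, start, end, chip_total, ctrl_total, p), q in zip(candidates, qvals):
        if q < params.island_fdr:
            score = SCORE_CAP if p <= 0 else min(-np.log10(p), SCORE_CAP)
            islands.append(Island(chrom, start, end, chip_total, ctrl_total,
                                  float(score), p, float(q)))
    islands.sort(key=lambda i: (i.chrom, i.start))
    return islands


def merge_island_union(*island_lists: Sequence[Island]) -> list[tuple[str, int, int]]:
    """Merge islands from several calls into a sorted union of intervals."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for lst in island_lists:
        for isl in lst:
            by_chrom.setdefault(isl.chrom, []).append((isl.start, isl.end))
    union: list[tuple[str, int, int]] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                union.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        union.append((chrom, cur_s, cur_e))
    return union


def call_differential(a: CoverageTrack, b: CoverageTrack,
                      islands_union: Sequence[tuple[str, int, int]],
                      params: IslandParams = IslandParams()) -> list[DifferentialIsland]:
    """Two-sided rate test of b vs a over each union island.

    Conditional on the total raw count n in an island, the count from b is
    Binomial(n, p0) with p0 = lib_b / (lib_a + lib_b) under equal rates; the
    reported p-value is the exact two-sided binomial test.  BH across
    islands keeps q < ``island_fdr``; direction is increase when the
    library-scaled b count exceeds the a count.
    """
    _check_grids(a, b)
    if not islands_union:
        return []
    lib_a, lib_b = a.library_size, b.library_size
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("both libraries must have positive depth")
    p0 = lib_b / (lib_a + lib_b)
    W = a.window_size

    rows = []
    for chrom, start, end, in islands_union:
        w0, w1 = start // W, end // W
        ca = float(a.counts[chrom][w0:w1].sum())
        cb = float(b.counts[chrom][w0:w1].sum())
        n = int(round(ca + cb))
        if n == 0:
            p = 1.0
        else:
            p = stats.binomtest(int(round(cb)), n, p0, alternative="two-sided").pvalue
        scaled_b = cb * lib_a / lib_b
        direction = "increase" if scaled_b > ca else "decrease"
        rows.append((chrom, start, end, ca, cb * lib_a / lib_b, direction, float(p)))

    qvals = bh_qvalues([r[6] for r in rows])
    out = [
        DifferentialIsland(chrom, start, end, ca, cb_scaled, direction, p, float(q))
        for (chrom, start, end, ca, cb_scaled, direction, p), q in zip(rows, qvals)
        if q < params.island_fdr
    ]
    out.sort(key=lambda i: (i.chrom, i.start))
    return out
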