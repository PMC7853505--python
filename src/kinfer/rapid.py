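"""Random-projection IBD segment detection over phased panels.

The detector replaces each window of ``w`` cM by the allele at one
randomly chosen site in the window, then finds all long exact matches
between the projected haplotypes with a PBWT scan.  A true IBD segment of
``S`` cM survives a projection when none of its ``L_win = S/w`` sampled
sites carries a mismatch (mutation or genotyping error); a random pair of
haplotypes produces a false hit when it agrees at ``L_win`` consecutive
sampled sites.  Running ``r`` independent projections and requiring ``c``
of them to succeed gives binomial detection/false-positive probabilities
that the parameter calculator inverts to choose ``w``.
"""

from __future__ import annotations

import dataclasses
import math
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import HaplotypePanel
from .pbwt import pbwt_long_matches


class InfeasibleParameters(ValueError):
    """No window size satisfies the requested power/accuracy targets."""


@dataclasses.dataclass
class RapidParams:
    """Detection parameters.

    Attributes
    ----------
    S : float
        Minimum IBD segment length to detect, cM.
    w : float
        Projection window size, cM.
    r : int
        Number of independent projection runs.
    c : int
        Required successful runs per reported segment.
    epsilon : float
        Per-projected-site mismatch rate between truly IBD haplotypes
        (mutation plus genotyping error).
    rho : float
        Probability that two random haplotypes agree at a projected site.
    seed : int
        Master seed; run ``i`` uses ``seed + i``.
    """

    S: float = 5.0
    w: float = 0.5
    r: int = 3
    c: int = 1
    epsilon: float = 0.002
    rho: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S <= 0 or self.w <= 0:
            raise ValueError("S and w must be positive")
        if not 1 <= self.c <= self.r:
            raise ValueError("need 1 <= c <= r")
        if not 0 <= self.epsilon < 1:
            raise ValueError("epsilon must be in [0, 1)")
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must be in [0, 1]")
        if self.L_win < 1:
            raise ValueError("S/w must round to at least one window")

    @property
    def L_win(self) -> int:
        """Windows a target-length segment must span."""
        return int(round(self.S / self.w))


@dataclasses.dataclass(slots=True)
class IBDSegment:
    """One haplotype-pair match, in site and cM coordinates.

    ``sample_a < sample_b``; the site interval is half-open
    ``[start_site, end_site)``; ``support`` counts projection runs that
    contributed to the (merged) interval.
    """

    sample_a: int
    sample_b: int
    hap_a: int
    hap_b: int
    chrom: str
    start_site: int
    end_site: int
    start_cm: float
    end_cm: float
    support: int = 1

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm

    @property
    def pair(self) -> tuple[int, int]:
        return (self.sample_a, self.sample_b)

    @property
    def pairing(self) -> tuple[int, int]:
        return (self.hap_a, self.hap_b)


def true_positive_prob(L_win: int, epsilon: float, r: int, c: int) -> float:
    """P(a segment spanning ``L_win`` windows is called in >= c of r runs).

    A single run succeeds when all ``L_win`` projected sites are
    mismatch-free, probability ``(1 - epsilon)^L_win ~= e^(-L_win*epsilon)``;
    the exponential form is used, matching the calculator's model.
    """
    if not 1 <= c <= r:
        raise ValueError("need 1 <= c <= r")
    if L_win < 1:
        raise ValueError("L_win must be >= 1")
    p = math.exp(-L_win * epsilon)
    return float(stats.binom.sf(c - 1, r, p))


def false_positive_prob(rho: float, L_win: int, r: int, c: int) -> float:
    """P(two random haplotypes fake a ``L_win``-window match in >= c runs)."""
    if not 1 <= c <= r:
        raise ValueError("need 1 <= c <= r")
    if L_win < 1:
        raise ValueError("L_win must be >= 1")
    if not 0 <= rho <= 1:
        raise ValueError("rho must be in [0, 1]")
    return float(stats.binom.sf(c - 1, r, rho**L_win))


def choose_parameters(
    S: float,
    epsilon: float,
    rho: float,
    tp_floor: float = 0.99,
    fp_ceiling: float = 1e-12,
    r: int = 3,
    c: int = 1,
    seed: int = 0,
    max_L: int = 100_000,
) -> RapidParams:
    """Pick a window size achieving both power and accuracy targets.

    Detection power decreases and the false-positive rate also decreases
    as ``L_win`` grows, so feasible window counts form an interval
    ``[L_min, L_max]``: ``L_min`` from ``fp <= fp_ceiling``, ``L_max``
    from ``tp >= tp_floor``.  ``w`` is taken at the midpoint of the
    corresponding window-size range ``[S/L_max, S/L_min]``.
    """
    if not 0 < tp_floor < 1 or not 0 < fp_ceiling < 1:
        raise InfeasibleParameters(
            "tp_floor must be in (0,1) and fp_ceiling in (0,1); "
            "tp=1 or fp=0 are only reached asymptotically"
        )
    # smallest L with fp <= ceiling
    L_min = None
    if rho == 0:
        L_min = 1
    else:
        lo, hi = 1, max_L
        if false_positive_prob(rho, hi, r, c) > fp_ceiling:
            raise InfeasibleParameters(
                "false-positive target unreachable; relax fp_ceiling or raise c"
            )
        while lo < hi:
            mid = (lo + hi) // 2
            if false_positive_prob(rho, mid, r, c) <= fp_ceiling:
                hi = mid
            else:
                lo = mid + 1
        L_min = lo
    # largest L with tp >= floor
    if epsilon == 0:
        L_max = max_L
    else:
        lo, hi = 1, max_L
        if true_positive_prob(1, epsilon, r, c) < tp_floor:
            raise InfeasibleParameters(
                "power target unreachable even at one window; relax tp_floor"
            )
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if true_positive_prob(mid, epsilon, r, c) >= tp_floor:
                lo = mid
            else:
                hi = mid - 1
        L_max = lo
    if L_min > L_max:
        raise InfeasibleParameters(
            f"no feasible window count: need L >= {L_min} for accuracy but "
            f"L <= {L_max} for power; relax tp_floor or fp_ceiling"
        )
    w = 0.5 * (S / L_max + S / L_min)
    return RapidParams(S=S, w=w, r=r, c=c, epsilon=epsilon, rho=rho, seed=seed)


# ---------------------------------------------------------------------------
# windows and projection
# ---------------------------------------------------------------------------


def window_assignment(panel: HaplotypePanel, w: float) -> tuple[np.ndarray, int]:
    """Assign each site to a window of ``w`` cM tiling the panel span.

    Windows are anchored at the first site's cM position.  Returns the
    per-site window index and the total number of windows in the tiling
    (including empty ones).  Sites with identical cM positions share a
    window; the site exactly at the far edge joins the last window.
    """
    if w <= 0:
        raise ValueError("window size must be positive")
    cm = panel.positions_cm
    if panel.n_sites == 0:
        raise ValueError("empty panel")
    rel = cm - cm[0]
    idx = np.floor(rel / w).astype(np.int64)
    n_win = int(idx[-1]) + 1
    return idx, n_win


def project_panel(
    panel: HaplotypePanel, w: float, seed: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """One random projection of the panel.

    For every non-empty window one site is drawn uniformly; empty windows
    are skipped.  Returns ``(projected, window_ids, n_windows)`` where
    ``projected`` is ``(2N, n_nonempty)`` and ``window_ids[j]`` is the
    tiling index of projected column ``j``.
    """
    site_win, n_win = window_assignment(panel, w)
    rng = np.random.default_rng(seed)
    # sites are sorted by window index already (cm non-decreasing)
    boundaries = np.searchsorted(site_win, np.arange(n_win + 1))
    chosen: list[int] = []
    win_ids: list[int] = []
    for wi in range(n_win):
        lo, hi = boundaries[wi], boundaries[wi + 1]
        if hi > lo:
            chosen.append(int(rng.integers(lo, hi)))
            win_ids.append(wi)
    chosen_arr = np.asarray(chosen, dtype=np.int64)
    projected = np.ascontiguousarray(panel.alleles[:, chosen_arr])
    return projected, np.asarray(win_ids, dtype=np.int64), n_win


def estimate_rho(
    panel: HaplotypePanel, windows: Sequence[int] | np.ndarray, seed: int = 0
) -> float:
    """Per-window probability that two random haplotypes agree.

    ``windows`` lists one projected site index per window; at a site with
    alternate-allele frequency p two random haplotypes agree with
    probability ``p^2 + (1-p)^2``.  Returns the mean over windows.
    """
    sites = np.asarray(windows, dtype=np.int64)
    if sites.size == 0:
        raise ValueError("need at least one window")
    if panel.n_haplotypes < 2:
        raise ValueError("need at least two haplotypes")
    p = panel.alleles[:, sites].mean(axis=0)
    return float(np.mean(p**2 + (1 - p) ** 2))


def estimate_rho_panel(panel: HaplotypePanel) -> float:
    """`estimate_rho` with every site as its own window (used before the
    window size is known; rho is a per-site quantity)."""
    return estimate_rho(panel, np.arange(panel.n_sites))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _merge_pair_intervals(
    intervals: list[tuple[int, int, int]], c: int
) -> list[tuple[int, int, int]]:
    """Union of window intervals ``(start, end, run)`` for one haplotype
    pair across runs; 0-gap adjacency merges touching intervals.  Returns
    ``(start, end, support)`` with support = #distinct contributing runs,
    filtered to support >= c."""
    intervals = sorted(intervals)
    merged: list[tuple[int, int, set[int]]] = []
    for s, e, run in intervals:
        if merged and s <= merged[-1][1]:
            prev = merged[-1]
            merged[-1] = (prev[0], max(prev[1], e), prev[2] | {run})
        else:
            merged.append((s, e, {run}))
    return [(s, e, len(runs)) for s, e, runs in merged if len(runs) >= c]


def detect_ibd(panel: HaplotypePanel, params: RapidParams) -> list[IBDSegment]:
    """Detect IBD segments of >= ``params.S`` cM among all sample pairs.

    Runs ``r`` independently seeded projections, finds >= ``L_win``-window
    exact matches per run with the PBWT scan, merges overlapping/adjacent
    matches per haplotype pair across runs (support = number of
    contributing runs), back-projects window intervals to cM (extending
    to window boundaries, clamped to the panel span) and keeps intervals
    with support >= c and length >= S.  Matches between the two
    haplotypes of one sample are discarded.
    """
    L_win = params.L_win
    cm = panel.positions_cm
    cm0, cm_last = float(cm[0]), float(cm[-1])
    per_pair: dict[tuple[int, int, int, int], list[tuple[int, int, int]]] = {}
    for run in range(params.r):
        projected, win_ids, _ = project_panel(panel, params.w, params.seed + run)
        if projected.shape[1] < L_win:
            continue
        for hi, hj, a, b in pbwt_long_matches(projected, L_win):
            if hi // 2 == hj // 2:
                continue  # same individual
            ws = int(win_ids[a])
            we = int(win_ids[b - 1]) + 1
            per_pair.setdefault((hi // 2, hj // 2, hi % 2, hj % 2), []).append(
                (ws, we, run)
            )
    segments: list[IBDSegment] = []
    for (sa, sb, ha, hb), intervals in sorted(per_pair.items()):
        for ws, we, support in _merge_pair_intervals(intervals, params.c):
            start_cm = max(cm0 + ws * params.w, cm0)
            end_cm = min(cm0 + we * params.w, cm_last)
            if end_cm - start_cm < params.S - 1e-9:
                continue
            start_site = int(np.searchsorted(cm, start_cm, side="left"))
            end_site = int(np.searchsorted(cm, end_cm, side="right"))
            segments.append(
                IBDSegment(
                    sample_a=sa,
                    sample_b=sb,
                    hap_a=ha,
                    hap_b=hb,
                    chrom=panel.chrom,
                    start_site=start_site,
                    end_site=end_site,
                    start_cm=start_cm,
                    end_cm=end_cm,
                    support=support,
                )
            )
    return segments


# ---------------------------------------------------------------------------
# segment TSV
# ---------------------------------------------------------------------------

SEGMENT_COLUMNS = [
    "sample1",
    "hap1",
    "sample2",
    "hap2",
    "chrom",
    "start_bp",
    "end_bp",
    "start_cm",
    "end_cm",
    "length_cm",
    "support",
]


def segments_to_frame(
    segments: Iterable[IBDSegment], panel: HaplotypePanel | None = None
) -> pd.DataFrame:
    """Tabulate segments; sample indices become ids when a panel is given."""
    rows = []
    for seg in segments:
        name_a, name_b = seg.sample_a, seg.sample_b
        if panel is not None:
            name_a = panel.sample_ids[seg.sample_a]
            name_b = panel.sample_ids[seg.sample_b]
        if panel is not None and panel.n_sites:
            start_bp = int(panel.positions_bp[min(seg.start_site, panel.n_sites - 1)])
            end_bp = int(panel.positions_bp[max(seg.end_site - 1, 0)])
        else:
            start_bp, end_bp = seg.start_site, seg.end_site
        rows.append(
            (
                name_a,
                seg.hap_a,
                name_b,
                seg.hap_b,
                seg.chrom,
                start_bp,
                end_bp,
                seg.start_cm,
                seg.end_cm,
                seg.length_cm,
                seg.support,
            )
        )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def write_segments(
    segments: Iterable[IBDSegment],
    path: str | os.PathLike,
    panel: HaplotypePanel | None = None,
) -> None:
    segments_to_frame(segments, panel).to_csv(path, sep="\t", index=False)


def read_segments(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
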