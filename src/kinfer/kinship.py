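"""Kinship estimation and degree classification from IBD segments.

For a pair of diploid individuals, detected haplotype matches are first
resolved into IBD1 (exactly one chromosome copy shared at a position) and
IBD2 (both copies shared) coverage.  With ``IBD1``/``IBD2`` the total cM
covered by each class and ``G`` the genome length in cM,

    phi_raw = IBD1/(4G) + IBD2/(2G)        (raw kinship coefficient)
    pi2_raw = IBD2/G                       (raw IBD2 fraction)

Phasing and genotyping errors shorten detected segments roughly
proportionally, so raw values are divided by a data-driven adjustment
factor ``alpha`` — the recoverable fraction of true IBD length — before
classification.  ``alpha`` is estimated from putative full siblings,
whose expected kinship 0.25 anchors the scale, by a fixed-point
iteration: alpha = mean(phi_raw over sibs)/0.25, sibs = pairs with
pi2_raw > alpha * 0.1.

Degrees follow the standard kinship decision boundaries: degree-d
relatives have expected phi = 2^-(d+1) and are called for phi in
(2^-(d+3/2), 2^-(d+1/2)]; within 1st degree, full siblings are separated
from parent-offspring by pi2 >= 0.1 (on the adjusted scale).
"""

from __future__ import annotations

import dataclasses
import math
import os
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .rapid import IBDSegment

DEGREE_LABELS = ["MZ", "PO", "FS", "2nd", "3rd", "4th", "unrelated"]

# phi boundaries: degree d in (2^-(d+1.5), 2^-(d+0.5)], d = 0 (MZ) .. 4
_UPPER = [2.0 ** (-(d + 0.5)) for d in range(5)]
_LOWER = [2.0 ** (-(d + 1.5)) for d in range(5)]
UNRELATED_BOUND = 2.0**-5.5
FS_PI2_CUTOFF = 0.1


@dataclasses.dataclass
class PairIBDProfile:
    """Total IBD1/IBD2 coverage (cM) for one sample pair over a genome of
    length ``G`` cM."""

    sample_a: int | str
    sample_b: int | str
    ibd1_cm: float
    ibd2_cm: float
    G: float

    def __post_init__(self) -> None:
        if self.G <= 0:
            raise ValueError("genome length G must be positive")
        if self.ibd1_cm < -1e-9 or self.ibd2_cm < -1e-9:
            raise ValueError("negative IBD coverage")
        if self.ibd1_cm + self.ibd2_cm > self.G * (1 + 1e-9):
            raise ValueError("IBD coverage exceeds genome length")

    @property
    def pi0(self) -> float:
        """Fraction of the genome with zero IBD sharing (derived)."""
        return 1.0 - (self.ibd1_cm + self.ibd2_cm) / self.G


@dataclasses.dataclass
class KinshipRecord:
    sample_a: int | str
    sample_b: int | str
    ibd1_cm: float
    ibd2_cm: float
    phi_raw: float
    pi2_raw: float
    phi_adj: float = float("nan")
    pi2_adj: float = float("nan")
    degree: str = ""


@dataclasses.dataclass
class AlphaState:
    """Result of the sibling-anchored adjustment-factor iteration."""

    alpha: float
    sib_pairs: list
    iterations: int


def resolve_ibd1_ibd2(
    segments: Sequence[IBDSegment], G: float
) -> PairIBDProfile:
    """Split one pair's haplotype matches into IBD1 and IBD2 coverage.

    A genomic position is IBD2 iff it is simultaneously covered by two
    matches whose haplotype pairings are disjoint — both haplotypes of
    each individual engaged, e.g. (a0-b0 and a1-b1) or (a0-b1 and a1-b0).
    A position covered by matches that reuse a haplotype (a0-b0 and
    a0-b1) is only IBD1.  Coverage is measured per chromosome with an
    interval sweep and summed.
    """
    if G <= 0:
        raise ValueError("genome length G must be positive")
    if not segments:
        raise ValueError("no segments given")
    pair = segments[0].pair
    for seg in segments:
        if seg.pair != pair:
            raise ValueError("segments from multiple sample pairs")
    ibd1 = 0.0
    ibd2 = 0.0
    by_chrom: dict[str, list[IBDSegment]] = defaultdict(list)
    for seg in segments:
        by_chrom[seg.chrom].append(seg)
    for segs in by_chrom.values():
        pts = sorted({s.start_cm for s in segs} | {s.end_cm for s in segs})
        if len(pts) < 2:
            continue
        pts_arr = np.asarray(pts)
        mids = 0.5 * (pts_arr[:-1] + pts_arr[1:])
        lengths = np.diff(pts_arr)
        active = np.zeros((4, len(mids)), dtype=bool)  # pairing (ha, hb) -> 2*ha+hb
        for s in segs:
            code = 2 * s.hap_a + s.hap_b
            active[code] |= (mids > s.start_cm) & (mids < s.end_cm)
        is2 = (active[0] & active[3]) | (active[1] & active[2])
        is1 = active.any(axis=0) & ~is2
        ibd2 += float(lengths[is2].sum())
        ibd1 += float(lengths[is1].sum())
    return PairIBDProfile(pair[0], pair[1], ibd1_cm=ibd1, ibd2_cm=ibd2, G=G)


def kinship_raw(profile: PairIBDProfile) -> tuple[float, float]:
    """Raw kinship coefficient and IBD2 fraction for one pair."""
    phi_raw = profile.ibd1_cm / (4 * profile.G) + profile.ibd2_cm / (2 * profile.G)
    pi2_raw = profile.ibd2_cm / profile.G
    return phi_raw, pi2_raw


def adjust_kinship(
    phi_raw: float, pi2_raw: float, alpha: float
) -> tuple[float, float]:
    """Rescale raw values by the recoverable-IBD fraction ``alpha``."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return phi_raw / alpha, pi2_raw / alpha


def classify_degree(phi_adj: float, pi2_adj: float) -> str:
    """Degree label from adjusted kinship and IBD2 fraction.

    Intervals are lower-exclusive/upper-inclusive; phi above the MZ upper
    bound (possible after adjustment) still maps to MZ.  Within 1st
    degree, full siblings require pi2 >= 0.1.
    """
    if not (math.isfinite(phi_adj) and math.isfinite(pi2_adj)):
        raise ValueError("non-finite kinship values")
    if phi_adj > _LOWER[0]:
        return "MZ"
    if phi_adj > _LOWER[1]:
        return "FS" if pi2_adj >= FS_PI2_CUTOFF else "PO"
    for d in (2, 3, 4):
        if phi_adj > _LOWER[d]:
            return DEGREE_LABELS[d + 1]  # "2nd", "3rd", "4th"
    return "unrelated"


def estimate_alpha(
    records: Sequence[KinshipRecord],
    k0: int = 50,
    max_pairs: int = 1000,
    min_increment: int = 50,
) -> AlphaState:
    """Estimate the adjustment factor from putative full siblings.

    The sibling set F starts as the ``k0`` pairs with the highest raw
    IBD2 fraction, then alternates alpha = mean_F(phi_raw)/0.25 with
    F = {pairs : pi2_raw > alpha * 0.1} until F reaches ``max_pairs``
    members (then truncated to the top ``max_pairs`` by pi2_raw) or an
    iteration adds no more than ``min_increment`` new pairs.  alpha is
    clamped to (0, 1].
    """
    candidates = [r for r in records if r.pi2_raw > 0]
    if len(candidates) < k0:
        raise ValueError(
            f"need at least k0={k0} pairs with positive pi2_raw to anchor "
            "the sibling set; provide a fixed alpha instead (estimation "
            "without full siblings is unreliable)"
        )
    order = sorted(candidates, key=lambda r: -r.pi2_raw)
    F = order[:k0]
    alpha = 1.0

    def _mean_alpha(pairs: Sequence[KinshipRecord]) -> float:
        a = float(np.mean([r.phi_raw for r in pairs])) / 0.25
        return min(max(a, 1e-12), 1.0)

    iterations = 0
    for _ in range(max(len(candidates), 1) + 2):
        iterations += 1
        alpha = _mean_alpha(F)
        new_F = [r for r in candidates if r.pi2_raw > alpha * FS_PI2_CUTOFF]
        added = len(new_F) - len(F)
        if len(new_F) >= max_pairs:
            F = sorted(new_F, key=lambda r: -r.pi2_raw)[:max_pairs]
            alpha = _mean_alpha(F)
            break
        if added <= min_increment:
            F = new_F if new_F else F
            alpha = _mean_alpha(F)
            break
        F = new_F
    return AlphaState(
        alpha=alpha,
        sib_pairs=[(r.sample_a, r.sample_b) for r in F],
        iterations=iterations,
    )


def profiles_from_segments(
    segments: Iterable[IBDSegment], G: float
) -> list[PairIBDProfile]:
    """Group segments by sample pair and resolve each pair's coverage."""
    grouped: dict[tuple, list[IBDSegment]] = defaultdict(list)
    for seg in segments:
        grouped[seg.pair].append(seg)
    return [resolve_ibd1_ibd2(segs, G) for _, segs in sorted(grouped.items())]


def infer_relatives(
    segments: Iterable[IBDSegment],
    G: float,
    alpha: float | None = None,
    k0: int = 50,
    max_pairs: int = 1000,
    min_increment: int = 50,
) -> tuple[list[KinshipRecord], AlphaState]:
    """Full inference pipeline for pairs sharing at least one segment.

    Resolves IBD1/IBD2 per pair, computes raw kinship, estimates the
    adjustment factor across the cohort (unless ``alpha`` is given),
    adjusts, and classifies.  Pairs classified unrelated are retained.
    """
    profiles = profiles_from_segments(segments, G)
    records: list[KinshipRecord] = []
    for prof in profiles:
        phi_raw, pi2_raw = kinship_raw(prof)
        records.append(
            KinshipRecord(
                sample_a=prof.sample_a,
                sample_b=prof.sample_b,
                ibd1_cm=prof.ibd1_cm,
                ibd2_cm=prof.ibd2_cm,
                phi_raw=phi_raw,
                pi2_raw=pi2_raw,
            )
        )
    if not records:
        return [], AlphaState(alpha=alpha if alpha else 1.0, sib_pairs=[], iterations=0)
    if alpha is None:
        state = estimate_alpha(records, k0=k0, max_pairs=max_pairs,
                               min_increment=min_increment)
    else:
        if not 0 < alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        state = AlphaState(alpha=alpha, sib_pairs=[], iterations=0)
    for rec in records:
        rec.phi_adj, rec.pi2_adj = adjust_kinship(rec.phi_raw, rec.pi2_raw, state.alpha)
        rec.degree = classify_degree(rec.phi_adj, rec.pi2_adj)
    return records, state


KINSHIP_COLUMNS = [
    "sample_a",
    "sample_b",
    "ibd1_cm",
    "ibd2_cm",
    "phi_raw",
    "pi2_raw",
    "phi_adj",
    "pi2_adj",
    "degree",
]


def records_to_frame(records: Iterable[KinshipRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.sample_a,
                r.sample_b,
                r.ibd1_cm,
                r.ibd2_cm,
                r.phi_raw,
                r.pi2_raw,
                r.phi_adj,
                r.pi2_adj,
                r.degree,
            )
            for r in records
        ],
        columns=KINSHIP_COLUMNS,
    )


def write_kinship(records: Iterable[KinshipRecord], path: str | os.PathLike) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_kinship(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
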