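"""Forward simulation of an outbred pedigree with known truth.

Founder haplotypes are frequency-sampled (sites independent, alternate
allele frequency uniform within configurable bounds, optionally
population-structured via a Balding-Nichols model), so the cohort has no
background linkage disequilibrium or background IBD.  Each subsequent
generation keeps the population size constant: non-overlapping couples
are formed by seeded shuffle and each child is produced by one gamete
from each parent, with crossovers per chromosome drawn Poisson with mean
``L/50`` (L the chromosome length in cM) and breakpoints uniform in cM.
With probability ``extra_pair_prob`` a child's father is replaced by a
random other male of the same generation (recorded as the biological
father in the truth pedigree).

Every transmitted haplotype carries its founder-ancestry track
(piecewise-constant founder-haplotype labels), which yields an exact
truth-IBD oracle; the truth pedigree yields exact kinship coefficients
by the standard recursive algorithm and hence truth degree labels.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np

from .panel import GeneticMap, HaplotypePanel

DEGREE_FROM_PHI_LABELS = ["MZ", "1st", "2nd", "3rd", "4th"]

# ancestry track: (breaks, labels) with breaks[0] == 0.0 (cM, relative to
# chromosome start) and labels[i] the founder haplotype for
# [breaks[i], breaks[i+1]); the last segment runs to the chromosome end.
Track = tuple[np.ndarray, np.ndarray]


@dataclasses.dataclass
class SimConfig:
    """Simulation parameters; defaults mirror the benchmark design:
    a 1000-founder population held at 1000 per generation, 500
    non-overlapping couples, 0.2 extra-pair probability, and a compact
    3-chromosome genome (150/120/100 cM, 5000 evenly spaced markers
    each) that keeps 4th-degree segments detectable at desk scale."""

    n_founders: int = 1000
    n_generations: int = 6
    keep_last: int | None = None  # defaults to min(4, n_generations)
    n_couples: int = 500
    extra_pair_prob: float = 0.2
    chrom_lengths_cm: tuple[float, ...] = (150.0, 120.0, 100.0)
    sites_per_chrom: tuple[int, ...] = (5000, 5000, 5000)
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_populations: int = 1
    fst: float = 0.0
    admixed_fraction: float = 0.0
    genotype_error_rate: float = 0.0
    switch_per_20cm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2 or self.n_founders % 2:
            raise ValueError("n_founders must be even and >= 2")
        if not 0 <= self.extra_pair_prob <= 1:
            raise ValueError("extra_pair_prob must be a probability")
        if 2 * self.n_couples > self.n_founders:
            raise ValueError("need 2*n_couples <= generation size")
        if len(self.chrom_lengths_cm) != len(self.sites_per_chrom):
            raise ValueError("chromosome length/site lists must align")
        if not 0 < self.maf_low <= self.maf_high < 1:
            raise ValueError("need 0 < maf_low <= maf_high < 1")
        if self.n_populations > 1 and self.fst < 0:
            raise ValueError("fst must be >= 0")
        if self.keep_last is None:
            self.keep_last = min(4, self.n_generations)
        # keep_last == n_generations + 1 keeps the founders in the panel
        if not 1 <= self.keep_last <= self.n_generations + 1:
            raise ValueError("keep_last must be in [1, n_generations + 1]")

    @property
    def genome_length_cm(self) -> float:
        return float(sum(self.chrom_lengths_cm))


@dataclasses.dataclass
class Individual:
    id: str
    generation: int
    mother: str | None
    father: str | None
    sex: str  # "M" or "F"

    @property
    def is_founder(self) -> bool:
        return self.mother is None


class Pedigree:
    """Truth pedigree with an exact kinship/degree oracle."""

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            self.individuals[ind.id] = ind
        for ind in self.individuals.values():
            for parent in (ind.mother, ind.father):
                if parent is not None:
                    p = self.individuals.get(parent)
                    if p is None:
                        raise ValueError(f"unknown parent {parent}")
                    if p.generation >= ind.generation:
                        raise ValueError("parents must be from an earlier generation")
        self._phi: dict[tuple[str, str], float] = {}

    def __contains__(self, iid: str) -> bool:
        return iid in self.individuals

    def __len__(self) -> int:
        return len(self.individuals)

    def kinship(self, a: str, b: str) -> float:
        """Pedigree kinship coefficient by the standard recursion:
        phi(i,i) = (1 + phi(mother_i, father_i))/2, and for i != j with i
        in the later generation phi(i,j) = (phi(mother_i, j) +
        phi(father_i, j))/2; distinct founders are unrelated."""
        key = (a, b) if a <= b else (b, a)
        cached = self._phi.get(key)
        if cached is not None:
            return cached
        ia, ib = self.individuals[a], self.individuals[b]
        if a == b:
            if ia.is_founder:
                val = 0.5
            else:
                val = 0.5 * (1.0 + self.kinship(ia.mother, ia.father))
        else:
            if ia.generation < ib.generation:
                ia, ib = ib, ia
            if ia.is_founder:
                val = 0.0  # both founders (ia later-or-equal gen), unrelated
            else:
                val = 0.5 * (
                    self.kinship(ia.mother, ib.id) + self.kinship(ia.father, ib.id)
                )
        self._phi[key] = val
        return val

    def is_parent_child(self, a: str, b: str) -> bool:
        ia, ib = self.individuals[a], self.individuals[b]
        return a in (ib.mother, ib.father) or b in (ia.mother, ia.father)

    def is_full_sibs(self, a: str, b: str) -> bool:
        ia, ib = self.individuals[a], self.individuals[b]
        if ia.is_founder or ib.is_founder:
            return False
        return ia.mother == ib.mother and ia.father == ib.father

    @property
    def _couples(self) -> set[tuple[str, str]]:
        pairs = getattr(self, "_couple_cache", None)
        if pairs is None:
            pairs = set()
            for ind in self.individuals.values():
                if ind.mother is not None:
                    pairs.add((ind.mother, ind.father))
                    pairs.add((ind.father, ind.mother))
            self._couple_cache = pairs
        return pairs

    def relationship_degree(self, a: str, b: str, max_depth: int = 6) -> int | None:
        """Degree of the closest pedigree relationship, or None if no
        shared ancestor within ``max_depth`` total meioses.

        The degree is the minimum over shared ancestors of the total
        path meioses, minus one when the minimum is achieved by a mated
        ancestor couple (both members shared at the same depths): full
        sibs 1, half sibs / grandparents / avuncular 2, first cousins 3,
        first cousins once removed 4, second cousins 5, and so on.
        """
        if a == b:
            return 0
        da = self._ancestor_depths(a, max_depth)
        db = self._ancestor_depths(b, max_depth)
        common = [c for c in da if c in db]
        if not common:
            return None
        m = min(da[c] + db[c] for c in common)
        if m > max_depth:
            return None
        best = [c for c in common if da[c] + db[c] == m]
        couples = self._couples
        for i, c1 in enumerate(best):
            for c2 in best[i + 1:]:
                if (c1, c2) in couples and da[c1] == da[c2] and db[c1] == db[c2]:
                    return m - 1
        return m

    def degree_label(self, a: str, b: str) -> str:
        """Truth degree label from the closest structural relationship;
        1st degree split into PO/FS; 5th or more distant -> unrelated.
        Structural labels agree with the kinship decision intervals for
        all simple (single) relationships and resolve compound ones the
        way pedigree extraction does."""
        d = self.relationship_degree(a, b)
        if d is None or d >= 5:
            return "unrelated"
        if d == 0:
            return "MZ"
        if d == 1:
            return "PO" if self.is_parent_child(a, b) else "FS"
        return ["2nd", "3rd", "4th"][d - 2]

    def _ancestor_depths(self, iid: str, max_depth: int) -> dict[str, int]:
        depths = {iid: 0}
        frontier = [(iid, 0)]
        while frontier:
            cur, d = frontier.pop()
            if d == max_depth:
                continue
            ind = self.individuals[cur]
            for parent in (ind.mother, ind.father):
                if parent is not None and depths.get(parent, 99) > d + 1:
                    depths[parent] = d + 1
                    frontier.append((parent, d + 1))
        return depths

    def related_pairs(
        self, ids: Sequence[str], max_depth: int = 6
    ) -> dict[tuple[str, str], str]:
        """Truth degrees for every pair of ``ids`` related up to 4th
        degree.  Candidate pairs are generated through shared ancestors
        (a degree <= 4 relationship needs a shared ancestor within
        ``max_depth`` total meioses), then labelled structurally."""
        descendants: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for iid in ids:
            for anc, d in self._ancestor_depths(iid, max_depth).items():
                descendants[anc].append((iid, d))
        candidates: set[tuple[str, str]] = set()
        for anc, members in descendants.items():
            members.sort()
            for i in range(len(members)):
                a, da = members[i]
                for j in range(i + 1, len(members)):
                    b, db = members[j]
                    if a != b and da + db <= max_depth:
                        candidates.add((a, b) if a <= b else (b, a))
        out: dict[tuple[str, str], str] = {}
        for a, b in sorted(candidates):
            label = self.degree_label(a, b)
            if label != "unrelated":
                out[(a, b)] = label
        return out


@dataclasses.dataclass
class FounderSet:
    """Founder haplotypes with per-chromosome panels and ancestry tracks."""

    panels: list[HaplotypePanel]
    tracks: list[list[Track]]  # [chrom][hap_row]
    populations: list[int] | None = None


@dataclasses.dataclass
class SimulatedCohort:
    """Output panel (last ``keep_last`` generations), truth pedigree and
    founder-ancestry tracks for the panel haplotypes."""

    panels: list[HaplotypePanel]
    pedigree: Pedigree
    tracks: list[list[Track]]
    config: SimConfig

    @property
    def sample_ids(self) -> list[str]:
        return self.panels[0].sample_ids

    @property
    def genome_length_cm(self) -> float:
        return float(sum(p.positions_cm[-1] - p.positions_cm[0] for p in self.panels))

    def truth_ibd(
        self, sample_a: int, sample_b: int, min_cm: float = 0.0
    ) -> list[tuple[int, int, int, float, float]]:
        """Exact IBD intervals between two samples from ancestry tracks.

        Returns ``(chrom_index, hap_a, hap_b, start_cm, end_cm)`` tuples
        (cM relative to the chromosome start) of at least ``min_cm``.
        """
        out = []
        for ci, chrom_tracks in enumerate(self.tracks):
            span = float(
                self.panels[ci].positions_cm[-1] - self.panels[ci].positions_cm[0]
            )
            for ha in (0, 1):
                for hb in (0, 1):
                    ta = chrom_tracks[2 * sample_a + ha]
                    tb = chrom_tracks[2 * sample_b + hb]
                    for s, e in _shared_intervals(ta, tb, span):
                        if e - s >= min_cm:
                            out.append((ci, ha, hb, s, e))
        return out


def _shared_intervals(ta: Track, tb: Track, span: float) -> list[tuple[float, float]]:
    """Intervals where two ancestry tracks carry the same founder label."""
    breaks_a, labels_a = ta
    breaks_b, labels_b = tb
    pts = np.union1d(breaks_a, breaks_b)
    la = labels_a[np.searchsorted(breaks_a, pts, side="right") - 1]
    lb = labels_b[np.searchsorted(breaks_b, pts, side="right") - 1]
    same = la == lb
    ends = np.append(pts[1:], span)
    out: list[tuple[float, float]] = []
    for s, e, eq in zip(pts, ends, same):
        if not eq or e <= s:
            continue
        if out and out[-1][1] >= s:
            out[-1] = (out[-1][0], e)
        else:
            out.append((float(s), float(e)))
    return out


# approximate genetic lengths (cM) of human autosomes 1..22
HUMAN_AUTOSOME_CM = (
    286.0, 269.0, 223.0, 214.0, 204.0, 192.0, 187.0, 168.0, 166.0, 181.0,
    158.0, 174.0, 126.0, 119.0, 141.0, 134.0, 128.0, 117.0, 107.0, 108.0,
    62.0, 74.0,
)


def human_autosome_config(sites_per_cm: float = 20.0, **kwargs) -> SimConfig:
    """A :class:`SimConfig` over the 22 human-autosome genetic lengths
    (~3540 cM), with marker density ``sites_per_cm``; other fields are
    passed through.  Used when classification accuracy itself is under
    study — realized-kinship variance scales inversely with the genome's
    recombination budget, so the compact default genome separates degree
    classes much less sharply than the full autosome set does."""
    sites = tuple(int(round(sites_per_cm * L)) for L in HUMAN_AUTOSOME_CM)
    return SimConfig(chrom_lengths_cm=HUMAN_AUTOSOME_CM, sites_per_chrom=sites, **kwargs)


def _uniform_positions(length_cm: float, n_sites: int) -> tuple[np.ndarray, np.ndarray]:
    cm = np.linspace(0.0, length_cm, n_sites)
    bp = np.round(cm * 1e6).astype(np.int64) + 1
    return bp, cm


def uniform_genetic_map(chrom: str, length_cm: float, step_cm: float = 1.0) -> GeneticMap:
    """Uniform 1 cM/Mb genetic map over ``[0, length_cm]``."""
    n = max(int(np.ceil(length_cm / step_cm)) + 1, 2)
    cm = np.linspace(0.0, length_cm, n)
    bp = np.round(cm * 1e6).astype(np.int64) + 1
    return GeneticMap(chrom=chrom, anchors_bp=bp, anchors_cm=cm)


def simulate_founders(config: SimConfig, seed: int | None = None) -> FounderSet:
    """Frequency-sampled founder haplotypes.

    Per site the alternate-allele frequency is uniform in
    ``[maf_low, maf_high]``.  With ``n_populations > 1`` these are
    ancestral frequencies and each population draws its own frequency
    from a Balding-Nichols Beta with divergence ``fst``; founders are
    assigned to populations round-robin, except an ``admixed_fraction``
    whose two haplotypes come from two different populations.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_hap = 2 * config.n_founders
    panels: list[HaplotypePanel] = []
    tracks: list[list[Track]] = []
    sample_ids = [f"G0I{i}" for i in range(config.n_founders)]
    npop = max(config.n_populations, 1)
    populations = [i % npop for i in range(config.n_founders)] if npop > 1 else None
    hap_pop = None
    if npop > 1:
        hap_pop = np.repeat(np.asarray(populations), 2)
        n_adm = int(config.admixed_fraction * config.n_founders)
        for i in range(n_adm):  # haplotype 1 from the next population over
            hap_pop[2 * i + 1] = (hap_pop[2 * i + 1] + 1) % npop
    hap_offset = 0
    for ci, (length_cm, m) in enumerate(
        zip(config.chrom_lengths_cm, config.sites_per_chrom)
    ):
        bp, cm = _uniform_positions(length_cm, m)
        p_anc = rng.uniform(config.maf_low, config.maf_high, size=m)
        if npop > 1 and config.fst > 0:
            f = config.fst
            a = p_anc * (1 - f) / f
            b = (1 - p_anc) * (1 - f) / f
            p_pop = rng.beta(a, b, size=(npop, m))
        else:
            p_pop = np.broadcast_to(p_anc, (npop, m))
        if npop > 1:
            alleles = (
                rng.random((n_hap, m)) < p_pop[hap_pop]
            ).astype(np.uint8)
        else:
            alleles = (rng.random((n_hap, m)) < p_anc).astype(np.uint8)
        panels.append(
            HaplotypePanel(
                alleles=alleles,
                sample_ids=sample_ids,
                chrom=f"chr{ci + 1}",
                positions_bp=bp,
                positions_cm=cm,
            )
        )
        tracks.append(
            [
                (np.array([0.0]), np.array([hap_offset + h], dtype=np.int64))
                for h in range(n_hap)
            ]
        )
        hap_offset += n_hap
    return FounderSet(panels=panels, tracks=tracks, populations=populations)


def make_gamete(
    hap0: np.ndarray,
    hap1: np.ndarray,
    track0: Track,
    track1: Track,
    length_cm: float,
    positions_cm: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, Track]:
    """One recombinant gamete from a parent's two haplotypes.

    Crossover count is Poisson with mean ``length_cm / 50``; breakpoints
    are uniform in cM; the source haplotype alternates at each
    breakpoint, starting from a fair coin.
    """
    k = rng.poisson(length_cm / 50.0)
    start = int(rng.integers(2))
    if k == 0:
        src_hap, src_track = (hap0, track0) if start == 0 else (hap1, track1)
        return src_hap.copy(), (src_track[0].copy(), src_track[1].copy())
    points = np.sort(rng.uniform(0.0, length_cm, size=k))
    rel = positions_cm - positions_cm[0]
    source = (start + np.searchsorted(points, rel, side="right")) % 2
    alleles = np.where(source == 0, hap0, hap1).astype(np.uint8)
    # splice the ancestry tracks at the breakpoints
    bounds = np.concatenate(([0.0], points, [length_cm]))
    breaks: list[float] = []
    labels: list[int] = []
    for i in range(len(bounds) - 1):
        lo, hi = bounds[i], bounds[i + 1]
        if hi <= lo:
            continue
        tb, tl = (track0, track1)[(start + i) % 2]
        j0 = int(np.searchsorted(tb, lo, side="right")) - 1
        j1 = int(np.searchsorted(tb, hi, side="left"))
        for j in range(j0, j1):
            s = max(float(tb[j]), lo)
            lab = int(tl[j])
            if labels and labels[-1] == lab and breaks[-1] <= s:
                continue  # same label continues across the boundary
            breaks.append(s)
            labels.append(lab)
    return alleles, (np.asarray(breaks), np.asarray(labels, dtype=np.int64))


def simulate_pedigree(
    founders: FounderSet, config: SimConfig, seed: int | None = None
) -> SimulatedCohort:
    """Grow the pedigree and return the last ``keep_last`` generations.

    Each generation forms ``n_couples`` disjoint couples by seeded
    shuffle; children keep the generation size constant and sexes
    alternate deterministically.  The biological father (after any
    extra-pair replacement) is recorded in the truth pedigree.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    size = config.n_founders
    n_chrom = len(config.chrom_lengths_cm)
    individuals: list[Individual] = [
        Individual(
            id=f"G0I{i}",
            generation=0,
            mother=None,
            father=None,
            sex="M" if i % 2 == 0 else "F",
        )
        for i in range(size)
    ]
    # live state per generation: ids, alleles per chrom, tracks per chrom
    gen_ids = [ind.id for ind in individuals]
    gen_sex = [ind.sex for ind in individuals]
    gen_alleles = [p.alleles for p in founders.panels]
    gen_tracks = [list(t) for t in founders.tracks]
    kept: list[tuple[list[str], list[np.ndarray], list[list[Track]]]] = []
    first_kept = config.n_generations - config.keep_last + 1
    if first_kept <= 0:
        kept.append((gen_ids, gen_alleles, gen_tracks))

    for g in range(1, config.n_generations + 1):
        males = [i for i, s in enumerate(gen_sex) if s == "M"]
        females = [i for i, s in enumerate(gen_sex) if s == "F"]
        rng.shuffle(males)
        rng.shuffle(females)
        couples = list(zip(males[: config.n_couples], females[: config.n_couples]))
        base, extra = divmod(size, config.n_couples)
        child_alleles = [
            np.empty((2 * size, a.shape[1]), dtype=np.uint8) for a in gen_alleles
        ]
        child_tracks: list[list[Track | None]] = [
            [None] * (2 * size) for _ in range(n_chrom)
        ]
        child_ids: list[str] = []
        child_sex: list[str] = []
        child_inds: list[Individual] = []
        ci_child = 0
        for k_couple, (father_idx, mother_idx) in enumerate(couples):
            n_children = base + (1 if k_couple < extra else 0)
            for _ in range(n_children):
                bio_father = father_idx
                if config.extra_pair_prob > 0 and rng.random() < config.extra_pair_prob:
                    others = [m for m in males if m != father_idx]
                    if others:
                        bio_father = others[int(rng.integers(len(others)))]
                cid = f"G{g}I{ci_child}"
                sex = "M" if ci_child % 2 == 0 else "F"
                child_inds.append(
                    Individual(
                        id=cid,
                        generation=g,
                        mother=gen_ids[mother_idx],
                        father=gen_ids[bio_father],
                        sex=sex,
                    )
                )
                for ch in range(n_chrom):
                    length = config.chrom_lengths_cm[ch]
                    pos_cm = founders.panels[ch].positions_cm
                    a = gen_alleles[ch]
                    t = gen_tracks[ch]
                    mat, mat_tr = make_gamete(
                        a[2 * mother_idx],
                        a[2 * mother_idx + 1],
                        t[2 * mother_idx],
                        t[2 * mother_idx + 1],
                        length,
                        pos_cm,
                        rng,
                    )
                    pat, pat_tr = make_gamete(
                        a[2 * bio_father],
                        a[2 * bio_father + 1],
                        t[2 * bio_father],
                        t[2 * bio_father + 1],
                        length,
                        pos_cm,
                        rng,
                    )
                    child_alleles[ch][2 * ci_child] = mat
                    child_alleles[ch][2 * ci_child + 1] = pat
                    child_tracks[ch][2 * ci_child] = mat_tr
                    child_tracks[ch][2 * ci_child + 1] = pat_tr
                child_ids.append(cid)
                child_sex.append(sex)
                ci_child += 1
        individuals.extend(child_inds)
        gen_ids, gen_sex = child_ids, child_sex
        gen_alleles = child_alleles
        gen_tracks = [list(t) for t in child_tracks]  # type: ignore[arg-type]
        if g >= first_kept:
            kept.append((gen_ids, gen_alleles, gen_tracks))

    out_ids: list[str] = []
    out_alleles = [[] for _ in range(n_chrom)]
    out_tracks: list[list[Track]] = [[] for _ in range(n_chrom)]
    for ids, alleles, tracks in kept:
        out_ids.extend(ids)
        for ch in range(n_chrom):
            out_alleles[ch].append(alleles[ch])
            out_tracks[ch].extend(tracks[ch])
    panels = [
        HaplotypePanel(
            alleles=np.concatenate(out_alleles[ch], axis=0),
            sample_ids=out_ids,
            chrom=founders.panels[ch].chrom,
            positions_bp=founders.panels[ch].positions_bp,
            positions_cm=founders.panels[ch].positions_cm,
        )
        for ch in range(n_chrom)
    ]
    return SimulatedCohort(
        panels=panels,
        pedigree=Pedigree(individuals),
        tracks=out_tracks,
        config=config,
    )


def simulate_cohort(config: SimConfig, seed: int | None = None) -> SimulatedCohort:
    """Founders + pedigree in one call (errors are injected separately)."""
    founders = simulate_founders(config, seed=seed)
    return simulate_pedigree(founders, config, seed=seed)


def inject_genotype_errors(
    panel: HaplotypePanel, rate: float, rng: np.random.Generator
) -> HaplotypePanel:
    """Flip each haplotype allele independently with probability ``rate``."""
    if not 0 <= rate <= 0.05:
        raise ValueError("genotype error rate must be in [0, 0.05]")
    if rate == 0:
        return panel
    flips = rng.random(panel.alleles.shape) < rate
    return HaplotypePanel(
        alleles=np.where(flips, 1 - panel.alleles, panel.alleles),
        sample_ids=panel.sample_ids,
        chrom=panel.chrom,
        positions_bp=panel.positions_bp,
        positions_cm=panel.positions_cm,
    )


def inject_switch_errors(
    panel: HaplotypePanel, switch_per_20cm: float, rng: np.random.Generator
) -> HaplotypePanel:
    """Add phasing switch errors as a per-individual Poisson process.

    Switch points arrive at rate ``switch_per_20cm / 20`` per cM; from
    each point to the chromosome end the individual's two haplotypes are
    swapped (so the site-wise genotype is unchanged).
    """
    if switch_per_20cm < 0:
        raise ValueError("switch rate must be >= 0")
    if switch_per_20cm == 0:
        return panel
    span = panel.span_cm
    rel = panel.positions_cm - panel.positions_cm[0]
    alleles = panel.alleles.copy()
    for i in range(panel.n_samples):
        k = rng.poisson(switch_per_20cm / 20.0 * span)
        if k == 0:
            continue
        points = np.sort(rng.uniform(0.0, span, size=k))
        swapped = (np.searchsorted(points, rel, side="right") % 2).astype(bool)
        h0 = alleles[2 * i].copy()
        alleles[2 * i, swapped] = alleles[2 * i + 1, swapped]
        alleles[2 * i + 1, swapped] = h0[swapped]
    return HaplotypePanel(
        alleles=alleles,
        sample_ids=panel.sample_ids,
        chrom=panel.chrom,
        positions_bp=panel.positions_bp,
        positions_cm=panel.positions_cm,
    )


def truth_degrees(
    pedigree: Pedigree, ids: Sequence[str]
) -> dict[tuple[str, str], str]:
    """Truth degree labels for all related pairs among ``ids`` (up to 4th
    degree); pairs absent from the result are unrelated."""
    return pedigree.related_pairs(ids)
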