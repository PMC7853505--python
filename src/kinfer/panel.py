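"""Phased haplotype panels, genetic maps, and their on-disk formats.

A :class:`HaplotypePanel` is the in-memory unit the whole pipeline operates
on: a binary allele matrix with two rows per sample (haplotype 0 then
haplotype 1, in sample order) over one chromosome, together with physical
(bp) and genetic (cM) coordinates per site.  Panels are read from phased
VCF (``GT`` with ``|`` separators, biallelic SNVs) and genetic positions
are obtained by piecewise-linear interpolation of a genetic map.
"""

from __future__ import annotations

import dataclasses
import io
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class PanelError(ValueError):
    """Raised for malformed panels, maps, or VCF records."""


@dataclasses.dataclass
class HaplotypePanel:
    """Binary allele matrix of 2N phased haplotypes over M sites.

    Parameters
    ----------
    alleles
        ``(2N, M)`` array of {0, 1}; row ``2*i`` is sample i's haplotype 0,
        row ``2*i + 1`` its haplotype 1.
    sample_ids
        N sample identifiers, in row order.
    chrom
        Chromosome name.
    positions_bp
        Strictly increasing physical positions.
    positions_cm
        Non-decreasing genetic positions in centimorgans.
    """

    alleles: np.ndarray
    sample_ids: list[str]
    chrom: str
    positions_bp: np.ndarray
    positions_cm: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.positions_cm = np.asarray(self.positions_cm, dtype=np.float64)
        self.sample_ids = list(self.sample_ids)
        n_hap, n_site = self.alleles.shape
        if n_hap % 2 != 0:
            raise PanelError("haplotype count must be even (2 per sample)")
        if n_hap != 2 * len(self.sample_ids):
            raise PanelError("sample_ids length does not match haplotype rows")
        if len(self.positions_bp) != n_site or len(self.positions_cm) != n_site:
            raise PanelError("coordinate arrays must match the site count")
        if n_site > 1:
            if np.any(np.diff(self.positions_bp) <= 0):
                raise PanelError("positions_bp must be strictly increasing")
            if np.any(np.diff(self.positions_cm) < 0):
                raise PanelError("positions_cm must be non-decreasing")
        if self.alleles.size and self.alleles.max(initial=0) > 1:
            raise PanelError("alleles must be biallelic {0,1}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def span_cm(self) -> float:
        """Genetic length covered by the panel (last cM minus first cM)."""
        if self.n_sites == 0:
            return 0.0
        return float(self.positions_cm[-1] - self.positions_cm[0])

    def haplotype(self, sample: int, hap: int) -> np.ndarray:
        return self.alleles[2 * sample + hap]


@dataclasses.dataclass
class GeneticMap:
    """Piecewise-linear bp -> cM map for one chromosome.

    Queries outside the anchor range are clamped to the terminal anchor's
    cM value rather than extrapolated.
    """

    chrom: str
    anchors_bp: np.ndarray
    anchors_cm: np.ndarray

    def __post_init__(self) -> None:
        self.anchors_bp = np.asarray(self.anchors_bp, dtype=np.int64)
        self.anchors_cm = np.asarray(self.anchors_cm, dtype=np.float64)
        if len(self.anchors_bp) < 2:
            raise PanelError("genetic map needs at least two anchors")
        if np.any(np.diff(self.anchors_bp) <= 0):
            raise PanelError("map anchors_bp must be strictly increasing")
        if np.any(np.diff(self.anchors_cm) < 0):
            raise PanelError("map anchors_cm must be non-decreasing")

    def interpolate(self, positions_bp: Sequence[int]) -> np.ndarray:
        return interpolate_cm(self, positions_bp)


def interpolate_cm(gmap: GeneticMap, positions_bp: Sequence[int]) -> np.ndarray:
    """Genetic positions for ``positions_bp`` by linear interpolation.

    np.interp clamps to the first/last anchor cM outside the anchor range,
    which is the behaviour we want for chromosome ends not covered by the
    map.
    """
    pos = np.asarray(positions_bp, dtype=np.float64)
    if pos.size > 1 and np.any(np.diff(pos) < 0):
        raise PanelError("query positions must be sorted ascending")
    return np.interp(pos, gmap.anchors_bp.astype(np.float64), gmap.anchors_cm)


def read_genetic_map(path: str | os.PathLike, chrom: str | None = None) -> GeneticMap:
    """Read a whitespace-delimited genetic map.

    Accepts either the 3-column layout ``chrom bp cM`` or the 4-column
    PLINK ``.map`` layout ``chrom id cM bp`` (detected by column count).
    A header line is tolerated if its bp field is non-numeric.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    if df.shape[1] == 3:
        cols = {"chrom": 0, "cm": 2, "bp": 1}
    elif df.shape[1] == 4:
        cols = {"chrom": 0, "cm": 2, "bp": 3}
    else:
        raise PanelError(f"unrecognised map layout with {df.shape[1]} columns")
    first_bp = df.iloc[0, cols["bp"]]
    try:
        float(first_bp)
    except ValueError:
        df = df.iloc[1:]
    if chrom is not None:
        df = df[df.iloc[:, cols["chrom"]].astype(str) == str(chrom)]
    if df.empty:
        raise PanelError("empty genetic map")
    chrom_out = str(df.iloc[0, cols["chrom"]]) if chrom is None else str(chrom)
    bp = df.iloc[:, cols["bp"]].astype(np.int64).to_numpy()
    cm = df.iloc[:, cols["cm"]].astype(np.float64).to_numpy()
    order = np.argsort(bp, kind="stable")
    return GeneticMap(chrom=chrom_out, anchors_bp=bp[order], anchors_cm=cm[order])


def write_genetic_map(gmap: GeneticMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for bp, cm in zip(gmap.anchors_bp, gmap.anchors_cm):
            fh.write(f"{gmap.chrom}\t{bp}\t{cm:.8g}\n")


def read_phased_vcf(
    path: str | os.PathLike,
    gmap: GeneticMap | None = None,
    strict: bool = True,
) -> HaplotypePanel:
    """Read a phased biallelic-SNV VCF into a :class:`HaplotypePanel`.

    Every genotype must be diploid and phased (``|`` separator).  With
    ``strict=True`` an unphased or missing genotype, or a multiallelic
    record, raises :class:`PanelError` naming the record; with
    ``strict=False`` offending records are skipped.

    Genetic positions come from ``gmap`` when given, otherwise from a
    ``CM`` INFO field, otherwise default to bp/1e6 (1 cM/Mb).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    columns: list[np.ndarray] = []
    positions: list[int] = []
    cm_info: list[float] = []
    chrom = ""
    for var in vcf:
        label = f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1 or var.is_indel:
            if strict:
                raise PanelError(f"non-biallelic-SNV record at {label}")
            continue
        gts = var.genotypes  # per sample: [allele0, allele1, phased]
        ok = True
        col = np.empty(2 * len(sample_ids), dtype=np.uint8)
        for i, gt in enumerate(gts):
            if len(gt) != 3 or gt[0] < 0 or gt[1] < 0:
                if strict:
                    raise PanelError(f"missing genotype at {label}, sample {sample_ids[i]}")
                ok = False
                break
            if not gt[2]:
                if strict:
                    raise PanelError(f"unphased genotype at {label}, sample {sample_ids[i]}")
                ok = False
                break
            col[2 * i] = gt[0]
            col[2 * i + 1] = gt[1]
        if not ok:
            continue
        chrom = var.CHROM
        columns.append(col)
        positions.append(var.POS)
        cm = var.INFO.get("CM")
        cm_info.append(float(cm) if cm is not None else np.nan)
    if not columns:
        raise PanelError(f"no usable phased records in {path}")
    alleles = np.stack(columns, axis=1)
    positions_bp = np.asarray(positions, dtype=np.int64)
    if gmap is not None:
        positions_cm = interpolate_cm(gmap, positions_bp)
    elif not np.isnan(cm_info).any():
        positions_cm = np.asarray(cm_info, dtype=np.float64)
    else:
        positions_cm = positions_bp / 1e6
    return HaplotypePanel(
        alleles=alleles,
        sample_ids=sample_ids,
        chrom=chrom,
        positions_bp=positions_bp,
        positions_cm=positions_cm,
    )


_VCF_HEADER = """##fileformat=VCFv4.2
##source=kinfer
##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic position in cM">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID={chrom}>
"""


def write_phased_vcf(panel: HaplotypePanel, path: str | os.PathLike) -> None:
    """Write a panel as a phased VCF (GT only, CM carried in INFO)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(chrom=panel.chrom))
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        a = panel.alleles
        for j in range(panel.n_sites):
            gts = "\t".join(
                f"{a[2 * i, j]}|{a[2 * i + 1, j]}" for i in range(panel.n_samples)
            )
            fh.write(
                f"{panel.chrom}\t{panel.positions_bp[j]}\t.\tA\tG\t.\tPASS\t"
                f"CM={panel.positions_cm[j]:.8g}\tGT\t{gts}\n"
            )


def thin_markers(
    panel: HaplotypePanel,
    keep_fraction: float,
    seed: int | None = None,
) -> HaplotypePanel:
    """Subsample markers for density experiments.

    Without a seed the subsampling is systematic — every k-th site with
    ``k = round(1/keep_fraction)`` — so repeated runs see identical panels.
    With a seed, a uniformly random sorted subset of
    ``floor(keep_fraction * M)`` sites is kept instead.
    """
    if not 0 < keep_fraction <= 1:
        raise PanelError("keep_fraction must be in (0, 1]")
    m = panel.n_sites
    if keep_fraction == 1:
        idx = np.arange(m)
    elif seed is None:
        k = int(round(1.0 / keep_fraction))
        idx = np.arange(0, m, k)
    else:
        rng = np.random.default_rng(seed)
        n_keep = int(np.floor(keep_fraction * m))
        idx = np.sort(rng.choice(m, size=n_keep, replace=False))
    if len(idx) < 2:
        raise PanelError("thinning would leave fewer than 2 sites")
    return HaplotypePanel(
        alleles=panel.alleles[:, idx],
        sample_ids=panel.sample_ids,
        chrom=panel.chrom,
        positions_bp=panel.positions_bp[idx],
        positions_cm=panel.positions_cm[idx],
    )
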