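"""End-to-end orchestration: simulate -> corrupt -> detect -> infer -> score.

This module wires the stages together the way the command-line
``end2end`` entry point and the robustness experiments use them.  All
randomness flows from a single master seed: the simulator, each error
injection, and each detection run derive their own streams from it, so
a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .benchmark import confusion, precision_recall_f1
from .kinship import AlphaState, KinshipRecord, infer_relatives
from .panel import HaplotypePanel
from .rapid import (
    IBDSegment,
    RapidParams,
    choose_parameters,
    detect_ibd,
    estimate_rho_panel,
)
from .simulate import (
    Pedigree,
    SimConfig,
    SimulatedCohort,
    inject_genotype_errors,
    inject_switch_errors,
    simulate_cohort,
    truth_degrees,
)


@dataclasses.dataclass
class DetectionConfig:
    """Detector settings for a whole (multi-chromosome) panel.

    ``assumed_genotype_error`` is the per-allele genotyping error rate
    the detector is parameterized for (the per-projected-site mismatch
    rate between IBD haplotypes is twice that, since a flip on either
    copy breaks the match); it is deliberately independent of the error
    rate actually injected, which is how misspecification experiments
    are run.
    """

    S: float = 5.0
    r: int = 3
    c: int = 1
    assumed_genotype_error: float = 0.001
    mutation_rate: float = 0.0
    tp_floor: float = 0.99
    fp_ceiling: float = 1e-12
    seed: int = 0

    @property
    def epsilon(self) -> float:
        return 2.0 * self.assumed_genotype_error + self.mutation_rate


def corrupt_panels(
    panels: Sequence[HaplotypePanel],
    genotype_error_rate: float,
    switch_per_20cm: float,
    seed: int,
) -> list[HaplotypePanel]:
    """Apply genotyping then switch errors to every chromosome panel."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    out = []
    for panel in panels:
        p = inject_genotype_errors(panel, genotype_error_rate, rng)
        p = inject_switch_errors(p, switch_per_20cm, rng)
        out.append(p)
    return out


def detect_panels(
    panels: Sequence[HaplotypePanel], det: DetectionConfig
) -> tuple[list[IBDSegment], list[RapidParams]]:
    """Choose parameters per chromosome and run detection on each.

    rho is estimated by scanning each chromosome's alleles; the window
    size then comes from the power/accuracy calculator.  Segment sample
    indices refer to the shared sample order of the panels.
    """
    all_segments: list[IBDSegment] = []
    used: list[RapidParams] = []
    for ci, panel in enumerate(panels):
        rho = estimate_rho_panel(panel)
        params = choose_parameters(
            S=det.S,
            epsilon=det.epsilon,
            rho=rho,
            tp_floor=det.tp_floor,
            fp_ceiling=det.fp_ceiling,
            r=det.r,
            c=det.c,
            seed=det.seed + 1000 * ci,
        )
        used.append(params)
        all_segments.extend(detect_ibd(panel, params))
    return all_segments, used


@dataclasses.dataclass
class End2EndResult:
    cohort: SimulatedCohort
    segments: list[IBDSegment]
    records: list[KinshipRecord]
    alpha: AlphaState
    truth: dict
    matrix: pd.DataFrame
    metrics: pd.DataFrame


def infer_and_score(
    cohort: SimulatedCohort,
    segments: Sequence[IBDSegment],
    alpha: float | None = None,
    k0: int = 50,
    max_pairs: int = 1000,
    min_increment: int = 50,
    truth: dict | None = None,
) -> End2EndResult:
    """Kinship inference on detected segments plus truth benchmarking."""
    ids = cohort.sample_ids
    records, state = infer_relatives(
        segments,
        G=cohort.genome_length_cm,
        alpha=alpha,
        k0=k0,
        max_pairs=max_pairs,
        min_increment=min_increment,
    )
    if truth is None:
        truth = truth_degrees(cohort.pedigree, ids)
    inferred = {
        tuple(sorted((ids[r.sample_a], ids[r.sample_b]))): r.degree
        for r in records
        if r.degree != "unrelated"
    }
    matrix = confusion(truth, inferred)
    metrics = precision_recall_f1(matrix)
    return End2EndResult(
        cohort=cohort,
        segments=list(segments),
        records=records,
        alpha=state,
        truth=truth,
        matrix=matrix,
        metrics=metrics,
    )


def end2end(
    sim: SimConfig,
    det: DetectionConfig | None = None,
    alpha: float | None = None,
    cohort: SimulatedCohort | None = None,
    truth: dict | None = None,
) -> End2EndResult:
    """Full pipeline under one seed; ``cohort``/``truth`` may be passed in
    to reuse one simulation across several error conditions."""
    if cohort is None:
        cohort = simulate_cohort(sim)
    det = det or DetectionConfig(seed=sim.seed)
    panels = corrupt_panels(
        cohort.panels, sim.genotype_error_rate, sim.switch_per_20cm, sim.seed
    )
    segments, _ = detect_panels(panels, det)
    return infer_and_score(cohort, segments, alpha=alpha, truth=truth)


def run_experiment_grid(
    sim: SimConfig,
    det: DetectionConfig | None = None,
    genotype_error_rates: Sequence[float] = (0.0,),
    switch_rates: Sequence[float] = (0.0,),
) -> pd.DataFrame:
    """One end-to-end run per (genotyping error, switch error) grid cell.

    The underlying cohort and truth are simulated once and re-corrupted
    per cell.  Returns tidy per-degree metric rows; a failing cell is
    recorded with an ``error`` column and does not abort the grid.
    """
    cohort = simulate_cohort(sim)
    truth = truth_degrees(cohort.pedigree, cohort.sample_ids)
    det = det or DetectionConfig(seed=sim.seed)
    rows = []
    for ge in genotype_error_rates:
        for sw in switch_rates:
            cell_sim = dataclasses.replace(
                sim, genotype_error_rate=ge, switch_per_20cm=sw
            )
            try:
                res = end2end(cell_sim, det, cohort=cohort, truth=truth)
            except Exception as exc:  # keep other cells running
                rows.append(
                    {
                        "genotype_error": ge,
                        "switch_per_20cm": sw,
                        "degree": "",
                        "error": str(exc),
                    }
                )
                continue
            for degree, row in res.metrics.iterrows():
                rows.append(
                    {
                        "genotype_error": ge,
                        "switch_per_20cm": sw,
                        "degree": degree,
                        "TP": int(row["TP"]),
                        "P": int(row["P"]),
                        "FP": int(row["FP"]),
                        "recall": row["recall"],
                        "precision": row["precision"],
                        "F1": row["F1"],
                        "alpha": res.alpha.alpha,
                    }
                )
    return pd.DataFrame(rows)
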