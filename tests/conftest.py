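"""Shared fixtures and independent oracles.

The expensive end-to-end fixtures are session-scoped and reused across
tests: one error-free cohort on the compact 3-chromosome genome (class
means, alpha behaviour) and one cohort on the 22-chromosome
human-autosome-length genome (classification accuracy, which depends on
the genome's recombination budget).
"""

from __future__ import annotations

import numpy as np
import pytest

from kinfer import (
    DetectionConfig,
    SimConfig,
    human_autosome_config,
    simulate_cohort,
    truth_degrees,
)
from kinfer.pipeline import corrupt_panels, detect_panels, infer_and_score


# ---------------------------------------------------------------------------
# independent oracles (kept free of the implementation paths they check)
# ---------------------------------------------------------------------------


def brute_force_long_matches(H: np.ndarray, min_length: int):
    """All maximal >= min_length-column exact row matches by direct
    all-pairs scanning."""
    out = []
    N, M = H.shape
    for i in range(N):
        for j in range(i + 1, N):
            eq = H[i] == H[j]
            k = 0
            while k < M:
                if eq[k]:
                    s = k
                    while k < M and eq[k]:
                        k += 1
                    if k - s >= min_length:
                        out.append((i, j, s, k))
                else:
                    k += 1
    return sorted(out)


def rasterized_ibd1_ibd2(segments, G, step=0.01):
    """IBD1/IBD2 totals by brute-force rasterization of the genome on a
    fine grid (independent of the interval-sweep implementation)."""
    from collections import defaultdict

    ibd1 = ibd2 = 0.0
    by_chrom = defaultdict(list)
    for s in segments:
        by_chrom[s.chrom].append(s)
    for segs in by_chrom.values():
        hi = max(s.end_cm for s in segs)
        grid = np.arange(step / 2, hi, step)
        active = np.zeros((4, len(grid)), dtype=bool)
        for s in segs:
            code = 2 * s.hap_a + s.hap_b
            active[code] |= (grid > s.start_cm) & (grid < s.end_cm)
        is2 = (active[0] & active[3]) | (active[1] & active[2])
        is1 = active.any(axis=0) & ~is2
        ibd2 += is2.sum() * step
        ibd1 += is1.sum() * step
    return ibd1, ibd2


# ---------------------------------------------------------------------------
# session-scoped cohorts
# ---------------------------------------------------------------------------

COMPACT_SEED = 11
AUTOSOME_SEED = 3


@pytest.fixture(scope="session")
def compact_cohort():
    """Error-free cohort on the default 3-chromosome genome, scaled to a
    400-per-generation population (keeps class counts >= 100 while
    staying desk-sized)."""
    sim = SimConfig(
        n_founders=400, n_couples=200, n_generations=5, keep_last=4, seed=COMPACT_SEED
    )
    cohort = simulate_cohort(sim)
    truth = truth_degrees(cohort.pedigree, cohort.sample_ids)
    return sim, cohort, truth


@pytest.fixture(scope="session")
def compact_result(compact_cohort):
    """Detection + inference on the error-free compact cohort."""
    sim, cohort, truth = compact_cohort
    segments, params = detect_panels(cohort.panels, DetectionConfig(seed=COMPACT_SEED))
    res = infer_and_score(cohort, segments, truth=truth)
    return res, params


@pytest.fixture(scope="session")
def switch_alpha_curve(compact_cohort):
    """Estimated adjustment factor at 1, 3 and 5 switch errors per 20 cM
    on the compact cohort (detection re-run per rate)."""
    sim, cohort, truth = compact_cohort
    det = DetectionConfig(seed=COMPACT_SEED)
    alphas = {}
    for sw in (1.0, 3.0, 5.0):
        panels = corrupt_panels(cohort.panels, 0.0, sw, sim.seed)
        segments, _ = detect_panels(panels, det)
        res = infer_and_score(cohort, segments, truth=truth)
        alphas[sw] = res.alpha.alpha
    return alphas


@pytest.fixture(scope="session")
def autosome_cohort():
    """200-per-generation cohort on the 22-chromosome human-autosome
    genetic lengths; used where classification accuracy is scored."""
    sim = human_autosome_config(
        n_founders=200, n_couples=100, n_generations=5, keep_last=4, seed=AUTOSOME_SEED
    )
    cohort = simulate_cohort(sim)
    truth = truth_degrees(cohort.pedigree, cohort.sample_ids)
    return sim, cohort, truth


def run_error_cell(sim, cohort, truth, genotype_error, switch_rate, seed):
    """Corrupt, detect, infer and score one error-grid cell."""
    panels = corrupt_panels(cohort.panels, genotype_error, switch_rate, seed)
    segments, _ = detect_panels(panels, DetectionConfig(seed=seed))
    return infer_and_score(cohort, segments, truth=truth)
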