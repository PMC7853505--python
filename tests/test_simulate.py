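"""Pedigree simulator: founders, gametes, mating structure, error
injection, and the truth oracles (kinship, degrees, IBD tracks)."""

import numpy as np
import pytest

from kinfer.simulate import (
    Individual,
    Pedigree,
    SimConfig,
    inject_genotype_errors,
    inject_switch_errors,
    make_gamete,
    simulate_cohort,
    simulate_founders,
    simulate_pedigree,
)


class TestFounders:
    def test_degenerate_frequency_bounds(self):
        cfg = SimConfig(n_founders=200, n_couples=100, chrom_lengths_cm=(50.0,),
                        sites_per_chrom=(500,), maf_low=0.5, maf_high=0.5, seed=1)
        founders = simulate_founders(cfg)
        freq = founders.panels[0].alleles.mean()
        assert freq == pytest.approx(0.5, abs=0.01)

    def test_single_population_has_no_labels(self):
        cfg = SimConfig(n_founders=50, n_couples=25, chrom_lengths_cm=(50.0,),
                        sites_per_chrom=(200,), seed=1)
        assert simulate_founders(cfg).populations is None

    def test_zero_divergence_populations_statistically_identical(self):
        cfg = SimConfig(n_founders=400, n_couples=200, chrom_lengths_cm=(50.0,),
                        sites_per_chrom=(2000,), n_populations=2, fst=0.0, seed=2)
        founders = simulate_founders(cfg)
        pops = np.repeat(founders.populations, 2)
        a = founders.panels[0].alleles[pops == 0].mean(axis=0)
        b = founders.panels[0].alleles[pops == 1].mean(axis=0)
        # per-site frequency differences are pure binomial noise
        assert abs(float(np.mean(a - b))) < 0.01

    def test_diverged_populations_differ(self):
        cfg = SimConfig(n_founders=400, n_couples=200, chrom_lengths_cm=(50.0,),
                        sites_per_chrom=(2000,), n_populations=2, fst=0.2, seed=2)
        founders = simulate_founders(cfg)
        pops = np.repeat(founders.populations, 2)
        a = founders.panels[0].alleles[pops == 0].mean(axis=0)
        b = founders.panels[0].alleles[pops == 1].mean(axis=0)
        assert float(np.mean(np.abs(a - b))) > 0.05


class TestMakeGamete:
    def setup_method(self):
        self.L = 100.0
        self.pos = np.linspace(0, self.L, 2000)
        self.h0 = np.zeros(2000, np.uint8)
        self.h1 = np.ones(2000, np.uint8)
        self.t0 = (np.array([0.0]), np.array([7], dtype=np.int64))
        self.t1 = (np.array([0.0]), np.array([8], dtype=np.int64))

    def test_mean_crossover_count(self):
        rng = np.random.default_rng(3)
        switches = []
        for _ in range(4000):
            g, _ = make_gamete(self.h0, self.h1, self.t0, self.t1,
                               self.L, self.pos, rng)
            switches.append(int((np.diff(g.astype(int)) != 0).sum()))
        # lambda = L/50 = 2; MC standard error ~ sqrt(2/4000)
        assert np.mean(switches) == pytest.approx(2.0, abs=0.1)

    def test_alleles_conserved_from_parents(self):
        rng = np.random.default_rng(4)
        ha = rng.integers(0, 2, 500).astype(np.uint8)
        hb = rng.integers(0, 2, 500).astype(np.uint8)
        pos = np.linspace(0, 80, 500)
        g, _ = make_gamete(ha, hb, self.t0, self.t1, 80.0, pos, rng)
        assert np.all((g == ha) | (g == hb))

    def test_track_matches_alleles(self):
        rng = np.random.default_rng(5)
        g, (breaks, labels) = make_gamete(self.h0, self.h1, self.t0, self.t1,
                                          self.L, self.pos, rng)
        # label 7 segments must carry hap0 alleles (0), label 8 -> hap1 (1)
        ends = np.append(breaks[1:], self.L + 1)
        for s, e, lab in zip(breaks, ends, labels):
            mask = (self.pos >= s) & (self.pos < e)
            assert np.all(g[mask] == (0 if lab == 7 else 1))


class TestPedigreeStructure:
    CFG = dict(n_founders=60, n_couples=30, n_generations=3, keep_last=3,
               chrom_lengths_cm=(60.0,), sites_per_chrom=(600,))

    def test_generation_sizes_constant(self):
        cohort = simulate_cohort(SimConfig(seed=6, **self.CFG))
        gens = {}
        for ind in cohort.pedigree.individuals.values():
            gens[ind.generation] = gens.get(ind.generation, 0) + 1
        assert set(gens.values()) == {60}

    def test_parents_come_from_previous_generation(self):
        cohort = simulate_cohort(SimConfig(seed=6, **self.CFG))
        ped = cohort.pedigree
        for ind in ped.individuals.values():
            if not ind.is_founder:
                assert ped.individuals[ind.mother].generation == ind.generation - 1
                assert ped.individuals[ind.father].generation == ind.generation - 1

    def test_no_extra_pair_means_all_couple_children_full_sibs(self):
        cfg = SimConfig(seed=7, extra_pair_prob=0.0, **self.CFG)
        cohort = simulate_cohort(cfg)
        ped = cohort.pedigree
        by_mother = {}
        for ind in ped.individuals.values():
            if not ind.is_founder:
                by_mother.setdefault(ind.mother, []).append(ind)
        for children in by_mother.values():
            assert len({c.father for c in children}) == 1

    def test_error_free_panels_are_mendelian_consistent(self):
        cohort = simulate_cohort(SimConfig(seed=8, **self.CFG))
        panel = cohort.panels[0]
        ids = {n: i for i, n in enumerate(cohort.sample_ids)}
        ped = cohort.pedigree
        checked = 0
        for name, ind in ped.individuals.items():
            if ind.is_founder or name not in ids or ind.mother not in ids:
                continue
            child = ids[name]
            mother = ids[ind.mother]
            # maternal haplotype is a mosaic of the mother's two haplotypes
            m0 = panel.haplotype(mother, 0)
            m1 = panel.haplotype(mother, 1)
            c0 = panel.haplotype(child, 0)
            assert np.all((c0 == m0) | (c0 == m1))
            checked += 1
        assert checked >= 30

    def test_truth_ibd_tracks_agree_with_alleles(self):
        cohort = simulate_cohort(SimConfig(seed=9, **self.CFG))
        panel = cohort.panels[0]
        ids = cohort.sample_ids
        pos = panel.positions_cm
        found = 0
        for a in range(5):
            for b in range(a + 1, 12):
                for ci, ha, hb, s, e in cohort.truth_ibd(a, b, min_cm=1.0):
                    mask = (pos >= s) & (pos < e)
                    if mask.sum() == 0:
                        continue
                    assert np.array_equal(
                        panel.haplotype(a, ha)[mask], panel.haplotype(b, hb)[mask]
                    )
                    found += 1
        assert found > 0


def hand_pedigree():
    """Three generations with the classic relationship examples."""
    inds = [Individual(f"F{i}", 0, None, None, "M" if i % 2 == 0 else "F")
            for i in range(8)]
    # couple F0 x F1 -> A, B (full sibs); F2 x F3 -> C; F4 x F5 -> D
    inds += [
        Individual("A", 1, "F1", "F0", "M"),
        Individual("B", 1, "F1", "F0", "F"),
        Individual("C", 1, "F3", "F2", "F"),
        Individual("D", 1, "F5", "F4", "M"),
        Individual("H", 1, "F3", "F0", "M"),  # half-sib of A/B via F0
    ]
    # A x C -> E ; B x D -> G  (E and G are first cousins)
    inds += [
        Individual("E", 2, "C", "A", "M"),
        Individual("G", 2, "D", "B", "F"),
    ]
    # E's child with unrelated F6-descendant is G's first cousin once removed
    inds += [
        Individual("U", 1, "F7", "F6", "F"),
        Individual("W", 3, "U", "E", "M"),
    ]
    return Pedigree(inds)


class TestTruthDegrees:
    def setup_method(self):
        self.ped = hand_pedigree()

    @pytest.mark.parametrize(
        "a,b,label",
        [
            ("F0", "A", "PO"),
            ("A", "B", "FS"),
            ("A", "H", "2nd"),   # half sibs
            ("F0", "E", "2nd"),  # grandparent
            ("B", "E", "2nd"),   # avuncular
            ("E", "G", "3rd"),   # first cousins
            ("G", "W", "4th"),   # first cousins once removed
            ("A", "D", "unrelated"),
            ("F0", "W", "3rd"),  # great-grandparent
        ],
    )
    def test_structural_labels(self, a, b, label):
        assert self.ped.degree_label(a, b) == label

    def test_kinship_recursion_values(self):
        assert self.ped.kinship("F0", "A") == pytest.approx(0.25)
        assert self.ped.kinship("A", "B") == pytest.approx(0.25)
        assert self.ped.kinship("A", "H") == pytest.approx(0.125)  # half sibs
        assert self.ped.kinship("E", "G") == pytest.approx(0.0625)
        assert self.ped.kinship("G", "W") == pytest.approx(0.03125)

    def test_related_pairs_covers_hand_examples(self):
        ids = [i for i in self.ped.individuals]
        rel = self.ped.related_pairs(ids)
        assert rel[("A", "B")] == "FS"
        assert rel[("E", "G")] == "3rd"
        assert ("A", "D") not in rel

    def test_cyclic_pedigree_rejected(self):
        with pytest.raises(ValueError):
            Pedigree([
                Individual("X", 0, None, None, "M"),
                Individual("Y", 1, "Z", "X", "F"),
                Individual("Z", 1, "Y", "X", "F"),
            ])


class TestErrorInjection:
    def make_panel(self):
        cfg = SimConfig(n_founders=100, n_couples=50, chrom_lengths_cm=(100.0,),
                        sites_per_chrom=(2000,), seed=10)
        return simulate_founders(cfg).panels[0]

    def test_zero_rates_are_identity(self):
        panel = self.make_panel()
        rng = np.random.default_rng(0)
        assert inject_genotype_errors(panel, 0.0, rng) is panel
        assert inject_switch_errors(panel, 0.0, rng) is panel

    def test_genotype_error_flip_count(self):
        panel = self.make_panel()
        rng = np.random.default_rng(1)
        noisy = inject_genotype_errors(panel, 0.005, rng)
        flips = int((noisy.alleles != panel.alleles).sum())
        n = panel.alleles.size
        assert flips == pytest.approx(0.005 * n, abs=4 * np.sqrt(0.005 * n))

    def test_switch_errors_preserve_genotypes(self):
        panel = self.make_panel()
        rng = np.random.default_rng(2)
        switched = inject_switch_errors(panel, 3.0, rng)
        for i in range(panel.n_samples):
            g0 = panel.haplotype(i, 0).astype(int) + panel.haplotype(i, 1)
            g1 = switched.haplotype(i, 0).astype(int) + switched.haplotype(i, 1)
            np.testing.assert_array_equal(g0, g1)

    def test_switch_point_rate(self):
        panel = self.make_panel()
        rng = np.random.default_rng(3)
        switched = inject_switch_errors(panel, 1.0, rng)
        # count haplotype-source changes at heterozygous sites
        n_switch = 0
        for i in range(panel.n_samples):
            het = panel.haplotype(i, 0) != panel.haplotype(i, 1)
            src = switched.haplotype(i, 0)[het] == panel.haplotype(i, 1)[het]
            n_switch += int((np.diff(src.astype(int)) != 0).sum())
        # 100 cM at 1 per 20 cM -> 5 expected per individual
        expected = 5.0 * panel.n_samples
        assert n_switch == pytest.approx(expected, rel=0.25)
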