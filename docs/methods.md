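# Methods

`kinfer` infers familial relationships in phased cohorts from
identity-by-descent (IBD) segments. This note records the model, the
numerical choices, and what the synthetic benchmark does and does not
establish.

## IBD detection by random projection

The input is a panel of phased haplotypes with genetic (cM) coordinates.
The genome is tiled into windows of `w` cM anchored at the first site;
each projection replaces every non-empty window by the allele at one
uniformly chosen site in it (empty windows are skipped and do not count
toward window runs). All maximal exact matches between projected
haplotypes spanning at least `L_win = S/w` windows are found with a
positional Burrows–Wheeler transform scan (positional prefix + divergence
arrays, reporting a match when it terminates), which is linear in panel
size plus output size — no all-pairs comparison. The scan is verified in
the test suite against an independent brute-force all-pairs oracle.

With a per-projected-site mismatch probability ε between truly IBD
haplotypes (mutation + genotyping error), one projection retains a
segment spanning `L_win` windows with probability `e^(−L_win·ε)`, and a
random haplotype pair fakes it with probability `ρ^L_win`, where ρ is
the probability two random haplotypes agree at a projected site
(estimated from the panel as the mean over windows of `p² + (1−p)²` at
the projected site's alternate-allele frequency `p`). Over `r` runs
requiring `c` successes, detection power and false-positive probability
are binomial tail sums; the parameter calculator inverts both bounds
(power decreasing in `L_win`, false positives decreasing in `L_win`,
hence a feasible interval) and takes the midpoint of the feasible
window-size range. Defaults follow the relatedness-oriented regime:
S = 5 cM, r = 3, c = 1, detector parameterized for a 0.1% per-allele
genotyping error (ε = 2 × 0.001, since a flip on either copy breaks a
haplotype match), power floor 0.99, false-positive ceiling 1e−12 (small
enough that the expected genome-wide false call count stays ≪ 1 across
~10⁶ pair-window trials at desk scale).

Per haplotype pair, window-interval matches from the `r` runs are merged
by union with zero-gap adjacency; the support of a merged interval is
the number of runs contributing to it, and intervals with support ≥ c
and back-projected length ≥ S cM are reported. Back-projection extends
matched runs to window boundaries, clamped to the panel span. A
boundary effect worth noting: an IBD segment of *exactly* S cM covers
`L_win` complete windows only when aligned to the window grid; unaligned
exactly-S segments cover `L_win − 1` complete windows plus two partials
and are detected with reduced probability. The power model (and the
power test, which plants grid-aligned segments) applies to segments
spanning `L_win` full windows; segments comfortably longer than S — the
relevant regime for relatives — are unaffected.

## Kinship from IBD1/IBD2 coverage

For each sample pair sharing at least one segment, coverage is resolved
by an interval sweep: a position is IBD2 iff covered simultaneously by
two matches with disjoint haplotype pairings (both haplotypes of each
individual engaged — (a0·b0, a1·b1) or (a0·b1, a1·b0)); positions covered
otherwise are IBD1. A haplotype matched to both haplotypes of the
partner remains IBD1. With `G` the total genome length in cM,

    phi_raw = IBD1/(4G) + IBD2/(2G),    pi2_raw = IBD2/G.

Phasing switch errors cut haplotype matches and shorten detected
segments roughly proportionally, so raw values are divided by an
adjustment factor α — the recoverable fraction of true IBD length —
estimated from putative full siblings, whose expected kinship 0.25
anchors the scale:

    alpha = mean_F(phi_raw) / 0.25,     F = {pairs : pi2_raw > alpha·0.1}.

F is initialised with the k0 = 50 pairs of highest pi2_raw and the two
equations are iterated until F reaches 1000 pairs (then truncated to the
top 1000 by pi2_raw) or an iteration adds at most 50 new pairs; α is
recomputed on the final set and clamped to (0, 1]. The iteration is
monotone in |F| in practice and is additionally capped at the candidate
count. Estimation requires at least k0 pairs with positive pi2_raw; in
cohorts without enough full siblings the caller must supply a fixed α
(the estimate would be anchored on non-siblings and unreliable).

A closed-form check on the expected α: switch errors arrive per
individual as a Poisson process at rate λ per cM, so a haplotype match
between two individuals is cut at rate 2λ; the length-weighted fraction
of an (infinitely long) segment surviving in pieces ≥ S cM is
`e^(−2λS)(1 + 2λS)`. At 3 switches per 20 cM and S = 5 this gives 0.56,
independent of genome size; the sibling-anchored estimator recovers a
value a few hundredths above it (≈ 0.60–0.61 at the default study
conditions) because detected segments extend by chance past their true
endpoints — each end continues through ~ρ/(1−ρ) extra windows of
identity-by-state agreement, a relative gain that is largest for the
short pieces produced by frequent switches. Genotyping errors enter the same way through the per-window
mismatch rate. Within an IBD2 region a switch merely swaps the two
pairings (matches continue crossed), so IBD2 coverage is thinned by
approximately the same factor as IBD1 and `pi2_adj` remains a usable
sibling discriminant under phasing errors; genotyping errors, which hit
the four haplotypes independently, erode IBD2 faster than α corrects.

Degrees follow the standard kinship decision boundaries: degree-d
relatives (expected φ = 2^−(d+1)) are called for adjusted φ in
(2^−(d+1.5), 2^−(d+0.5)], d = 0 (MZ) … 4, below 2^−5.5 unrelated.
Boundaries are lower-exclusive/upper-inclusive; values above the MZ
upper bound (possible after adjustment) map to MZ. Within 1st degree,
full siblings require adjusted π2 ≥ 0.1, parent–offspring otherwise.
Background IBD is assumed zero, which the LD-free synthetic founders
satisfy by construction. π0 = 1 − (IBD1+IBD2)/G is exposed as a derived
field but unused by the classifier.

## The synthetic benchmark

Founders are frequency-sampled: per site an alternate-allele frequency
uniform in [0.05, 0.5], haplotypes drawn independently per site — no
linkage disequilibrium, no background relatedness. Multi-population
scenarios draw population-specific frequencies from a Balding–Nichols
Beta around shared ancestral frequencies with divergence `fst`, with an
optional admixed fraction whose two haplotypes come from different
populations. Each later generation holds the population size constant:
non-overlapping couples by seeded shuffle, children per couple =
size/couples, sexes alternating deterministically; with probability 0.2
a child's father is replaced by a random other male of the same
generation (the biological father is recorded). Gametes recombine with
a Poisson number of crossovers per chromosome, mean = length/50 cM,
breakpoints uniform in cM, starting haplotype by fair coin. Genotyping
errors flip each allele independently; switch errors arrive per
individual per chromosome as a Poisson process (rate per 20 cM
configurable) and swap the haplotypes from each point onward, leaving
site-wise genotypes unchanged. Defaults mirror the benchmark design:
1000 founders, population 1000, 500 couples, six generations with the
last four genotyped.

Every transmitted haplotype carries its founder-ancestry track
(piecewise founder-haplotype labels), giving an exact truth-IBD oracle;
the test suite checks that track-equal intervals are allele-identical.
Truth degrees are labelled *structurally* — the closest pedigree
relationship, computed as the minimum total meioses over shared
ancestors, minus one when the minimum is achieved by a mated ancestor
couple; parent–offspring, full siblings and direct-line ancestors are
resolved explicitly, and 5th degree or more distant counts as
unrelated. For simple relationships this is identical to mapping
pedigree kinship through the decision intervals; for compound relatives
(e.g. half siblings whose mothers are cousins) it matches how
relationships are extracted from pedigree records, whereas
kinship-interval mapping would shift them one class up. Under this
convention second cousins (kinship 2^−6) are 5th degree, i.e. truth
unrelated — the convention the decision boundaries themselves imply.

Two genome configurations are used deliberately:

* the compact default — 3 chromosomes of 150/120/100 cM, 5000 evenly
  spaced markers each — for everything that depends on *means*:
  per-class kinship recovery, α estimation, α monotonicity. These are
  insensitive to genome length (the α geometry is scale-free in λ·S).
* the 22-chromosome human-autosome genetic lengths (~3540 cM) for
  everything that depends on *classification accuracy*. Realized
  kinship varies around its expectation with a standard deviation
  scaling as (genome length)^−1/2; on 370 cM a grandparent-type pair has
  sd ≈ 0.04 — as wide as the decision bands themselves — so degree
  classes overlap regardless of detector quality, while on the full
  autosome set they separate as in real data.

Cohort sizes in the test suite are scaled (population 400 on the
compact genome, 200 on the autosome genome; ≥ 100 pairs per degree
class, ≥ 250 full-sibling pairs) to keep the suite desk-sized; the
acceptance script runs the full 1000-population default.

What passing does not show: the founders carry no LD, so the empirical
false-positive behaviour of the detector is cleaner than on real
haplotypes (where IBS runs from LD require the minimum-length cutoff to
do real work); phasing errors are injected as ideal Poisson switch
processes rather than the spatially heterogeneous errors of real
phasers; marker density is uniform; and there is no genotype
missingness, which the pipeline rejects rather than imputes.

## Numerical choices and edge cases

* Site indices are 0-based; IBD intervals half-open `[start, end)`;
  cM lengths are `cm[end−1] − cm[start]` style differences on the
  extended window boundaries.
* Interval merging uses exact zero-gap adjacency; the final ≥ S filter
  allows a 1e−9 slack for floating-point window arithmetic.
* Marker thinning is systematic (every k-th site) by default for
  reproducible density experiments; a seeded random mode exists.
* Sites with identical cM positions (map plateaus) share a window.
* Genetic-map interpolation is piecewise linear and clamps beyond the
  terminal anchors.
* Missing or unphased genotypes are hard errors in strict mode (the
  pipeline assumes complete phased arrays); a skip mode drops records.
* estimate_alpha clamps α into (0, 1]; division by α can push adjusted
  values above 0.5, which classify_degree maps to MZ.
* Per-run projection seeds are `seed + run_index`; all pipeline
  randomness descends from one master seed, and a fixed seed gives
  byte-identical outputs.

## Known limitations

Degrees beyond 4th are out of scope (the 5 cM cutoff leaves many such
pairs without any detectable segment). Inbreeding and background IBD
are not corrected for; the classifier reuses theoretical boundaries.
Second-degree subtypes (half-sib vs grandparental vs avuncular) are not
discriminated. The simulator's mating model implements only the printed
rules (non-overlapping couples, 0.2 extra-pair rate, constant
population); it does not model assortative mating, migration,
overlapping generations, or sex chromosomes.
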