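# Methods

This note records the models implemented in `sweepset`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Haplotype sweep statistics

iHS and nSL detect incomplete selective sweeps from the unusual length of
haplotypes carrying a derived allele. For a core SNP, EHH at a flanking
site is the fraction of pairs of carrier haplotypes identical over the
whole interval between the core and that site; it starts at 1 and is
non-increasing outward. The implementation tracks pair identity by
refining a partition of the carriers (two carriers stay in one group while
identical), which is exact and O(carriers) per flanking site; tests verify
it against direct pair enumeration.

- **iHS** = ln(iHH_ancestral / iHH_derived), where iHH is the trapezoidal
  integral of the EHH curve over genetic-map distance (cM), summed over
  both sides. Integration proceeds outward from EHH = 1 at the core and
  stops after the segment on which EHH first drops below the truncation
  floor (0.05 by default; that crossing segment is included). If either
  allele's curve reaches the edge of the data still at/above the floor,
  the site is scored missing rather than extrapolated, avoiding edge bias.
  Negative iHS means unusually long derived-allele haplotypes — the
  signature of an ongoing sweep on the derived allele.
- **nSL** replaces map distance with the number of segregating sites: the
  statistic is ln of the ratio of mean pairwise identity-tract lengths
  (ancestral over derived), tracts truncated at the data edges. It needs
  no genetic map and is more robust to local recombination-rate variation.
- **Standardization**: raw values are z-scored within derived-allele
  frequency bins (50 equal-width bins over (0,1) by default, population
  standard deviation), because expected haplotype length depends strongly
  on allele frequency. Sites with minor-allele frequency below 0.05 are
  not scored. Both the floor, the MAF cutoff and the bin count follow
  common practice for these statistics and are configurable.

## Gene windows, ranking, and the enrichment score

Genes are represented by the midpoint between their most upstream
transcript start and most downstream transcript stop; windows of 50, 100,
200, 500 and 1000 kb centered there capture sweeps of different footprint
sizes. A gene's signal per stratum (statistic x window size x population)
is the mean of |standardized score| over the window's SNPs; windows with
fewer than 10 scored SNPs (configurable) are treated as missing, and genes
missing in any stratum are dropped from the whole analysis so every
stratum ranks the same gene universe. Ranks are assigned descending by
signal with lexicographic gene-id tie-breaks, making ranking independent
of input order.

Enrichment is evaluated along a whole curve of rank thresholds (top 5000
down to top 10, 31 values): D_t counts focal genes in the top t, C_t is
the mean count over bootstrap control sets (a control gene drawn twice
counts twice). The summary score sums D_t − C_t over thresholds and
strata. An algebraically identical form weights each gene's first
appearance by n+1−t (strong sweep signals count in every threshold below
them); both forms are computed from exact integer count totals — C_t kept
as the rational total/n_sets — and must agree bit-for-bit, which the code
asserts on every call. The 95% interval shown on curves is the 2.5–97.5
percentile of D_t / C_t^(set) across control sets; it is descriptive and
plays no role in significance.

## Confounder matching

Focal genes differ from the genome background in expression, constraint,
recombination and more; any of these could change sweep prevalence by
itself. Control sets are therefore built to match the focal set's
*averages* on every confounder simultaneously: a set starts as a uniform
with-replacement sample of eligible non-focal genes of size |focal|, and a
stochastic greedy search swaps members for random pool genes, accepting
only swaps that reduce the worst per-factor relative deviation
|mean_c − mean_f| / (|mean_f| + 1e-9), until all factors are within the
tolerance (0.05 relative by default; binary factors are matched as
proportions by the same machinery). Sampling with replacement is essential
because the eligible pool — non-focal genes at least 300 kb from every
focal gene, so one sweep cannot cover both a focal gene and its control —
is typically barely larger than the focal set. Set-mean matching (rather
than one-to-one gene matching) keeps the pool usable; the residual
statistical cost of a small pool is exactly what the block-randomized
null absorbs.

## Block-randomized genomes and the false positive risk

Sweep signals are spatially autocorrelated: one sweep can cover several
neighboring genes, so gene-label permutations would be anti-conservative.
The null therefore shuffles *blocks* of consecutive analyzed genes (the
focal set plus the eligible pool, in genomic order). Two consecutive
analyzed genes belong to the same cluster when their largest analysis
windows overlap (center distance < the largest window size) — the most
conservative operational reading of "genes in the same putative sweep" —
and block boundaries never split a cluster. Blocks grow to a target size
in genes (20 by default at full scale; 3 at the desk scale used in the
tests, keeping the number of shuffleable blocks near a hundred);
chromosome ends always close a block. A shuffle permutes block order
uniformly and reassigns the positional sequence of per-gene rank tuples
(all strata at once) to the genes in their new order: each gene keeps its
label and confounders and acquires the ranks of the position it lands on,
so the multiset of rank tuples and their within-block adjacency are
preserved, and the bootstrap control sets are reused, not rebuilt.

The FPR of an observed score is (k+1)/(n+1), with k the number of
randomized genomes whose score is ≥ the observed one for an enrichment
(≤ for a deficit); the add-one form never returns 0 and matches reporting
conventions like "FPR < 1/n". The side must be stated — the hypotheses
are one-sided. Calibration is verified empirically: on synthetic genomes
with no focal/sweep association the FPR is uniform on (0, 1].

## Wright-Fisher engines

**Single locus.** Each attempt introduces one copy of an allele with
genotype fitnesses 1 : 1+hs : 1+s (h = 0.5 throughout, "co-dominant") into
a diploid population of the size at the introduction time, and evolves it
by binomial sampling of 2N gametes from the post-selection allele
frequency until loss or fixation; attempts are vectorized in batches.
With no linked variation, the pre-introduction history is irrelevant to
this locus, so the bottleneck demography reduces to "N = 1000 at
introduction". The engine matches an exact Markov-chain computation and an
independently coded Kimura diffusion oracle (fixation probability
(1−e^{−s})/(1−e^{−2Ns}) for a single copy, and the conditional
sojourn-time integral) within Monte-Carlo error.

**Linked region.** The interference experiment simulates a 1 Mb region in
which 8% of background sites and 10–40% of a central 100 kb gene-like core
are constrained (can receive deleterious mutations), with recombination at
0.1 cM/Mb (deliberately low, one tenth of the human average, to maximize
interference). Deleterious mutations arrive as a Poisson process at
1.25e-8 per constrained site per generation (the human point-estimate
mutation rate; configurable), drawing s uniformly from the four-point set
{−0.002, −0.02, −0.1, −0.5} (a flat-across-orders-of-magnitude DFE) with
dominance h = 0 (recessive) or h = 1 (dominant). Fitness is multiplicative
across loci; haplotypes are rows of a byte matrix with one column per
segregating mutation, and the per-generation kernel (fitness, alias-table
fitness-weighted parent sampling, gamete copying with Poisson crossovers,
recurrent mutation) is numba-compiled, with fixed and lost columns
compacted every four generations (a lost column is all zeros; a fixed
deleterious column rescales every individual's fitness equally, so
neither affects the interim dynamics). After a burn-in of 2N generations
(deleterious variation equilibrates faster than neutral), the bottleneck
(if any) drops N ten-fold; the advantageous mutation is introduced 500
generations later on a random haplotype at the region center, and the
population state at the introduction generation is checkpointed and
restored on every rewind, so all attempts within a replicate face the
same standing deleterious background. Fixation probability is fixations
per attempt; fixation time is averaged over fixing attempts.

**Desk-scale interference configuration.** The with-deleterious contrasts
are expensive at full scale, so the packaged experiments run a coherently
scaled version: N and the region are both reduced ten-fold (N0 = 1000,
bottleneck to 100, 100 kb region with a 10 kb core, burn-in 10N) while
every per-meiosis quantity is preserved — the deleterious input per gamete
per generation (per-site rate 1.25e-7 against the ten-fold smaller
constrained target) and the total map length (1 cM/Mb over 100 kb). All
population-scaled intensities (2Ns, 2NU, 2Nr) then shrink uniformly
ten-fold, which compresses effect magnitudes but preserves their
direction and ordering; s_adv = 0.01 (one of the study's two values)
keeps 2Ns = 20 well inside the selected regime at the smaller N. The
scaled checks are therefore directional: recessive backgrounds increase
fixation time, more under constant size than after the bottleneck, and
increasingly with the constrained fraction; dominant backgrounds do not.

A note on the published baselines: the s = 0.005 no-deleterious cells
agree with our engine and with diffusion theory within Monte-Carlo error,
while the published s = 0.01 fixation times sit ~7% above the value that
the exact Markov chain, the diffusion integral and this simulator jointly
give; the corresponding agreement tests report that discrepancy rather
than hiding it.

## Synthetic genome generator

The generator emulates the *analyzed* gene universe of a sweep-enrichment
study — genes with complete sweep and confounder data — not a raw
annotation file:

- genes placed by a Poisson process with 450 kb mean spacing (the real
  analyzed-gene spacing, ~3 Gb over ~6500 genes) on several chromosomes,
  with lognormal span lengths;
- a focal fraction of 0.3, approximating the real analyzed focal/control
  balance, with geometric disease-variant counts at focal genes (roughly
  half carrying five or more, matching the subset split);
- confounders with disease-gene-like mean shifts of at most 0.3 sd
  (higher expression and conserved density, lower pN, equal pS, slightly
  lower recombination and background-selection B), on realistic scales so
  relative-tolerance matching behaves as it does on real data;
- a sweep-signal continuum: ~1.2 localized score elevations per gene with
  heavy-tailed amplitudes (0.25 + Exp(0.6) in |z| units above a folded
  normal baseline of 0.8), elevating every gene whose window covers the
  sweep center — mirroring the fact that real rank thresholds down to the
  top quarter of genes still carry signal, and producing the spatial
  clustering the block null must respect;
- an injectable deficit: with focal_deficit = d < 1, a candidate sweep
  position within a focal gene's largest window is kept with probability d
  and redrawn otherwise, so focal windows receive proportionally fewer
  sweeps; d = 1 makes placement exactly independent of labels (a true
  null).

What the generator does *not* emulate: linkage-disequilibrium structure
within windows (scores are generated at the gene-window level, not from
haplotypes), realistic confounder-confounder correlations, correlation
between confounders and sweep occurrence (so matching is exercised, but
its causal necessity is not), or human demography. Consequently, passing
the calibration and recovery experiments shows the *statistical machinery*
is sound — calibrated null, recoverable injected signal, honored matching
contract — not that any particular real gene set has a sweep deficit.
Haplotype-level test data come separately from an msprime coalescent
backend (neutral, or with a partial genic sweep) and exercise the iHS/nSL
implementations on realistic LD.

## Reduced problem sizes used by the packaged experiments

The packaged tests and the acceptance script choose sizes that keep each
experiment to minutes: single-locus baselines use 100,000–200,000 attempts
(≥ 300–1000 fixations per cell); the calibration experiment runs 200
pipeline replicates on 500-gene genomes at 200 randomizations each; the
recovery experiment 50 replicates on 800-gene genomes at 500
randomizations (at 500 genes a two-fold deficit is recovered in only about
nine replicates out of ten — the block-shuffle noise of a single small
genome is comparable to the injected signal — while 800 genes leave a
clear margin); the interference contrasts use ≥ 200 fixations per cell
averaged over 25 independent deleterious backgrounds, sampled as snapshots
every 2000 generations of one equilibrated chain, because which
deleterious variants happen to segregate near the selected site at
introduction is the dominant source of between-replicate variance.
Full-scale runs (20,000+ genes, thousands of randomized genomes, 1 Mb
regions at N = 10,000) use the same code paths with larger configuration
values.

## Known limitations

- iHS/nSL sites whose EHH does not reach the floor before the data edge
  are dropped rather than extrapolated; near chromosome ends this loses
  sites.
- The matching search is stochastic-greedy; it satisfies the declared
  set-mean contract but is not guaranteed to find a feasible set when one
  barely exists, and it reports the offending factors when it gives up.
- The region simulator models a single linked region; unlinked background
  selection elsewhere in the genome is intentionally out of scope (it
  cannot affect a single selected locus's trajectory).
- Cluster definition for the block null (largest-window overlap of
  consecutive analyzed genes) is the conservative end of the plausible
  range; finer cluster rules would shuffle more finely and gain power.
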