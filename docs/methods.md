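# Methods

`sweeplab` re-implements, against synthetic data, the statistical pipeline
used to find and verify a Cry1Ac-selection signature in a pair of
laboratory *Helicoverpa zea* lines: an unselected line (GA) and a
Cry1Ac-selected line (GA-R), both descended from one field collection.
This note records the models, parameter choices, numerical conventions,
and the limits of what the synthetic experiments demonstrate.

## The breeding-program simulator (`simkit`)

The generator is a discrete-generation, two-line forward Wright-Fisher
model on a single 40-kb window:

* **Founders.** 180 diploid founders carry standing variation drawn from a
  neutral coalescent (msprime) with infinite-sites mutation.
  `theta_per_window = 120` (locus-wide, unitless 4Nμ·L) was calibrated
  once so that the post-filter SNP density of a simulated sample matches
  the genome-wide density of the study (≈ 237 SNPs per 40-kb window,
  i.e. 1,986,042 SNPs over 335.5 Mb). `founder_rho = 400` (locus-wide
  4Nr·L) gives founder haplotypes the fine-scale mosaic structure expected
  of a sample from a large wild insect population; at r ≈ 3×10⁻⁸ per bp
  per generation this corresponds to a wild effective size of ~8×10⁴ — a
  deliberately conservative lower bound, chosen because realistic sizes
  (~10⁶, rho ~ 5×10³) make coalescent simulation two orders of magnitude
  slower while barely changing the statistic of interest once the window
  contains many quasi-independent genealogies. With `founder_rho = 0`
  the whole window shares one genealogy and the window F_ST behaves like
  a single locus, with a far heavier neutral tail; this sensitivity is
  the reason the null (below) depends on treating standing variation as
  recombinant.
* **Generations.** One shared clock: GA runs 72 generations at a census
  of 600; GA-R is split off at generation 2, runs 52 generations of its
  own (terminal shared-clock generation 54), and is re-founded at
  generation 27 by a 50:50 cross of GA-R and contemporaneous GA parents.
  The published generation counts (F52/F72, a 2012 backcross, ~11
  generations/year from 2008) cannot all be honored simultaneously; the
  defaults keep the sampled generation numbers and place the backcross at
  the midpoint of the selected line's span. Within-line subsetting and
  periodic subset crossing is approximated by one panmictic deme per line.
* **Reproduction.** Random mating with selfing allowed (each gamete draws
  an independent parent), per-bp crossover rate 3×10⁻⁸ during breeding,
  no new mutation. Internally each chromosome carries a founder-haplotype
  label; recombinant gametes get fresh labels referencing their parents
  plus breakpoints, and sequences are resolved only for sampled
  individuals. This is an exact implementation of the model, not an
  approximation, and makes 10,000-replicate nulls tractable.
* **Selection.** Episodic viability selection at one target site
  (fitnesses 1, 1+hs, 1+s), applied to GA-R only. The default schedule
  helper spreads 19 episodes before the backcross and 32 after, matching
  the experiment's 9+10 and 7+25 selection rounds. The selected allele
  defaults to rare standing variation (founder frequency 0.002-0.008,
  i.e. 2-3 copies among 360 founder chromosomes): the study's signature —
  a ~40-kb window nearly emptied of variation — is that of a hard sweep,
  which requires the beneficial haplotype to be (nearly) unique at
  founding. Commoner standing variants produce soft sweeps that leave
  most window diversity in place.
* **Sampling.** 5 diploids per line at the terminal generations,
  matching the study's sequencing design; emitted as VCF 4.2 with
  Poisson-distributed per-genotype depth (mean 16, the study's mean
  coverage).

## Variant filters (`vcfio`)

Per-genotype depth masking (DP < 5 or DP > 2.5 × mean genome-wide depth;
the mean is taken over all non-missing DP in the input, or pinned by the
caller), then ≥ 50% called genotypes per site, biallelic-only, pooled
minor-allele frequency strictly > 0.1, in that order, with per-criterion
removal counts. Positional thinning keeps one SNP per 5 kb greedily per
contig. Depth masking is per genotype (the behavior of the tooling the
filters emulate), so the call-fraction test runs after masking.

## Diversity summaries (`popdiv`)

P_N, mean MAF, H_O, H_E (with Nei's 2n/(2n−1) small-sample correction),
F_IS = 1 − mean(H_O)/mean(H_E) computed from means over sites (avoiding
per-site ratios at low-diversity sites), and mean pairwise Nei (1972)
standard distance between individuals (each individual a two-allele
"population"; infinite distances capped at 10). Confidence intervals are
BCa bootstrap over loci (scipy), 1,000 resamples by default.

## The sweep scan (`sweepscan`)

Pooled heterozygosity per 40-kb window (20-kb step) for the selected
line, `Hp = 2 ΣnMAJ ΣnMIN / (ΣnMAJ + ΣnMIN)²`; the denominator is the
squared *sum* of the two count totals — the only reading under which
Hp ≤ 0.5. Windows with fewer than 10 SNPs are excluded (absent, not
zero). Window F_ST is Weir & Cockerham's (1984) two-population theta,
ratio-of-sums across SNPs by default (`mean` mode averages per-SNP
estimates). Both statistics are Z-standardized across all included
windows. A count-based binomial likelihood-ratio test on a 5-kb/1-kb
grid stands in for the genotype-likelihood divergence test of the
original pipeline; at the study's 5+5 sampling its chi-square p-values
are anticonservative (the asymptotics need larger samples — its test
calibration therefore runs at 25 diploids per line), which is acceptable
in its screening role behind BH-FDR correction. Candidates are windows
with ZHp < −6, ZF_ST > 1.1 and ≥ 1 overlapping fine-grid window with
q < 0.05; flagged windows within one step merge.

## The neutral null (`neutralnull`)

Each replicate simulates the full neutral demography over one 40-kb
window, samples 5+5 diploids, applies the scan's pooled MAF > 0.1 filter,
and computes the weighted window F_ST; the tail probability at the
observed threshold (0.44) is reported with an exact binomial 95% CI.
The sensitivity grid reruns this with founder collections of 180/90/45
and censuses of 300/150. Tail counts depend materially on the founder
recombination assumption (see above) and on the unrecoverable details of
the original simulation setup; the package reports its own Monte-Carlo
counts with CIs rather than asserting the published ones.

## Amplicon statistics (`seqdiv`)

θ_W is per locus (S/a₁, matching the published table's convention:
20 SNPs over 48 chromosomes → 4.5), π per site (mean pairwise proportion
of differences, pairwise deletion). S, θ_W and Tajima's D use complete
deletion of gap columns. D's p-value uses Tajima's bounded-beta
approximation (a normal option exists). The π permutation test shuffles
line labels over pooled sequences, two-sided, with the add-one
correction; π of a subset is a mean of fixed per-pair difference
proportions, so the pairwise matrix is precomputed once.

## Protein variants (`protvar`)

Two consensus haplotype CDSs per individual are translated (standard
code; stop renders '*' and halts translation; ambiguous codons → 'X'),
collapsed into variants named by descending pooled chromosome count, and
described against the reference protein via global alignment:
substitutions in reference coordinates (e.g. T1706K), in-frame indels
with their residue strings (e.g. the DNTAT loss), and truncations at a
premature stop. The between-line test is a two-sided exact r×c Fisher
test (sum of probabilities of all margin-constrained tables no more
probable than the observed one, tolerance 1e-9), with a closed-form
hypergeometric 2×2 path and a Monte-Carlo fallback (Patefield sampling,
10⁶ draws) beyond 10⁷ enumerable states.

## Protein phylogeny (`protphylo`)

Pairwise ML distances under WAG (embedded published exchangeabilities and
frequencies; rate matrix normalized to one expected substitution per unit
time; eigendecomposition precomputed; bounded scalar optimization on
[10⁻⁶, 10]); pairwise deletion of gaps. Gamma rate heterogeneity is
omitted. Neighbor joining is the canonical Q-criterion algorithm with a
deterministic lexicographic tie-break and negative branch lengths clamped
to zero. Bootstrap supports resample columns and count, per internal
bipartition of the full-alignment tree, the fraction of replicate trees
containing it.

## Expression (`qpcr`)

Replicate Cts are averaged per (sample, gene); ΔCt = Ct_target −
Ct_reference; ΔΔCt subtracts the calibrator line's mean ΔCt; fold =
2^−ΔΔCt without efficiency correction. Because "the line's fold change"
is ambiguous, both the fold of line-mean ΔCt and the mean of per-sample
folds are reported. The Mann-Whitney comparison is exact for ≤ 8
observations per group without ties, otherwise tie-corrected normal.

## The demonstration pipeline (`pipeline`)

`run_demo` simulates a multi-contig genome as independent 40-kb loci
under the shared demography (inter-locus linkage and the shared pedigree
across loci are not represented — the marginal window-statistic
distributions, which the scan consumes, are unaffected), plants one
sweep, writes VCF/GFF3/line-map files, and runs
filter → diversity → scan → null → annotation. The planted locus is
re-simulated (fresh seeds, up to 50 tries) until the selected allele
reaches frequency 0.95 in the selected line: the emulated experiment is
conditioned on resistance having evolved, as the real one was. Neutral
mode (`--no-sweep`) plants nothing and should yield no candidates.

## Problem sizes used by the test suite

The suite favors many small replicates over few large ones: founder
expectations use 600 coalescent replicates; drift checks use censuses of
20-25 over 10-300 generations with 1,000-1,500 replicates; the scaled
neutral-null ordering check uses 1,000 replicates per census; recovery
and specificity each use four demo replicates on 5-contig × 0.8-Mb
genomes; permutation-uniformity uses 250 datasets at 199 permutations.
The acceptance script runs the full 10,000-replicate null at 25% census.

## Known limitations

* Single panmictic deme per line; no subset structure, no sex.
* No new mutation during breeding; all terminal variation is standing.
* The fine-grid divergence test is count-based, not
  genotype-likelihood-based, and is anticonservative at 5+5 sampling.
* Independent-locus genome assembly understates long-range correlation
  of window statistics along a real chromosome.
* The neutral-null tail counts are calibration-dependent (founder rho
  and theta); treat them as order-of-magnitude statements with their CIs.
* Real-data percent-identity regimes (e.g. highly divergent cadherin
  families) are represented only by synthetic analogues.
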