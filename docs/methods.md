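# Methods

## Scan statistics

**Nucleotide diversity.** Per site and population, π is the unbiased
pairwise heterozygosity 2·c_ref·c_alt / (c·(c−1)) over the c called
alleles (missing genotypes excluded; sites with c < 2 contribute 0).
Window π sums site values and divides by the window span in bp.
Normalizing by span rather than by callable sites is the convention
for π computed from a VCF, where invariant-site callability is
unknown; per-variant normalization is available
(`window_pi(..., per_variant=True)`) and the π-ratio is invariant to
any normalization shared by the two populations. Watterson's θ_W per
window is S/(a_n·span) with S the segregating-site count in the
population and a_n the harmonic number for the window's median called
allele count (missingness makes the allele count vary site-to-site;
the median is a stable summary).

**F_ST.** The default estimator is Weir–Cockerham variance components
for two populations: per site, a (among populations), b (among
individuals within populations) and c (within individuals) are
computed from sample sizes, allele frequencies and observed
heterozygosities; windows combine sites as the ratio of sums
Σa/Σ(a+b+c). Ratio-of-averages is the form the estimator's authors
prescribe; the mean of per-site ratios is noticeably biased (≈0.068
at a true F of 0.1 in our calibration cohorts, versus ≈0.10 for the
ratio of sums), so all reported "genome-mean" or per-window values
are ratios of sums. Negative per-window values are retained, not
clamped — clamping would distort the empirical quantile used for
thresholding. A Hudson-type alternative (numerator
(p₁−p₂)² − unbiased within-population terms, denominator the
between-population heterozygosity) is selectable; it is less sensitive
to unequal sample sizes and agrees with Weir–Cockerham within 0.02 on
balanced cohorts, which the tests assert. Sites need at least one
fully called diploid per population; others are skipped.

**Window grid.** Windows are 0-based half-open [k·step, k·step+size)
while they fit the chromosome; one trailing partial window is kept if
its span is at least half a window, flagged `partial`, and excluded
from thresholding by default. A site at 1-based position pos belongs
to a window iff start ≤ pos−1 < end. Windows with fewer than
`min_snvs` SNVs (default 10) are invalid: they never enter the
threshold distribution and are never selected. The default floor
guards the π-ratio against near-empty windows; the simulated cohorts
average ~70 SNVs per window.

**Joint selection.** Thresholds are nearest-rank upper quantiles:
sort descending, take the value at rank ⌈q·N⌉ (q = 0.01 by default),
select value ≥ threshold. With distinct values this is literally the
best ⌈q·N⌉ windows; ties beyond the rank are included (conservative)
and +∞ π-ratios sort above all finite values. A window is a candidate
only when it passes both the F_ST and the π-ratio threshold.
Overlapping or book-ended candidate windows merge into maximal runs;
region statistics are maxima over members. Merging is the default
(the CLI offers `--no-merge`); gene overlap is any-overlap (≥1 bp) on
transcript spans with a full-containment flag.

## Site filters and LD

The scan filter retains sites with call rate ≥ 0.90, pooled MAF ≥ 0.05
and missing fraction ≤ 0.20; the structure filter retains MAF ≥ 0.05,
missing fraction ≤ 0.05 and QUAL ≥ 30 (skipped with a warning when
QUAL is absent). Filters are stated as exclusion rules, so boundary
values are kept. MAF is pooled across populations. Call-rate and
missing-fraction criteria are partially redundant but exposed
separately so either can be tightened.

LD pruning follows plink's `--indep-pairwise`: per chromosome, within
each window of `window_snps` sites advancing by `step_snps`, while any
retained pair has r² above the threshold, the lower-MAF member of the
worst pair is dropped (ties → later position). r² is the squared
Pearson correlation of dosages — composite LD, the right quantity when
only genotypes are available. For pruning, missing dosages are
mean-imputed before correlation (vectorizable and adequate at the ≤5%
missingness the structure filter guarantees); the LD-decay curve, whose
values are themselves the result, computes each pair over co-called
samples exactly, in 500-bp bins up to 300 kb by default. The pipeline
thins the LD-decay input to at most 20,000 evenly spaced sites
(configurable) to bound the pair enumeration.

## Functional annotation

One category per variant with precedence
coding > splicing > UTR5 > UTR3 > intron > upstream > downstream >
intergenic (within coding, non-synonymous ranks above synonymous when
a variant touches two genes and the more severe call is kept; multi-
gene hits are counted and logged). Splicing means an intronic position
within 2 bp of an exon boundary; flanks are 1 kb up/downstream,
strand-aware. These distances follow the conventions of the standard
gene-based annotators and are configurable. Coding variants are
translated with the standard codon table on the coding strand
(reverse-complement for − strand); a variant REF disagreeing with the
reference sequence raises an error naming the site, and genes whose
CDS length is not a multiple of 3 are skipped with a warning. UTRs are
derived from exons minus the CDS span when reading GFF3, which
tolerates files without explicit UTR features; the first transcript
per gene is used.

## Synthetic cohorts

The generator emulates the frequency structure a two-population scan
actually measures, not the coalescent process that produces it:

- Ancestral frequencies follow the neutral spectrum P(i) ∝ 1/i over a
  notional pool of 100 alleles, truncated to [0.02, 0.98].
- Each population draws site frequencies from Balding–Nichols
  Beta(p(1−F)/F, (1−p)(1−F)/F). E[F_ST] = F, giving the scan a
  closed-form calibration target (tests assert recovery of F = 0.1
  within ±0.02 at 50k sites).
- Inside sweep intervals the domestic population uses `sweep_F` and
  its frequency q is moved to q′ on the same side of ½ with
  q′(1−q′) = scale·q(1−q), so expected heterozygosity shrinks exactly
  by `sweep_diversity_scale`. Truth intervals are exact, which is what
  recovery scoring needs; this is a frequency-deterministic sweep
  model, not a hitchhiking simulation.
- Genotypes are two binomial draws per diploid; missingness is i.i.d.
  Bernoulli; REF/ALT pairs are transitions with probability
  t/(t+1) for a target Ts/Tv of t (default 2.29, the genome-wide
  mammalian value).

Default study conditions, chosen once as the regime the scan is meant
for: 20 domestic + 13 wild diploids; five 30-Mb chromosomes (150 Mb);
105,000 sites ≈ 0.7 SNVs/kb ≈ 70 SNVs per 100-kb window; background
F = 0.05; five 300-kb sweeps (one per chromosome) with sweep_F = 0.6
and diversity scale 0.1; missing rate 0.02. The planted sweeps total
1.5 Mb = 1% of the genome, matching the capacity of a top-1% scan the
way real sweep fractions are small relative to a genome; a generator
whose truth occupied far more than q of the genome could not be fully
recovered by construction, which would measure the thresholding rule,
not the statistics. Synthetic gene models are single-transcript,
6-kb, three-exon genes tiled every 200 kb with alternating strands so
every annotation category and both codon orientations occur; CDS
totals 1800 bp per gene. The synthetic VCF writes QUAL 100 for all
sites, so the quality filter is exercised by hand-built fixtures in
the unit tests rather than by the simulator.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: within-population structure (each
population is panmictic), linkage between sites (sites are
independent given frequencies, so LD decay on synthetic data is flat
at the finite-sample floor), demographic history (bottlenecks,
migration, admixture), indels/structural variants, sequencing error
and genotype-quality variation, and soft or incomplete sweeps.

## Numerical conventions and tie-breaks

- Missing dosage is −1 in an int8 matrix; half-called VCF genotypes
  count as missing; multiallelic and non-SNV records are skipped with
  logged counts.
- π-ratio: x/0 → +∞ (kept; ranks above finite values), 0/0 → NaN
  (window invalid). Window F_ST with a zero denominator is NaN.
- Neighbor joining is the classic Saitou–Nei agglomeration; Q-ties are
  broken by lexicographic label order (a merged node inherits its
  smallest member label), negative branch estimates are clamped to 0
  with the deficit moved to the sibling edge (the PHYLIP-compatible
  behaviour), and the final three nodes use the three-point formulas,
  leaving an unrooted tree serialized with a trifurcating root.
- PCA standardizes each site by 2p̂ and √(2p̂(1−p̂)), mean-imputes
  missing entries (zero after centering), eigendecomposes the
  sample×sample covariance and fixes signs by making each component's
  first nonzero loading positive. Variance explained is λ_k/Σλ over
  all components.
- All simulation randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical configurations produce
  byte-identical VCFs and pipeline tables (asserted by the tests).
- Stage outputs are TSV/BED/JSON with fixed float formatting ("%.10g")
  so re-runs diff cleanly; the manifest records per-stage output
  checksums and wall times.

## Known limitations

- The sweep model plants frequency patterns, not haplotype
  signatures; haplotype-based statistics (iHS, XP-EHH) are out of
  scope and would see nothing in these cohorts.
- Windows overlap, so neighbouring window statistics are strongly
  correlated; the empirical-quantile selection makes no independence
  assumption, but region counts should not be read as independent
  discoveries.
- The Watterson θ windows use the median called allele count; under
  extreme, site-heterogeneous missingness a per-site a_n correction
  would be preferable.
- Gene overlap uses the first transcript per gene; multi-isoform
  resolution is not attempted.
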