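# Methods

This note documents the statistical model behind `cmiscan`, the
conventions and numerical choices the implementation commits to, what
the bundled simulator does and does not emulate, and the problem sizes
the test suite uses.

## Genotype representation

A biallelic SNP genotype is represented as the unordered base pair of
the two alleles, one of ten classes in the fixed canonical order

    AA, TT, GG, CC, AT, AG, AC, TG, TC, GC.

Heterozygote orientation is collapsed (0/1 and 1/0 are the same class;
{C,G} is always written GC).  Strand is ignored — the classes are
strandless by construction.  Positions are 1-based (as in VCF); gene
intervals are normalized to 0-based half-open on read (BED native;
GFF3 `start..end` becomes `[start−1, end)`).  SNP→gene distance is
measured between the 1-based site position and the half-open bounds:
0 when `start < pos <= end`, otherwise `start − pos` or `pos − end`;
ties go to the gene with the smaller start.

Missing genotypes are a hard error, not a warning: the entropy
estimates below are plug-in counts, which are ill-defined on partial
tables without an imputation model.  Imputation and phasing are
upstream concerns.  Multiallelic records and indels are dropped (and
counted), not decomposed: the ten-class scheme is defined on biallelic
SNPs only.

## The mutual information extractor

For population label *y* (exactly two populations) and genotype classes
*x₁*, *x₂* at two loci, all information measures use natural logarithms
(nats), plug-in cell probabilities, and the convention 0·log 0 = 0.
Ratios with zero denominators only arise in cells of zero joint count
and contribute 0.  The pair score is

    CI(y; x₁, x₂) = I(y; (x₁, x₂)),

the mutual information between the label and the composite two-locus
class.  The conditional form is implemented independently as the
explicit triple sum

    CI(y; x₁ | x₂) = Σ p(y,s₁,s₂) ln [ p(s₂) p(y,s₁,s₂) / ( p(y,s₂) p(s₁,s₂) ) ],

and the chain rule CI(y; x₁, x₂) = CI(y; x₁ | x₂) + CI(y; x₂) holds to
1e-12 by construction; the test suite asserts it on 1,000 random count
tables.  Tiny negative values from floating-point cancellation are
clamped at −1e-12 → 0.  No bias correction (Miller–Madow, shrinkage,
…) is applied: the flagging threshold below is only interpretable on
the raw plug-in scale.

**Why θ = 0.693.**  For a balanced two-population panel,
H(y) = ln 2 ≈ 0.693147 bounds every score, and a pair attains it iff
the composite genotype perfectly determines the population.  The
flagging threshold θ = 0.693 (closed comparison, score ≥ θ) therefore
selects exactly the perfect discriminators at the printed 3-decimal
precision; scores cannot fall strictly between 0.693 and ln 2, because
the smallest nonzero conditional entropy reachable with 10 + 10 counts
is ≈ 0.16 nats.

## Permutation significance

The null hypothesis is exchangeability of population labels against the
fixed genotype columns.  Monte-Carlo mode shuffles labels and reports
the add-one-corrected

    p = (1 + #{null score ≥ observed}) / (1 + n_perm),

a valid p-value whose smallest reachable value is 1/(1+n_perm).  Exact
mode enumerates all C(n, n_A) balanced label assignments (the observed
one included) and reports the tail fraction; it refuses beyond 200,000
assignments and directs the caller to Monte Carlo.  Default
n_perm = 9,999: flagging demands p < 10⁻³, and with the add-one
correction a single tying permutation at n_perm = 999 already pushes p
to exactly 10⁻³; 9,999 permutations tolerate up to 9 ties, which makes
the p-value of a genuinely perfect discriminator robust to the
~1.1 × 10⁻⁵ per-permutation probability of resampling the true
partition (2 / C(20,10)).

Calibration: on label-independent genotypes the rate of p ≤ 0.05 sits
inside the binomial 99% band around 0.05 over 500 replicates (asserted
in the test suite).  Permutation ties make the test mildly
conservative, which is inherent to permutation p-values on discrete
statistics.

## The genome scan

Adjacency means consecutive SNPs in coordinate order on the same
chromosome, with no physical-distance cap — the simplest reading of a
two-locus neighbourhood.  Each SNP belongs to at most two pairs; its
reported score is the **maximum** over those pairs with the partner
recorded, so per-SNP output preserves discriminative potential.  A
direct consequence: both members of a pair containing one perfect
discriminator score ln 2, so flagged sets always include the immediate
pair partners of truly discriminative loci.  Chromosome singletons
cannot be paired and are reported unscored with a warning count.

Permutation p-values are computed lazily, only for SNPs at or above θ —
sub-threshold SNPs are never flagged regardless of p and are reported
with p = 1.  No multiple-testing correction is applied by default (the
raw strict threshold p < 10⁻³ is the convention this scan follows); a
Bonferroni option over the number of pairs is exposed.

Descriptive summaries of the flagged set:

* **Genotype-class distribution** — per chromosome and population, each
  flagged SNP contributes that population's majority genotype class;
  ties break by the canonical class order.
* **Heterozygosity table** — over flagged loci (optionally restricted
  to a gene subset), the per-locus heterozygote count of each
  population is averaged three ways: overall, over loci where the
  *other* population is entirely homozygous, and over loci where the
  other population has ≥ 1 heterozygote.  An empty partition is
  reported as undefined (None), which is distinct from a mean of 0.
* **Genotype profile** — sites × 10-class counts for one population
  inside a gene interval; every row sums to the population size.
* **Mitochondrial summary** — flagged / total SNPs on the configured
  mito contig (default `MT`), percent to one decimal.

## Small-sample chance separation

With 10 + 10 samples, two label-independent background loci can have
*disjoint* composite genotype supports by chance, in which case the
pair genuinely attains ln 2 in that sample and is flagged.  Monte-Carlo
measurement (400,000 random pairs, allele frequencies uniform on
[0.05, 0.95], Hardy–Weinberg genotypes) puts this probability at
≈ 4 × 10⁻⁵ per adjacent pair.  This is a property of the statistic at
this sample size, not an artifact: any validation that expects a
*exactly* clean flagged set must size the experiment so the expected
number of chance separations is ≪ 1.  The planted-recovery test uses
20 replicate panels of 49 adjacent pairs (expected chance events
≈ 0.04); the null-calibration scan test tolerates flags in up to 5% of
replicates.

## XP-EHH

EHH here is flanking-haplotype homozygosity with both core alleles
pooled: walking outward from a core SNP, the n population haplotypes
are grouped by their allele vector over the sites strictly between the
core and the current site (current site included), and
EHH(d) = Σ_h C(c_h, 2) / C(n, 2) over the group sizes.  The curve
starts at exactly 1 at the core and is non-increasing (groups only
refine).  Distances are physical bp throughout — no genetic map is
assumed, since only VCF coordinates are available.

iHH is the trapezoid-rule integral of the EHH curve over distance,
summed over the two directions.  Integration stops at the *first
sampled point* whose EHH is below the truncation level (default 0.05),
*including* the trapezoid that reaches it; the crossing is not
interpolated — simpler and deterministic.  A curve that never falls
below the truncation before the chromosome end is integrated to its
end and sets an edge warning.  A core on the chromosome edge has a
length-1 curve in that direction and contributes zero area.

Per core, the raw score is ln(iHH_A / iHH_B); cores where either iHH
falls below `min_ihh` (default 10⁻³ bp, i.e. only degenerate areas) are
dropped, because the log-ratio of near-zero areas is unstable — a floor
rather than pseudocounts, to keep retained scores exact.  Raw scores
are z-normalized genome-wide to mean 0, variance 1 (population SD).
Positive extremes indicate unusually long haplotype homozygosity —
a sweep signature — in population A, negative in population B; the
top/bottom `quantile` (default 1%, `k = int(n·q)` per tail) are the
candidate sets, each annotatable to the nearest gene.  A degenerate
all-equal z distribution yields empty tails.  Candidate-set overlap
reports strip structural/small-RNA symbols (5S_rRNA, 7SK, U-RNAs,
snoRNAs, …; configurable pattern) before counting, and accept
externally produced XP-CLR candidate lists as optional inputs.

A per-site statistic on a regional signal: within a swept region iHH_A
is nearly constant (any site covered by the carriers' shared tracts
sees the same total shared extent), so the *peak* z localizes the
region rather than the selected site.  Validations that ask for the
core site itself in the extreme tail must therefore use panels where
the tail size 0.01·n exceeds the number of SNPs inside the sweep
region; the test suite uses 10 chromosomes × 1,000 SNPs at ~2 kb
spacing with a 100 kb sweep (~50 sweep sites vs. a tail of 100).

## Hypergeometric enrichment

The over-representation p-value is the exact upper tail
P(X ≥ k) = Σ_{j ≥ k} C(K,j) C(N−K,n−j) / C(N,n), evaluated in log
space via log-gamma and log-sum-exp; one-sided only.  The gene
universe N is a **required explicit input** — reported p-values are
meaningless without the background, so none is ever assumed.  Symbols
are matched case-insensitively after whitespace stripping; query and
catalog genes outside the universe are dropped with warnings.

## The simulator

The generator emulates the structure of a balanced two-breed
resequencing panel without coalescent machinery:

* **Panel**: 10 + 10 individuals by default (a typical two-breed
  comparison design); phased haplotypes throughout, written as a
  deterministic, byte-stable VCF.
* **Background**: per-site allele frequency uniform on [0.05, 0.95],
  shared by both populations; alleles drawn independently per
  haplotype copy (Hardy–Weinberg within populations, label-independent
  by construction).
* **Fixed differences**: one breed homozygous REF, the other
  homozygous ALT — exact ln 2 discriminators.
* **Breed-exclusive heterozygosity loci**: one breed entirely
  homozygous REF; each individual of the other breed heterozygous
  (probability 0.5, at least one forced) or homozygous ALT.  These are
  still perfect separators — so they are actually flagged by the scan —
  while carrying breed-private heterozygosity, which is what produces
  the characteristic conditional pattern: wherever one breed has any
  heterozygote, the other breed's mean heterozygote count is exactly 0.
* **Sweep**: a carrier fraction (default 0.9) of one population's
  haplotypes copy a single donor haplotype outward from a core
  position until per-carrier breakpoints; one-sided extents are
  uniform on [length/4, length/2], so every carrier shares at least
  the central half-window and the shared haplotype frays toward the
  edges like a sweep flank.  (A hard-edged shared segment was
  deliberately rejected: it makes iHH constant across the whole
  segment interior and the core unidentifiable even in principle.)
* **Mitochondrion**: a haploid contig (written as homozygous diploid
  calls) whose fixed differences form one contiguous block from the
  first mito SNP — on a non-recombining molecule, discriminative
  variants form a single linked haplogroup cluster.  A block of 7
  planted sites yields 8 flagged (block + one flanking partner) of 33,
  i.e. 24.2%.
* **Truth and annotation**: every planted locus is written to a truth
  TSV with its role, expected classes and heterozygote counts, and a
  synthetic gene (±500 bp tile, `SIMGENE_k`) is emitted per planted
  locus for annotation tests.

Planted autosomal loci are kept ≥ 3 SNP indices apart so each planted
locus's pair partners are background.  All randomness flows from the
single configured seed; identical configs produce byte-identical
output files.

**What the simulator does not emulate** — and hence what passing tests
do not certify about real data: background linkage disequilibrium
(every non-sweep locus is independent), recombination-map and
mutation-rate heterogeneity, demography and admixture, genotyping
error, imputation artifacts, and SNP ascertainment bias.  In
particular, because both populations' backgrounds are drawn
independently, the iHH denominator does not share locale effects with
the numerator the way real cross-population panels do; real-data
XP-EHH typically benefits from that cancellation.

## Problem sizes used by the test suite

Chosen as the package's validation design points: recovery — 20 panels
of 1 chromosome × 50 SNPs with 5 fixed differences; null calibration —
500 label-independent pairs at n_perm = 999, and 40 null scans of 150
SNPs; sweep — 10 panels of 10 chromosomes × 1,000 SNPs (2 kb spacing,
100 kb sweep, carrier fraction 0.9); identities — 1,000 random count
tables (chain rule) and 200 random 2×10×10 tables (triple-sum oracle);
enrichment — 10,000 resampling draws at N = 200, K = 50, n = 40.

## Known limitations

* Two populations only; k-locus extractors beyond pairs are out of
  scope, as are continuous covariates and estimator bias correction.
* The per-SNP max-over-pairs projection double-reports neighbours of
  perfect discriminators by design; consumers wanting pair-level output
  can reconstruct it from the partner column.
* XP-CLR is not implemented (an external tool's candidate lists are
  consumed for overlap reports only); iHS and F_ST are not provided.
* The scan's flagged *count* on real data depends on upstream variant
  calling, filtering and imputation choices that are outside this
  package.
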