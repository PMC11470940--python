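# Methods

baokit re-implements, as a reusable library, the downstream analyses used to
characterize a recently sequenced autotetraploid plant genome: ploidy
inference from allele balance, genome profiling from k-mer spectra, solo-LTR
dynamics, centromere/telomere repeat topography, Ks-based dating of
whole-genome multiplications (WGMs) with syntenic depth, and population
structure. Every stage is paired with a synthetic-data generator that plants
known truth, so the whole pipeline is testable end to end without any
external download. This note records the models, the defaults and why, and
what the synthetic data does and does not emulate.

## Synthetic data: what it emulates

Each generator draws from a single explicitly seeded `numpy` Generator (no
global state) and returns the dataset together with a `SimTruth` sidecar
holding every planted parameter its consuming module needs.

- **Allele depths** (`sim_allele_depths`): heterozygous biallelic sites of a
  sequenced individual of ploidy 2–4. Per site, the alternate-allele dosage
  g is drawn from 1..ploidy−1 (uniform by default — there is no canonical
  genotype-class proportion for a wild autotetraploid, and uniform weights
  make every dosage stratum testable), total depth from Poisson(mean depth,
  default 60×, a typical resequencing depth), and alternate reads from
  Binomial(depth, g/ploidy) perturbed by a base error rate (default 0.001).
  Not emulated: mapping bias, allele-specific error, linked sites.
- **K-mer spectra** (`sim_kmer_spectrum`): two haplotypes at a stated
  per-base heterozygosity; a tandem block of identical unit copies (default
  10) realizes the repeat fraction; exact canonical k-mer counting; observed
  depth per distinct k-mer Poisson at multiplicity × (depth/2); a declining
  low-depth error tail. Not emulated: sequencing errors inside real reads,
  GC bias, heterozygous structural variation.
- **TE annotations** (`sim_te_gff`): GFF3 in the dialect of
  homology+structural TE annotators (`Method=`, `Identity=`,
  `Classification=` attributes; intact elements as parent + two LTR children
  + internal child). Decoy solo candidates each violate exactly one of the
  six solo-LTR filters, with local geometry constructed so no second rule is
  touched.
- **Repeat sequences** (`sim_repeat_sequences`): tandem arrays (mutated
  monomer copies, optional higher-order pattern of divergent monomer
  variants) and telomere-bearing sequences (terminal motif tract; the two
  motif-lengths of flank next to the tract are forced to mismatch the
  periodic continuation so planted tract lengths are exact by construction).
- **Paralog CDS pairs** (`sim_paralog_cds`): fourfold-degenerate codon
  families only, so every planted substitution is synonymous and no stops
  can arise; the substituted-codon count is searched until the realized NG86
  Ks is within 0.01 of target (raising an error when the integer granularity
  of Sd makes a target unreachable, which happens near Ks 2 at small codon
  counts).
- **Genotypes** (`sim_genotypes_bn`): Balding–Nichols — ancestral frequency
  uniform on [maf_floor, 1−maf_floor], population frequency Beta(p(1−F)/F,
  (1−p)(1−F)/F), dosages Binomial(ploidy, p_pop). Chosen because its F
  parameter equals the expected Weir–Cockerham Fst, giving a closed-form
  recovery target. No linkage, no admixture.
- **Anchor sets** (`sim_anchor_sets`): a single query chromosome segmented
  into runs of 40 genes; each segment's copy number c (0–5,
  largest-remainder allocation so class fractions match the requested
  profile) produces c collinear runs on target chromosomes. Segment length
  (40) deliberately exceeds the default chaining gap limit (20) so runs
  break wherever a segment skips a target chromosome, making span-based
  depth equal the planted copy number.

## Ploidy inference

Folded minor-allele fractions are binned at 0.02, smoothed with a 3-bin
moving average; modes are local maxima with prominence ≥ 10% of the tallest
bin, merged within 0.05. Folding is computed as min(ref, alt)/total so the
histogram is exactly invariant under swapping the depth columns. A diploid
shows one folded mode near 0.5; an autotetraploid two, near 0.25 and 0.5.

Model selection follows the nQuire convention on unfolded fractions: for
each hypothesis P, a Gaussian mixture with fixed means {i/P}, free weights
and one shared variance is fit by EM (200 iterations max, 1e-6 log-likelihood
tolerance, variance floored at 1e-4, uniform weight init) and compared to a
free 3-component mixture via Δ = logL_free − logL_fixed. Because the fixed
models are nested (the tetraploid mixture imitates the diploid one by
zeroing two weights), the raw argmin of Δ would drift to the largest
hypothesis on noise alone; a parsimony penalty of 3 log-likelihood units per
component beyond the diploid model (AIC-scale) breaks that degeneracy —
genuine ploidy signals separate hypotheses by thousands of units at the
default simulation size (20k sites, 60×). Depth window defaults: minimum 20,
maximum 3× the median (a collapsed-repeat guard); site quality ≥ Q20.

## K-mer genome profile

A deliberately simple peak-based model rather than a full negative-binomial
mixture fit: error cutoff = first local minimum of the smoothed counts;
homozygous peak = dominant mode above the cutoff (if a substantial peak sits
near twice the dominant depth, the dominant one is relabeled heterozygous);
genome size = above-cutoff k-mer mass / homozygous peak depth; k-mers deeper
than 1.5× the homozygous peak contribute their excess copies to the repeat
partition; heterozygosity h = 1 − (1−f)^(1/k) where f is the
haplotype-specific fraction of distinct k-mers estimated from the
het-region/hom-region distinct counts. Genome size scales proportionally
with the spectrum's counts (it is a mass ratio); heterozygosity and repeat
fraction are scale-invariant. `ploidy_hint` only relabels peaks.

## Solo-LTR dynamics

Candidates are homology-method LTR records; six filters apply in order
(length ≥ 100 bp, identity ≥ 0.8, score ≥ 300, no element ID shared across
the candidate's two flanks among the four nearest ID-carrying records,
distance ≥ 5000 bp to the nearest candidate/LTR/internal record, length ≤
the genome-wide 95th percentile of intact-element LTR lengths), recording
the first violation. The adjacency rule is read as "shared across sides":
an ID on both flanks means the candidate sits inside a fragmented element,
whereas a contiguous intact element adjacent on one side (whose records
necessarily share an ID) is normal context for a true solo. Absent identity
attributes fail the identity rule (conservative). With no intact elements
the percentile rule is skipped with a warning. Insertion age = d/(2μ) with
Jukes–Cantor-corrected LTR–LTR divergence by default (raw p-distance via a
flag) and μ = 4.72e-9 per site per year.

## Repeat topography

Periodicity score(p) = mean per-base identity between the sequence and
itself shifted by p, over p in 50–1000 bp (covers the 158/314/468 bp units
of interest). No structure is reported below score 0.6. The monomer is the
smallest significant peak — not the global maximum, because higher-order
repeat (HOR) variant divergence depresses the monomer lag; HORs are
near-multiple peaks scoring clearly above the monomer lag, with multiples of
an already-reported HOR dropped. Window identity heatmaps use k-mer-set
Jaccard mapped through the Mash transform (k = 15, 5 kb windows). Telomere
tracts extend inward from each sequence end through whole motif copies
(default AAACCCT, its reverse complement, and all circular permutations; the
6-mer variant AAACCT is accepted via the motif flag), allowing one mismatch
per copy and stopping after two consecutive failing copies; tract length is
whole-copy based, which makes mismatch-free planted tracts exact.

## Ks, WGM dating, synteny

Nei–Gojobori (1986): per-codon synonymous sites as the per-position fraction
of non-stop single-nucleotide changes that are synonymous; pathway-averaged
difference counts with equal weights, skipping stop-passing paths; S
averaged over the two sequences; Ks = −¾ ln(1 − 4pS/3), flagged saturated at
pS ≥ 0.75. Peaks come from a Gaussian KDE on (0, 3] (local maxima ≥ 10% of
the global density maximum). Time T = Ks/(2r), default r = 6.56e-9 per
synonymous site per year — on that scale Ks ≈ 0.39 corresponds to the ~30
Myr WGM horizon discussed for these genomes.

Anchor chaining is a deliberate simplification of MCscan: per chromosome
pair, dynamic programming finds maximum-anchor chains strictly monotone in
both genomes (both orientations), consecutive ordinal gaps ≤ 20, extracted
best-first with each anchor in at most one block and chains under 4 anchors
discarded. Ties are fully deterministic: the lexicographically smallest
(query, target) ordinal sequence wins, forward orientation preferred. The
test suite proves the DP equal to exhaustive chain enumeration on ≤15-anchor
instances. Per-gene syntenic depth = number of blocks whose query span
covers the gene; the retention profile reports the gene fraction at depths
0–5 and the modal nonzero depth as "d:1".

## Population structure

Weir–Cockerham (1984) per-locus variance components a, b, c with observed
heterozygosity from genotype calls; weighted Fst = Σa/Σ(a+b+c), monomorphic
loci excluded and counted. Tetraploid dosages are diploidized (0,1→0; 2→1;
3,4→2) for this path — the estimator's heterozygosity terms assume diploid
genotypes — with a frequency-based Hudson estimator as the ploidy-agnostic
alternative. PCA mean-imputes missing dosages per locus (loci > 20% missing
dropped), centers columns, and uses a full SVD. Local PCA summarizes each
window (3 kb genomic span by default, SNP-count windows available) by the
rank-2 approximation of its sample covariance with eigenvalues normalized to
unit total; window distance is the Frobenius norm between summaries;
classical (Torgerson) MDS embeds windows with negative eigenvalues truncated
at zero. Outliers lie more than 3 MADs above the median distance to the
medoid window and are grouped by single linkage at the same distance scale
into at most three clusters labeled LS1–LS3 by size.

## Problem sizes and numerical choices

Simulation defaults mirror realistic study conditions (60× depth,
50k heterozygous sites for histograms, 20k for classification, 2000 loci ×
2×30 diploids for Fst recovery, 4000 genes for retention profiles, 158 bp
monomers, AAACCCT tracts up to 30 kb); genome lengths for k-mer tests are
0.2–1 Mb, a size at which exact counting is comfortable and all rate
estimates are already stable. EM and chaining tie-breaks are deterministic
as described; all randomness flows from explicit seeds.

## Known limitations

- The k-mer model has no error-rate or bias fitting beyond the cutoff; it is
  not a GenomeScope replacement for real read sets.
- The solo-LTR score threshold is read from the annotation, not recomputed;
  the alignment scoring scheme behind it is annotation-defined.
- Anchor chaining has no distance penalty or score weighting, so it is
  validated by planted-truth recovery, not by MCscan output equality.
- Fst on tetraploids through diploidized calls inherits the diploid-model
  caveat; use the Hudson mode when that matters.
- The local-PCA outlier rule (3 MADs) flags occasional background windows by
  construction; planted structure separates by an order of magnitude.
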