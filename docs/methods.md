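# Methods

## The generative model

`lesionphase.simgen` follows one diploid cell — the "penned founder" — and
its clonal descendants through an acute damage burst and a chronic mutation
process.

**Genome.** Random i.i.d. sequence per chromosome at a configurable GC
fraction (default 0.42, mammalian-like). Non-overlapping gene models with
strand, expression bin (1 = silent, 2–4 = expressed tertiles; TPM values are
drawn per bin so that the binning rules recover the generating bins) and
accessibility peaks; in F1 mode, Poisson-placed strain-discriminating SNPs.
Default desk-scale genome: five 10-Mb autosomes plus a 6-Mb X (~56 Mb).

**Burst.** Lesions land once, in G1 of the founder, independently on every
strand of every homolog at dipyrimidine sites that contain at least one
cytosine, with per-site probability `uv_lesion_rate`. TT dimers are skipped
because the bypass spectrum mutates cytosines only, so they can never
produce a call. Template-strand lesions inside gene bodies are removed with
a per-expression-bin probability (transcription-coupled repair); all other
lesions with `repair_global`. The default lesion rate (8×10⁻⁴ per candidate
site per strand) was chosen so that a sister clone carries several thousand
UV-class calls on the desk-scale genome, matching the per-genome mutation
loads the sister-pair experiment operates at; the dose-to-lesion-density
mapping itself is not an observable here and the rate is a free parameter.

**Lineage and VAF bookkeeping.** At the first mitosis each homolog's two
chromatids — one carrying the Watson strand, one the Crick strand —
segregate randomly (`retention_mode` can force same/opposite retention for
controlled experiments). All UV mutations a sister inherits on a homolog
therefore derive from one strand's lesions and share one orientation; the
other sister carries the complement. SCE events, Poisson(`sce_rate`) per
chromosome, reciprocally exchange the distal segments at a uniform position,
flipping the retained strand beyond the breakpoint in both sisters. SCE is
applied at the first mitosis only: exchanges in later divisions act on
subclonal cell fractions and are invisible to consensus phasing, so
simulating them would add cost without observable effect.

A mutation fixed by bypass at clone division *d* (d = 0 is the division
creating the sisters) starts on a single nascent strand and becomes a stable
heterozygous lineage of cell fraction 2^−(d+1), i.e. expected VAF
2^−(d+2): 0.25 for first-cycle UV events, 0.125 for events fixed after one
extra persistence cycle (hence the 2:1 multiallelic ratio). Chronic
mutations are modelled as duplex-fixed heterozygotes: ancestral ones (before
the sister split) are present in both sisters at VAF 0.5; post-split ones
arise in one cell of generation *g* at VAF 2^−(g+1). Events with expected
VAF below `vaf_floor` (default 0.02, far below the calling threshold at 60×)
are not tracked. The expansion is a synchronous perfect binary tree; real
expansion is asynchronous, which leaves these VAF expectations unchanged.

**Bypass spectrum.** Each bypass over a surviving lesion fixes a mutation
with `bypass_mut_prob` (default 0.8). At CC dimers the 3′ C mutates with
probability `cc_three_prime_bias` (0.8), both bases with `cc_tt_prob`
(0.25, producing CC>TT tandems); the alternate base is drawn from
{T: 0.92, A: 0.05, G: 0.03}, a transition-dominated UV-like spectrum. These
per-event probabilities are configurable; only the qualitative spectrum
shape is externally constrained.

**Chronic process.** `ros_rate` G>T events per genome per generation at G:C
sites, strand chosen by which strand carries the damaged guanine (uniform,
history-independent), modulated by per-bin transcription suppression and an
accessibility multiplier inside peaks. `f_background` injects strand-
agnostic C>T/G>A calls amounting to a fraction f of the UV class, emulating
chronic-process calls that are spectrally indistinguishable from UV.

**Sequencing.** Depth ~ Poisson(coverage), alt count ~ Binomial(depth, VAF);
no sequencing-error model beyond binomial sampling, no indels or copy-number
events. Emitted calls carry alignment-metric columns that pass the
post-calling filter, so filter behaviour is driven by the documented
clauses. Tandem-site reads cover both bases jointly; read pairs are
haplotype-assignable with probability 1 − exp(−snp_density · (2·read_len +
insert_len)), and `hap_tag_error` flips all tags of a site (locus-level
mis-assignment, the mode that read-level voting cannot out-vote).

## Analytical choices

**Coordinates.** Mutations are 1-based (VCF convention); all intervals and
bins are 0-based half-open (BED convention).

**Filtering.** The removal clauses are applied in a fixed documented order
and each removed call is labelled with the first failing clause; a clause
whose metric column is absent is skipped and logged, because simulated
tables need not carry every alignment metric. The filter is idempotent.

**Runs test.** The genome-wide statistic counts runs on the concatenation
of per-chromosome code sequences (sorted chromosome order). Summing
per-chromosome run counts instead would inflate R by ~(number of
chromosomes − 1) relative to the single-sequence null and skew the null
p-value distribution. rl20 itself is computed from per-chromosome runs, so
runs never span a chromosome boundary. The normal approximation is used
without continuity correction; `runs_test_exact` enumerates the run-count
distribution for small n. At very small n (n₁ or n₂ ≤ ~5) the normal
approximation deviates from the exact tail by design; tests validate the
exact route against full enumeration and the approximation at the scale the
statistic is actually used.

**Segmentation.** PELT with an L2 mean-shift cost on the ±1 codes; penalty
3·log n (1.5× the BIC rate for a unit-variance mean shift). The extra
factor is deliberate: two interleaved Poisson processes (the two homologs)
produce occasional one-sided runs of 20–30 mutations by chance, and the BIC
rate calls them changepoints. Minimum segment size 20 mutations and phase
threshold τ = 0.5, which separates the three Bernoulli modes even at a 16%
background fraction. Chromosomes with fewer than 20 informative mutations
return a single MIXED segment flagged low-confidence. Binary segmentation
with the same cost and penalty is available as a fallback.

**SCE.** Every within-chromosome boundary between segments of different
state is a candidate; direct phased-to-phased switches are detected but
flagged (`phased_to_phased`), since they may be two unresolvable events.
Event position is the midpoint between the flanking segments' nearest
informative mutations; sister reciprocity uses a 2-Mb positional tolerance.
Because transcription-coupled repair itself imprints genuine local strand
asymmetry in gene bodies, SCE-rate recovery experiments switch TCR off.

**Sister sharing.** Two calls are "shared" on an exact (chrom, pos, ref,
alt) match. At simulation truth level the lesion-segregation invariant
(zero shared UV at persistence 0) is checked homolog-resolved, because two
independent lesions on opposite homologs can coincide at one position.

**Rates.** 64 stranded plus-strand trinucleotide contexts for rates (alt
alleles pooled), 96 pyrimidine-fold contexts for signatures — two foldings,
kept distinct on purpose. Rates are per-context counts over opportunities,
weighted by the trinucleotide representation of either the region or the
genome (`weight_source`; which comparison uses which is a caller decision),
×10⁶. Stranded rates are doubled and divided by the genome-average class
rate. Flank enrichment uses two-sided Fisher tests with Benjamini–Hochberg
correction across flank offsets.

**Haplotype assignment.** Unique tagged alt reads vote; assignment needs
≥2 assignable reads and |n_A − n_B| ≥ 2 (the cutoff is exposed), with zero
minority reads never counted as a conflict and ≥2 reads on both haplotypes
treated as one.

**Bin geometry.** The mappability/binning machinery defaults to the
full-genome geometry (10-Mb bins, 100-kb step, ≥95% mappable, ≥10 informative
mutations per scored bin). Desk-scale simulated genomes use 1-Mb bins with a
100-kb step — the same ~50× ratio of bin width to expected run scale —
because a 10-Mb bin equals a whole simulated chromosome.

## What the simulator does and does not emulate

It reproduces the strand-phasing geometry, VAF structure, multiallelic
arithmetic, repair asymmetries and haplotype-tagging statistics of the
sister-pair and F1 designs, with exact ground truth. It does not emulate
sequencing error, mapping artefacts, copy-number variation, cell-cycle
heterogeneity, real trinucleotide landscape (sequence is i.i.d.), or the
clustered spatial distribution of real strain SNPs — so a passing test
demonstrates correctness of the analytical machinery under the model's
assumptions, not robustness to every artefact of real data.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen so the whole
suite completes in minutes on one CPU: sister pairs on ~56 Mb genomes
(~7,000 UV-class calls per sister, matching the per-genome loads of the
design being emulated), 200 tandem CC sites at 60× for the multiallelic
ratio, 100 chronic replicates for null-uniformity, 200 × 2-Mb chromosomes
for SCE-rate recovery, a 50-Mb hemizygous X (~30,000 assigned mutations)
for the false-assignment rate, and three pooled sister pairs on 30-Mb
genomes (~1,300 template-strand mutations) for the repair-efficiency
recovery. Statistical tolerances in the tests are set from the binomial or
Poisson standard errors these sizes imply.
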