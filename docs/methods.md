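# Methods

This note documents the models and procedures implemented in `darkamp`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data tests do and do not demonstrate.

## Problem setting

The package processes mixed-target amplicon libraries from individually
extracted wild insects. Each library contains two co-amplified products:
a 418-bp fragment of the host mitochondrial COI gene (primers BF3/BR2)
and the bacterial 16S rRNA V4 region (primers 515F/806R), plus synthetic
spike-in templates of known copy number added during DNA extraction.
From these, the pipeline reconstructs (i) a host barcode and species
assignment per individual, (ii) decontaminated bacterial ZOTU/OTU
tables, (iii) absolute 16S rRNA copy numbers calibrated by the
spike-ins, (iv) Wolbachia strain tables from the COI bycatch, and
(v) a hierarchical hurdle-model analysis of what drives microbiota
variation.

## Read preparation

Reads are assigned to a target when both mates carry that target's
primers within IUPAC-compatible comparison. Heterogeneity spacers of
0–7 nt before the primer are allowed (`max_spacer`, default 7; the
insert lengths used in the lab protocol are not published, so the upper
bound is a configurable choice). One mismatch per primer is tolerated
by default. Orientation is assumed forward-primer-on-R1 with a rescue
pass for swapped mates. A pair whose mates match different targets is
unassigned and logged.

Merging takes the best ungapped overlap between the forward mate and
the reverse-complemented reverse mate, scored as matches minus twice
the mismatches; the pair is rejected if no overlap of ≥ 20 nt keeps the
mismatch fraction ≤ 0.25. At disagreeing positions the higher-quality
base wins; at agreeing positions the consensus quality is the maximum
of the two. These parameters are explicit choices — published mergers
differ in details, and the contigs here feed exact-sequence
dereplication, so the conservative overlap minimum matters more than
the consensus-quality model.

Merged contigs are kept when they fall in the expected length window
(400–430 nt for COI, 250–260 nt for 16S-V4) and contain no low-quality
region, operationalised as a run of ≥ 3 consecutive bases with Phred
≤ 30 (`run_length`, `q_threshold` configurable; the underlying
filtering rule in the original protocol is stated only as "lower
quality regions").

## Denoising and taxonomy

Each library is dereplicated exactly, singletons discarded. Denoising
is a greedy abundance-skew pass in the style of the UNOISE algorithm:
candidates in descending count order join the first accepted centroid
at edit distance d whenever count ratio ≤ β(d) = 1/2^(αd+1) with α = 2,
else found a new ZOTU if count ≥ `minsize` (default 2 — singletons are
already gone, so nothing is silently dropped and per-sample counts are
conserved). Denoising is strictly per library; ZOTU identity across
samples is established by exact sequence match when tables are merged.

Chimera screening is a deliberately simplified exact two-parent test: a
ZOTU is flagged when some breakpoint splits it into a prefix matching
one parent and a suffix matching a different parent exactly, both
parents ≥ 2× as abundant. This catches PCR bipartition chimeras with
perfect segments; abundance-weighted scoring models are out of scope.

OTUs are built by greedy centroid clustering at 97% identity, identity
defined as matches over alignment columns of a global alignment with
unit edit costs and penalised end gaps (amplicons share a length
range). Centroids are scanned in descending abundance, so ties resolve
toward the more abundant centroid.

Taxonomy is a k-mer bootstrap classifier in the style of SINTAX: 100
bootstraps, each drawing 32 8-mers with replacement from the query's
k-mer set; each bootstrap votes for the reference sharing most drawn
k-mers (ties broken at random under the run's seeded generator). The
reported lineage follows the winning path rank by rank, so confidence
is non-increasing with depth; ranks are reported down to the deepest
with confidence ≥ 0.80.

## Host barcodes and species proposals

A sample's dominant OTU is the arthropod-classified OTU with most
reads; the sample passes QC when that OTU has ≥ 300 reads and holds
≥ 95% of all arthropod reads (both thresholds inclusive), and the
barcode is the most abundant ZOTU sequence within the dominant OTU,
required to be exactly 418 nt. Identical barcodes collapse to
genotypes, numbered by descending individual counts.

Species-level clusters are proposed by average-linkage hierarchical
clustering on pairwise p-distance (N positions excluded; pairs with
> 10% masked overlap treated as maximally distant), cut at 3%. Expert
review of a reference dendrogram is replaced by an automated flag: a
cluster that joins references of more than one named species is marked
ambiguous and reported, not resolved. Names are assigned at ≥ 97%
global identity to a named reference barcode, with genus- then
family-level fallback from the classifier. The 3% cut is a stand-in
for manual delimitation, not a claim about phorid taxonomy.

The sex-ratio helper is the standard one-degree-of-freedom chi-square
test against 1:1.

## Contamination filtering and spike-ins

Relative abundances are computed per sample on the raw decontamination
input table (columns sum to 100%). The ratio rule keeps a ZOTU only if
its percentage in at least one experimental sample is at least 5× the
maximum percentage across blank libraries (extraction, first-PCR and
indexing blanks; positive controls belong to neither set). ZOTUs absent
from every blank are kept whenever present in any experimental sample.
Blanks are pooled globally; a per-batch option exists.

Spike-in ZOTUs (≥ 99% identity to the extraction spike-in reference)
are identified on the raw table *before* the ratio rule, because the
spike-in dominates blank libraries by design and would otherwise remove
itself; their per-sample read counts are tabulated and the ZOTUs then
dropped. The second, PCR-stage spike-in is detected and dropped without
further use. Archaea, Eukaryota, chloroplast, mitochondria and flagged
chimeras are removed with per-category logging.

## Absolute quantification

With C spike-in copies added to 1/f of the homogenate (f = 5 from the
40 µl aliquot of a ~200 µl homogenate; C = 10,000 or 20,000 per batch,
carried in the sample sheet), the copy estimate for a ZOTU with r reads
against s spike-in reads is

    copies = (r / s) · C · f.

Estimates are linear in reads at fixed spike depth and invariant to
uniform rescaling of a sample's depth. Samples with zero spike-in reads
cannot be calibrated and are discarded. Totals are sums over ZOTUs;
OTU-level copies sum member ZOTUs; richness summaries count taxa at
≥ 100 estimated copies (inclusive). No correction is made for 16S
operon copy-number variation across genomes.

## Wolbachia from COI bycatch

Insect COI primers co-amplify the COI of alphaproteobacterial
endosymbionts. ZOTUs classified to genus Wolbachia, non-chimeric and
exactly 418 nt, form the strain table; presence is called at ≥ 2 reads
per sample. Cross-marker concordance against 16S-based detection uses
stricter cutoffs (≥ 3 COI reads vs ≥ 400 16S reads) intended to
exclude low-level cross-contamination, and reports simple agreement
plus Cohen's kappa.

## Hurdle community model

Presence-absence and abundance conditional on presence are modelled
separately. Presence is Bernoulli-probit; abundance is Gaussian on
log-transformed, per-taxon standardised values with absences as missing
cells. Season and sex are fixed effects; site, host species, host
genotype and the individual insect are community-level random effects,
each structured as latent factors η with taxon loadings Λ
(genotype is crossed with species, not nested — both appear as separate
levels). Priors: standard normal on fixed effects, multiplicative-gamma
shrinkage on loadings (a₁ = 2.1, a₂ = 3.1, ν = 3), inverse-gamma(0.5,
0.5) on residual variances.

The sampler is a blocked Gibbs scheme: truncated-normal data
augmentation for the probit layer, conjugate normal updates for fixed
effects, factors and loadings, and conjugate inverse-gamma updates for
residual variances on observed cells only. The number of factors per
level is fixed (default 2, capped at 10) rather than adaptively
truncated: under the shrinkage prior surplus factors are driven toward
zero, which achieves the same practical effect while keeping parameter
identity stable across draws — a property the convergence diagnostics
rely on.

Each chain runs 375·thin iterations, discards the first 125·thin as
burn-in and thins to 250 retained draws; four chains give 1000 draws.
Convergence is accepted when the third quartile of split-chain PSRFs
over the taxa's season and sex coefficients is ≤ 1.05, escalating
thin = 1, 10, 100 … otherwise.

Variance partitioning attributes, per draw and taxon, the fixed-effect
variance to covariates via the covariance of the design (negative
cross-terms clipped at zero; the intercept carries no variance) and
each random level the diagonal of Ω = ΛᵀΛ; fractions are normalised per
taxon and averaged over draws. Residual associations correlation-scale
Ω per draw and report pairs whose positive or negative fraction of
draws reaches 0.90. Fixed-effect support calls a taxon
positive/negative at 0.95 posterior probability. Fit is summarised by
AUC and Tjur R² (presence) and squared Pearson correlation (abundance),
explanatory from in-sample posterior-mean predictions and predictive
from two-fold cross-validation with folds stratified by species;
held-out sample units contribute their factor variance to the probit
denominator rather than a mean shift.

A note on identifiability: intercepts absorb the (uncentred) means of
realised group factors and are therefore weakly identified, as in any
latent-factor joint species distribution model. Calibration checks in
this package assess the season and sex coefficients, which are well
identified; intercept intervals should be read with that caveat.

## Synthetic data

The generator emulates the study design it is tested against: a
site × season × sex grid (defaults: 6 sites, 2 seasons, 88 individuals
per sex per cell), log-series host species abundances with several COI
genotypes per species (intraspecific distance a few nucleotides,
interspecific effectively random), endosymbiont strains (Wolbachia,
Rickettsia, Spiroplasma) structured by host species, genotype and sex
with lognormal loads of high median (10⁶ copies), broadly distributed
lognormal generalists, contaminants shared between blanks and (at low
level) experimental samples, spike-ins at 10,000 or 20,000 copies
alternating by 88-sample batch, and 6 negative plus 2 positive controls
per batch. Reads are allocated multinomially with template weights
copies/f against the spike-in's full copies, so quantification is
unbiased by construction up to multinomial sampling. Wolbachia COI
bycatch is a configurable fraction of a sample's COI reads (default 1%,
matching the order of the study's non-insect read share), split among
infecting strains by load. Sequencing is modelled as uniform per-base
substitution with a flat quality profile and a fixed ladder of
heterogeneity spacers; flow-cell artefacts, quality decay and indels
are not modelled. Chimeras are simple two-template crossovers at a
configurable rate.

What passing tests show: the pipeline's logic is correct against known
truth — exact recovery under error-free reads, calibrated
quantification under multinomial sampling, correct decision boundaries,
and a sampler whose credible intervals cover generative-truth
parameters. What they do not show: robustness to real error profiles,
indels, NUMTs, tag-jumping, or reference databases with incomplete or
wrong lineages.

## Problem sizes and numerical choices

Tests and the acceptance script run scaled-down designs chosen as the
smallest sizes at which each property is informative: a 24-sample
error-free cohort for exact recovery, a 48-sample cohort with
study-like error rates for the summary statistics, 200 samples for
quantification calibration, and 500 samples × 30 taxa for model
recovery. Ties in greedy clustering and classifier votes are broken by
abundance then lexicographic id, or by the run's seeded generator;
probit augmentation clips tail probabilities at 10⁻¹² for numerical
stability; degenerate inputs (empty libraries, empty blanks, taxa
present in < 2 samples, zero-variance taxa) warn and are excluded
rather than fatal wherever a partial result is meaningful.
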