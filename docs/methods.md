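# Methods

## Scope and model

`circqtl` analyses variation in circular RNA (circRNA) expression across
individuals. A circRNA is observed only through reads spanning its
back-splice junction; at each locus the caller reports a circular junction
count C and a linear junction count L (the mean read count crossing the two
back-splice sites on the linear transcript). Two quantifications are
carried through the whole pipeline:

- **circular ratio** = C / (C + L), the fraction of junction-spanning reads
  supporting the circular isoform (a splicing-level trait);
- **log2 circCPM** = log2((C + 0.5) / (T + 1) × 10⁶), circular junction
  counts per million total circular junction reads T in the sample (an
  abundance-level trait). The 0.5/1 offsets are the voom-lineage
  convention and keep zero counts finite.

A locus is *expressed* when C ≥ 1 in strictly more than half of the
samples and its mean circular ratio is at least 0.05 (loci below that are
indistinguishable from linear-splicing byproducts). Loci are classified by
where the two back-splice sites fall: if either site lies outside all
annotated genes the locus is intergenic; otherwise if either site falls in
an intron it is intronic; only loci with both sites in annotated exons are
exonic. Exonic circle length is the summed length of annotated exons fully
enclosed by the back-splice sites; an enclosed gap between those exons is
counted as retained sequence only when the annotation provides no
donor/acceptor pair that would splice it out (this is one reading of an
ambiguous convention — with a complete single-transcript annotation it
reduces to the plain sum of enclosed exons). Intronic and intergenic
circles use the genomic span.

## Covariate model

Expression heterogeneity is driven by technical (institution, library
batch, post-mortem interval, RNA integrity and its square) and biological
(age, ethnicity, sex, diagnosis) factors; the synthetic covariate table
carries a minimal set of one categorical batch, one continuous age, sex
and diagnosis. Precision weights follow the voom recipe: per feature, an
OLS fit of log2 circCPM on the design gives residual standard deviations;
the square-root standard deviation is smoothed against mean log-count by
lowess (span 0.5, the published default), and each observation receives
the inverse fourth power of the trend value at its fitted log-count,
clamped to the trend's range. Covariate scans are per-feature weighted
least squares — a t-test for single columns, an F-test for multi-level
factors, and RIN/RIN² merged by min-P per feature before
Benjamini–Hochberg correction. Empirical-Bayes variance moderation is
deliberately omitted: at the feature counts used here plain WLS gives
calibrated type-I error (verified by the null scans in the test suite) and
keeps inference dependency-free. Covariate-adjusted expression is the WLS
residual matrix.

Case–control power uses the standardized effect size d =
|log2(fold change)| / sd, with the fold change on the linear scale and sd
the pooled log2-scale standard deviation over all samples (pooled, not
per-group — the formula is silent and pooling is the conservative common
choice). The required per-group n for a two-sided two-sample t-test solves
the noncentral-t power equation (df = 2n − 2, noncentrality d·√(n/2)) by
bisection; α defaults to a Bonferroni cutoff 0.05/number of features.

## cis-circQTL mapping

SNPs are retained at imputation quality ≥ 0.8 and MAF ≥ 0.05, autosomes
only. A SNP is cis to a circRNA when it lies in the closed interval from
100 kb upstream of the 5′ back-splice site to 100 kb downstream of the 3′
site. The additive-dosage model regresses covariate-adjusted log2 circCPM
on dosage per pair (simple linear regression; the ratio route instead
logit-transforms the circular ratio with a 0.01 boundary offset for
variance stabilization and includes the covariates as co-regressors via
Frisch–Waugh projection, without voom weights).

Multiple testing across correlated cis SNPs is corrected per circRNA by
permutation: each of N rounds applies one sample-label permutation, shared
across all features to preserve cross-feature correlation, to the
expression matrix (genotypes fixed) and records the per-circRNA minimum P
over its cis SNPs. The empirical P of the observed minimum is

    empP = (1 + #{n : minP_n < P_obs}) / (N + 1)

with strict inequality, so ties resolve conservatively toward larger empP.
Storey q-values over the per-circRNA empirical P values estimate π0 by the
smoother method (cubic fit of π0(λ) over λ = 0.05…0.95, read off at the
largest λ, clamped to (0, 1]; fewer than 10 features fall back to π0 = 1,
the BH limit). circRNAs with q < 0.05 are circQTL-containing. The largest
empirical P among them maps back to a nominal-P cutoff per circRNA as the
inverse-CDF empirical quantile of that circRNA's own permutation minima;
every cis SNP below its circRNA's cutoff is a circQTL SNP. This
quantile back-mapping is the standard reading of a procedure whose
original description stops at the empP threshold.

The smallest achievable empP is 1/(N + 1), so the q-value resolution is
bounded by the permutation count: at N = 200 a single-feature discovery
among ~100 features cannot reach q < 0.05 even when the association is
perfect. Desk-scale defaults therefore use N = 500–1000 (the pipeline
default is 1000); matching the original study takes N = 10,000.

**Concordance refinement.** Because circCPM tracks host-gene expression as
well as circularization, the final circQTL set keeps (i) pairs significant
under both quantifications with the same slope sign and (ii)
circCPM-significant pairs of intergenic circRNAs, which have no host gene
and no informative ratio. Planted expression-level effects (multiplying C
and L equally) are recovered by the circCPM scan but depleted from the
ratio scan — the filter's purpose — and the experiments module measures
exactly that. Sign concordance is enforced, not merely observed.

## Characterization

The most significant SNP per circQTL-containing circRNA (max-circQTL) is
selected with ties broken by distance to the nearest back-splice site,
then SNP id. Linked SNPs are pruned by the sliding-window rule (window 50
SNPs, step 5, r² > 0.5; r² is the squared Pearson correlation of dosage
vectors, the PLINK dosage convention). The exact removal order of the
original pruning tool is unspecified; within a window the smaller-MAF
member of an offending pair is removed (ties drop the later position) —
set-level results are robust to this choice, and a brute-force all-pairs
checker in the tests confirms no retained within-window pair exceeds the
threshold. Non-circQTL controls are SNPs whose minimum nominal P across
all tested circRNAs exceeds 0.05, LD-pruned, then sampled without
replacement to match the max-circQTL set's joint distribution over MAF
bins (width 0.05) and distance bins ({internal, 0–1 kb, 1–10 kb,
10–100 kb}); empty bins borrow from the nearest bin with a logged
warning. Joint (not marginal) matching is a documented choice.

Element enrichment uses the 11 sequence-defined categories (splice
acceptor/donor merged into one canonical-splice-site category) with a
two-tailed Fisher exact test per category — the hypergeometric-sum
definition, odds ratios Haldane-corrected when a cell is zero — and BH
correction across categories; a separate reverse-complement-sequence (RCS)
test is restricted to intronic SNPs. Distances to the back-splice sites
are signed bp for external SNPs (negative upstream of the 5′ site) and
relative position (pos − start)/(end − start) for internal SNPs.

## RCS detection

The introns flanking an exonic circRNA promote circularization when they
carry reverse-complementary segments that base-pair across the circle.
One intron is aligned locally (Smith–Waterman, affine gaps; a gap of
length k costs open + k·extend) against the reverse complement of the
other; N scores as a mismatch against everything. Raw scores convert to
Karlin–Altschul bitscores, bits = (λS − ln K)/ln 2, and an RCS is called
when any alignment strictly exceeds 100 bits. The default scheme (match
+2, mismatch −3, gap open 5, extend 2, λ = 0.625, K = 0.41) follows the
standard blastn task parameters; under it the shortest exact repeat
exceeding 100 bits is 55 bp (closed form in `min_repeat_length`).
Alignment is exact dynamic programming (through Biopython's C aligner,
checked against a brute-force DP oracle in the tests) rather than
word-seeded heuristics: correctness over BLAST fidelity at desk scale.
E-values are not computed; the threshold is on bitscore alone.

## GWAS colocalization

GWAS-catalog rows are filtered to P ≤ 5×10⁻⁸ with literal trait-label
matching (ontology traversal is out of scope; trait labels are inputs).
Index SNPs are expanded to panel SNPs within 1 Mb at r² > 0.6 (strict);
enrichment of pruned max-circQTLs in the linked set over matched controls
is a one-tailed Fisher test, repeated per trait (BH across traits) for
traits with more than 90 risk loci. Colocalized pairs are circQTL SNPs at
r² > 0.8 (strict) with an index SNP, reported with the SNP's region class
(flanking intron / circRNA region / other). The 1 Mb search radius is a
documented knob; the LD panel is pluggable.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with a truth table as ground truth for recovery tests.

- **Genotypes.** Two haplotypes per sample; within an LD block each SNP
  copies the previous SNP's allele with probability `ld_rho` (default 0.9)
  or draws fresh at its allele frequency (uniform in [0.05, 0.5], the
  common-SNP range); blocks of 10 SNPs are independent. Dosage is the
  haplotype sum; near-monomorphic SNPs are redrawn. One synthetic
  chromosome, SNPs every 1 kb, so every circRNA has well over 20 cis SNPs
  in its ±100 kb window.
- **Loci.** ~80% exonic, 10% intronic, 10% intergenic (the class mix seen
  in brain data), each with a minimal host-gene annotation.
- **Counts.** Per circRNA and sample, a total junction mean = sample depth
  (uniform in 100k–200k circular junction reads, the order observed in
  brain libraries) × a log-normal abundance share; the circular fraction
  p0 is uniform in [0.08, 0.5]. C ~ NB(mean·p, φ) and L ~ NB(mean·(1−p), φ)
  with a single shared dispersion φ = 0.15 (var = μ + φμ²) — one knob,
  adequate for recovery tests. Covariate effects act on the log2 mean.
- **Planted effects.** `ratio_shift` adds β·dosage to logit p (splicing
  level); `abundance_shift` multiplies both means by 2^(β·dosage)
  (host-gene level); `splice_disruption` multiplies only C's mean by
  2^(β·dosage), β < 0, mimicking a broken canonical back-splice site.
  Default βs (1.5 logit units, 1.0–1.2 log2 units, −2) give per-dosage
  effects large enough that realized dosage-R² on adjusted expression
  typically exceeds 0.2 — the regime the recovery experiments measure.
- **Introns and RCS.** Flanking introns are 800 bp of uniform random
  sequence; 30% of circRNAs receive an exact 100-bp reverse-complement
  planted segment (comfortably above the 55-bp detection boundary).
- **GWAS.** Linked index SNPs are haplotype near-copies of planted circQTL
  SNPs (per-allele flip probability 0.01, realized r² ≈ 0.94) appended to
  the panel; background index SNPs are non-effect panel SNPs; decoy rows
  sit at P = 10⁻⁶, above the genome-wide threshold.

**Compositional coupling at desk scale.** circCPM normalizes by the
per-sample total circular junction count. With only tens of simulated
circRNAs and log-normal abundance shares, a strong planted effect on one
high-share locus shifts that total in a dosage-correlated way and induces
genuine abundance-level associations at neighbouring loci whose cis
windows overlap the planted SNP's LD block. The circular ratio is
normalization-free, so these induced hits fail the ratio scan and the
concordance filter removes them (verified in the worked example: 17 of 18
non-planted circQTL-containing loci were dropped; the survivors were
intergenic and bypass the filter by design). At realistic circRNA counts
(thousands of loci, no dominant share) the coupling is negligible; at desk
scale it is a feature, not a bug — it exercises precisely the
host-gene-versus-circle confounding the dual-quantification design
exists to resolve.

What the generator does **not** emulate: read-level noise (junction counts
are drawn directly, not from alignments), population structure and
relatedness, imputation uncertainty (quality is fixed at 1.0), realistic
LD decay (block-constant rather than distance-decaying), GC/mappability
artefacts, and trait ontologies. Passing tests therefore demonstrate that
the statistical machinery is correct and calibrated under its stated
assumptions — not that those assumptions hold in any particular cohort.

## Numerical choices and degenerate inputs

- Circular ratio at C + L = 0 is defined as 0 (counts the locus as
  unexpressed, consistent with the filter's intent).
- Constant expression features get P = 1 in scans, never significance.
- Monomorphic SNPs are dropped from scans; their r² is reported missing.
- Missing dosages would be mean-imputed per SNP (imputed-dosage inputs are
  rarely missing; the simulator never produces them).
- Correlations are clipped away from ±1 before the t-transform.
- The permutation seed, control-matching seed and every simulator draw
  derive from the run seed; identical config + seed gives byte-identical
  artifacts (asserted in the tests).

## Experiment problem sizes

The calibration experiments run at desk scale, chosen to estimate the
relevant proportions with adequate precision: null false-discovery
control uses 150 circRNAs × 200 samples × 1500 SNPs with 1000 permutations
per seed; planted-effect recovery uses 60 circRNAs × 150 samples × 600
SNPs with 500 permutations across 20 seeds; the end-to-end pipeline
default is 100 samples × 100 circRNAs × 1000 SNPs.

## Known limitations

- The ratio-route degrees of freedom treat the projected covariates as
  estimated once, as in standard two-stage eQTL practice; at n ≫ p the
  difference from exact joint inference is negligible.
- π0 estimation is unstable below a few dozen features (hence the π0 = 1
  fallback), making small scans conservative.
- The greedy pruning order and the bin-borrowing rule in control matching
  are implementation choices where the original tools leave the order
  unspecified; results are set-level robust but not bit-compatible with
  PLINK.
- Trans effects, conditional/secondary signals, interaction QTLs and
  posterior-probability colocalization are out of scope.
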