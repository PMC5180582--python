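# Methods

`gbskit` models the full arc of a two-enzyme genotyping-by-sequencing (GBS)
experiment — library design, marker-yield prediction, read cleaning, SNP
filtering, validation statistics, annotation, and trait association — with a
synthetic-data generator that stands in for the wet-lab and alignment steps.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic data does and does not emulate.

## In silico digestion

Recognition sites are IUPAC patterns matched with full degeneracy
(`W = {A,T}` etc.); overlapping matches are all reported, and an `N` in the
sequence satisfies only an `N` pattern position. A cut at a matched site
starting at `s` is placed at `s + cut_offset` on the top strand
(EcoRI `G^AATTC` → offset 1; NlaIII `CATG^` → 4; PstI `CTGCA^G` → 5; ApeKI
`G^CWGC` → 1; BstNI `CC^WGG` → 2). Because all five built-in enzymes are
palindromic, top-strand matching finds every double-stranded site; for a
user-supplied non-palindromic enzyme both strands would need scanning, which
is a documented limitation.

A double digest merges both cut sets; consecutive cuts plus the sequence
termini bound fragments that tile each sequence exactly (lengths always sum
to sequence length). On a coincident cut, the first enzyme argument takes
labelling priority. Coordinates are 0-based half-open internally and in the
BED6 export.

One convention deserves a note: representing a staggered cut by a single
coordinate breaks exact strand symmetry of *fragment lengths*. Under reverse
complement, an enzyme's cut set mirrors shifted by `2*offset - len(site)`
bases; the shift cancels between cuts of the same enzyme but not between
different enzymes, so mixed-enzyme fragment lengths can differ by a few bp
between strands even for palindromic sites. Site positions themselves mirror
exactly, which is what the tests assert.

Size selection uses an inclusive window, default 200–300 bp (the range used
to keep fragment counts near 1.5 M in a ~700 Mb fish genome). `end_filter`
chooses which fragment end-classes count as library members (`any`,
`both_sites`, `mixed_ends`); the literature is not explicit about which
classes are sequenced in practice, so all three interpretations are exposed
rather than hard-coding one. Length histograms default to 100 bp bins with
every fragment above 1 kb pooled in a final overflow bar — the standard
presentation for comparing enzyme combinations.

Fragments with more than 50% `N` can be flagged via `digest.n_fraction`;
they are not removed by default.

## Expected marker yield and retention

The design-stage estimate is plain arithmetic: `n_fragments x fragment_len x
snp_rate` expected SNPs, with defaults 200 bp (the window lower bound, so
the canonical 1.5 M x 200 x 0.001 = 300 k calculation is reproduced exactly)
and 1 SNP/kb, a typical teleost polymorphism density.

Retention is modelled with per-sample depth `D ~ Poisson(lambda)` shared
across loci and samples: a locus is callable in one sample when `D >= t`,
and retained population-wide when a `Binomial(n, P(D >= t))` count reaches
`m` samples (independence across samples assumed; both are stated
approximations, and a negative-binomial depth option is available for
overdispersed libraries). The saturation curve maps a per-sample sequencing
amount `a` to `lambda = a / library_bp` and evaluates the same tail — it is
non-decreasing and plateaus at the total locus count.

## Synthetic study generator

The generator's defaults are the study conditions the package is tested
under, chosen to preserve the ratios of a 500-fish GBS experiment at
desk scale:

| parameter | default | rationale |
| --- | --- | --- |
| genome | 2 Mb, 2 chromosomes | seconds-level digestion; ~2,000 enzyme sites at 1 site/kb |
| samples | 500 | the study's population size |
| SNP density | 0.001 /bp | 1 SNP/kb |
| MAF | Uniform(0.05, 0.5) | detectable polymorphism, no fixed alleles |
| depth mean | 10 | the well-covered regime of a GBS library |
| het miscall rate | 0.05 | heterozygote undercalling, the dominant assay-discordance mode |
| missing rate | 0.02 | residual dropout beyond depth-0 |
| QUAL < 100 fraction | 0.05 | fraction of sites failing the quality threshold |
| causal loci | 39 | the hit-count analogue |
| causal variance share | 0.63 | subset share of total additive variance |
| heritability | 0.5 | not reported for the trait; a typical value for fish meat-quality traits |
| trait mean / SD | 21.5 / 4.1 mg/g | muscle EPA+DHA scale |
| sex effect | 0.5 mg/g | small balanced covariate effect |

The genome is random A/C/G/T with EcoRI/NlaIII sites planted at a known
density; spontaneous site occurrences in the background (and any created by
planting) are repaired by single-base edits, so the planted truth map equals
the discovered cut set exactly and digestion can be scored against truth.

Genotypes are biallelic, Hardy–Weinberg, independent across loci and
samples. *No linkage disequilibrium, relatedness, or family structure is
simulated* — passing tests therefore demonstrate statistical correctness of
the estimators under independence, not robustness to the pedigree structure
(30 sires x 30 dams) a real breeding population would carry. An observed
call set applies, in order: heterozygote miscall to a random homozygote,
depth-0 dropout, extra missingness. Site QUAL is lognormal (sigma 0.5) with
its mean set so a configurable fraction falls below 100, and correlated 0.5
with standardized mean site depth.

The phenotype is `y = mu + sum_j beta_j g_j + delta*sex + e`. `n_causal`
loci get large effects and every other locus a small background effect;
both groups are rescaled on realized genotypes so the causal subset
contributes exactly `target_var_fraction` of the additive variance and the
total genetic variance is `h2 * sd^2`. The environmental term fills the
remainder, so the marginal trait distribution has the configured mean and
SD.

Simulated read pairs come from (EcoRI → NlaIII)-oriented in-window
fragments: mate 1 reads from the EcoRI end (beginning `AATTC`), mate 2 is
the reverse complement from the NlaIII end (beginning `CATG`). That
orientation is the only one whose interval contains both remnants, because
EcoRI cuts at the start of its site and NlaIII at the end. Disjoint
fractions of pairs are corrupted to violate exactly one QC rule each, with
truth labels; base-level substitution error is not simulated.

## Read QC

Rules run in a fixed order per pair, and any failing mate drops the whole
pair: (0) each mate must start with an allowed site remnant (`AATTC`/`CATG`;
the set and whether both mates are checked are configurable); (1) a mate
with more than 5% `N` (strict inequality) is removed; (2) a mate whose
*mean* Phred quality is below 20 is removed — the per-base reading of
"quality lower than 20" would discard essentially all real data; (3)
trailing 5 bp windows with mean quality below 20 are trimmed from the 3'
end, a final partial window on the same rule; (4) a mate shorter than 50 bp
after trimming drops the pair. Cleaning is idempotent.

## SNP filtering

The composite marker filter masks genotype calls with `DP < 5` to missing,
then keeps a site iff `QUAL >= 100` and at least `ceil(0.8 * n)` samples
still carry a call. All three comparisons are inclusive ("higher than 5"
and "a threshold of 5" are used interchangeably in the GBS literature; the
inclusive reading is adopted and applied consistently). The 80% default
corresponds to 400 of 500 individuals. Rejected sites are partitioned by
first failing rule, quality before call rate. Indels and multi-allelic
records are passed through untouched with a warning.

## Concordance statistics

Pipeline and assay calls are crossed into a 4x4 table over {AA, AB, BB,
NN}. Success rate is the exact-agreement diagonal over all compared loci.
TN = (AA, AA); FP = pipeline-variant/assay-AA; FN = pipeline-AA/
assay-variant; specificity = TN/(TN+FP) and sensitivity = TP/(TP+FN), with
NN-involved cells excluded from the partition. Two TP readings are exposed:
*detection* (both methods variant, regardless of AB/BB agreement — default)
and *strict* (identical variant genotype, AB/BB disagreements booked as
FN). On the bundled 1,500-call validation table these give 94.3%
specificity and 99.6%/97.9% sensitivity; the source report prints 94.2% and
98.3%, which no documented reading of the printed table reproduces exactly
— the package asserts its own documented definitions and flags the
discrepancy rather than tuning to the printed numbers.

## Annotation

Location classes use overlap precedence CDS-exon > UTR > intron >
intergenic, with the UTR side taken from explicit `five_prime_UTR` /
`three_prime_UTR` features when present and otherwise inferred from the
position relative to the transcript's CDS extent and strand. Effects are
computed by splicing the transcript CDS, substituting the allele
(complemented for minus-strand transcripts), and translating the affected
codon with the standard code. Length-changing alleles are `frameshift` when
`|len(ref) - len(alt)| % 3 != 0`; in-frame indels are reported `NA` (codon
insertion/deletion classification is out of scope). With multiple
transcripts the most severe class is reported (stop_gained > frameshift >
start_lost > stop_lost > missense > synonymous). A CDS whose length is not
a multiple of three triggers a model warning and `NA`.

## Association and variance partition

IBS distance is `1 - shared/(2 x compared)` with pairwise missing
exclusion; classical (Torgerson) MDS embeds it by double-centering and
spectral decomposition, truncating negative eigenvalues.

The scan is ordinary least squares `y ~ 1 + g + sex` with additive coding
(AA=0, AB=1, BB=2), a two-sided t-test on the genotype coefficient, and a
fixed significance threshold `p <= 1e-4` with *no* multiple-testing
correction — matching common single-marker GBS practice; Bonferroni/FDR are
available but off by default, and MDS axes are not added as covariates by
default. Complete-case loci are solved in vectorised blocks by
residualising trait and dosage on the covariates (Frisch–Waugh, identical
to the full OLS); loci with missing calls fall back to per-locus normal
equations. Monomorphic loci and loci with fewer than 4 usable samples
return NA with a reason.

The GRM is VanRaden's allele-frequency-centred cross-product with per-locus
mean imputation of missing calls. REML for `y = Xb + u + e`,
`u ~ N(0, sg2 K)`, `e ~ N(0, se2 I)` profiles the restricted likelihood
over `delta = se2/sg2` on the spectral decomposition of `K`, maximised by
bounded Brent search over `log(delta)` in [-12, 12] with tolerance 1e-8.
An optimum at the interval edge is reported as a boundary solution (the
upper edge is the `sg2 = 0` null). The variance-explained ratio divides
`sg2` fitted with the subset-marker GRM by `sg2` with the all-marker GRM,
identical covariates in both fits; it is flagged undefined when either fit
is at a boundary.

The trait normality check is a one-sample Kolmogorov–Smirnov test against a
normal with estimated mean and SD, without the Lilliefors small-sample
correction.

## Problem sizes used in the checked runs

The automated checks run at desk scale by design: digestion oracles on
random sequences up to 10 kb; retention and QC checks on a 300 kb
two-chromosome genome with 80 samples; null-scan calibration with 500
samples and 100,000 independent loci; variance-partition recovery with 39
causal loci, a 0.63 causal share and n=800 over 20 generator seeds (the
acceptance script uses 10). Genome-scale outcomes of the original
experiment (hundreds of thousands of raw markers, ~70k filtered markers, a
specific hit count) depend on a real assembly and real data and are not
reproduced; the package instead verifies the governing models and exact
small-fixture behaviour.

## Known limitations

- No LD, relatedness, or pedigree structure in the generator; REML recovery
  is demonstrated under independence.
- Read simulation injects rule violations but not realistic base errors,
  adapters, or barcodes (demultiplexing is upstream of the implemented
  rules).
- Methylation sensitivity, star activity, and partial digestion are not
  modelled.
- Top-strand-only cut finding is exact only for palindromic enzymes.
- Mixed-model (kinship-corrected) association is out of scope; the scan is
  plain OLS by design.
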