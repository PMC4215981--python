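# Methods

This note documents the models, defaults and design choices behind
`pedqtl`, what the synthetic generator does and does not emulate, and the
numerical conventions a maintainer should know.

## Trial model and heritability

Phenotypes are modelled as a two-way crossed design of genotypes and
environments with optional replication within environment. Replicates are
averaged per (genotype, environment) cell before analysis, so unequal
replicate counts (a common field-trial reality) do not unbalance the
crossed design; with one value per cell the genotype×environment
interaction is confounded with error and `MS_err` is the residual term.
Missing cells are handled by a one-step unweighted-means fill (row mean +
column mean − grand mean) with the residual degrees of freedom reduced by
the number of filled cells, and the result flagged unbalanced; this is an
approximation adequate for a few missing plots, not for systematically
missing environments.

Variance components use the expected-mean-squares (method-of-moments)
solution; negative estimates are truncated to zero and flagged. REML would
be the modern choice, but method-of-moments is what a JMP-style standard
least squares analysis produces and keeps the worked example exactly
reproducible from printed mean squares. Broad-sense heritability is

    H² = σ²_G / (σ²_G + σ²_E + σ²_ε).

Including σ²_E in the denominator is deliberate: the published worked
example (MS_G = 61.76, F = 19.65, MS_E = 475.57, 65 genotypes, 9
environments) yields 6.513/(6.513 + 7.268 + 3.143) = 0.385, and only this
form reproduces it. H² is invariant to shifting and rescaling the trait.

Environment correlations use pairwise-complete accessions (Pearson), with
pairs sharing fewer than 3 accessions reported missing. The genotypic
value for mapping is the accession's unweighted mean over environments.

## Association scan

The scan fits, per marker, `y = μ + β_k·kernel + β_m·x + u + ε` with
`u ~ N(0, σ²_g K)`. Decisions worth recording:

* **Kinship.** Allele-sharing similarity (proportion of matching calls
  over mutually non-missing markers) linearly rescaled so the minimum
  off-diagonal is 0 and the diagonal 1. The exact formula used by the
  classical GUI tools is unpublished; this IBS-with-rescaling form matches
  their description and, in our null simulations, whitens exactly as well
  as a centred genomic-relationship matrix.
* **REML.** The variance ratio δ = σ²_e/σ²_g is estimated once under the
  null model (intercept + covariates) through a spectral decomposition of
  K, then reused for every marker — the "population parameters previously
  determined" shortcut. The optimiser is a 61-point log-grid over
  δ ∈ [1e-5, 1e5] refined by bounded scalar minimisation; a fine-grid
  oracle test pins its accuracy. Exact per-marker refitting is available
  via `refit_per_marker=True`; at panel size n = 65 both are cheap, and
  they agree within an order of magnitude on p-values when K is estimated
  from a reasonable number of markers.
* **Marker tests.** With δ fixed, each marker's F-test is a rank-one
  update of the null regression in the whitened basis, vectorised across
  markers. Marker r² is the marker sum of squares over the
  intercept-corrected total on the whitened scale (reported as a
  percentage). Effects are reported for the code-1 allele; by convention
  code 1 is the focal line's allele where orientation is known, so
  positive effects mean the focal allele raises the trait. Markers
  collinear with the fixed effects are skipped with a reason rather than
  fitted.
* **Multiple testing.** Storey q-values with the smoother π₀: a cubic
  polynomial fit of π̂₀(λ) over λ ∈ {0, 0.05, …, 0.90} evaluated at 0.90,
  falling back to π₀ = 1 outside (0, 1]. q-values are monotone in p and
  clipped to [0, 1]. The default significance threshold is the workflow's
  q < 0.5 — a deliberately liberal false-discovery rate that accepts up
  to half false calls in exchange for sensitivity at n = 65; downstream
  validation is what separates the wheat from the chaff.

**Null calibration.** On simulated panels with kinship-structured
polygenic background and no marker effects, the scan's p-values are
uniform (KS < 0.05 in ≥ 90% of replicates) when tested markers are drawn
independently of the structure, and plain least squares on
pedigree-structured markers is severely inflated (median KS ≈ 5× the
MLM's). One caveat discovered during calibration: for pedigree-structured
test markers the p-values of kinship-correlated markers are mutually
dependent, so the empirical KS statistic of one scan does not shrink with
marker count even for a perfectly calibrated test — the same plateau
appears for ordinary least squares on a pure i.i.d. phenotype. Uniformity
should therefore be judged on structure-free nulls or across replicates,
not from a single structured scan.

## Supporting structure analyses

kNN imputation follows the classical settings: Manhattan distance
(normalised by the shared-marker count so unequal missingness does not
bias neighbour choice), 3 neighbours, unweighted average rounded to the
nearer code (0.5 rounds to 1), accessions under 80% data dropped. PCA is
correlation-based (markers standardised to unit variance), zero-variance
markers excluded, component signs fixed by making the largest-magnitude
loading positive; explained proportions are invariant to 0/1 allele-code
flips. Distances for clustering are 1 − IBS; UPGMA uses average linkage
with a deterministic tie-break (the pair whose lexicographically smallest
member sorts first), so trees are reproducible under input reordering.

## QTL classification, LD blocks, origin tracing

Significant markers are grouped per (map source, linkage group) by merging
consecutive markers with cM gaps ≤ 15 — the transitive closure of the gap
relation. The default of 15 cM reproduces the published grouping
behaviour, which merges markers spanning ~11 cM and separates gaps of
~19 cM; it is configurable. Markers on different consensus maps are never
merged (cross-map QTL overlap is a reporting matter). Markers without a
map position are reported but excluded from classification.

The source workflow never states its LD-block criterion; the rule adopted
here is explicit: the block is the maximal run of map-adjacent genotyped
markers containing a QTL member in which every adjacent-pair r² ≥ 0.7,
declared present when it spans ≥ 3 markers. r² is the squared Pearson
correlation of allele codes, which for inbred biallelic data equals the
standard haplotype r².

Origin tracing defines a carrier as a pedigree member whose within-block
genotype similarity to the focal line is ≥ 0.9 (the published figure's
cutoff is unstated; 0.9 is exposed as a parameter). The origin class reads
off the focal line's parents — maternal, paternal, both (side
undeterminable), or undetermined — and source ancestors are carriers
reached along carrier-only parent paths that have no carrying parent. A
non-founder source is flagged as a pedigree discrepancy, mirroring the
mismatches between genotypes and breeding records that real panels show.
On tagged simulations (allele origins tracked through every meiosis) the
tracer recovers the introducing founder in ≥ 95% of replicates for
5-marker blocks.

## Synthetic generator

The generator emulates a pedigree-derived inbred panel:

* **Inbreds only.** All material is homozygous; a non-founder is the
  doubled product of one meiosis of its parents' F1. Heterozygotes never
  occur, which matches DH-style breeding material and keeps genotypes one
  code per cell.
* **Meiosis.** Haldane model (no interference): crossover probability
  between adjacent markers r = (1 − exp(−2d/100))/2, independent
  assortment across linkage groups. Allele origins can be tracked through
  the identical crossover draws (`return_origins=True`), which is the
  oracle for transmission and tracing tests.
* **Phenotypes.** y = μ + Σ effect·x + kernel_effect·k + g + E_env + ε
  with a polygenic line effect g ~ N(0, σ²_G), an environment main effect
  shared by all lines, and a plot residual. No genotype×environment
  interaction is generated (it is confounded with error in the trial
  design) and no epistasis.
* **Study conditions.** 65 lines from a 12-founder breeding pedigree
  (crosses biased toward recent material, giving the strong familial
  relatedness of a real panel), 9 environments, environment and residual
  variances 7.3 and 3.1 (flour-yield percentage points squared), a kernel
  locus worth 3 trait units, and 12 additive QTLs with per-allele effects
  1.5–2.7. Printed per-allele effects of that size are only compatible
  with a genotypic variance near 6.5 if the QTL alleles are minor-ish, so
  founder frequency at QTL markers defaults to 0.15 (the mapped QTLs' own
  MAFs run 0.12–0.39) with a 0.8 polygenic remainder; realized H² then
  averages ≈ 0.40 across seeds with single-trial spread of roughly ±0.2.
* **LD blocks.** Founder genotypes are drawn at linkage equilibrium, which
  cannot produce LD blocks at any realistic map density; but a mapped QTL
  allele in a breeding panel rides on a shared ancestral haplotype. Each
  QTL therefore sits in a dense local cluster (8 markers over 0.8 cM)
  whose founder haplotypes tag the QTL allele — one ancestral haplotype
  per allele with 5% per-founder flips standing in for ancestral
  recombination and genotyping error. Block sizes in the synthetic panel
  (≈0.3–2 cM) sit at the dense end of the 0.5–23.5 cM range such panels
  show.
* **Missing data.** 2% of panel calls are masked at random (never at QTL
  or kernel markers, whose values define the simulated trait), so the
  imputation stage operates on realistic input.
* **Contig triplets.** Three homoeologous sequences from a common ancestor
  with independent substitutions at half the pairwise divergence per
  branch; the target SNP site is held invariant across genomes, and for
  positive divergence the triplet is resampled (bounded retries) until a
  genome-discriminating site exists within 200 bp on each side of the SNP.
  At divergence 0 genome-specific design correctly becomes impossible.

What passing tests on this generator do **not** show about real data:
genotyping-platform artefacts, multi-allelic markers (SSRs are assumed
pre-split into presence/absence pseudo-markers), selection and drift
across cycles, genotype×environment interaction, population structure
beyond familial relatedness, and real homoeolog divergence profiles
(indels in particular — the primer designer requires pre-aligned,
equal-length contigs and refuses otherwise).

## Marker design

Alignment search (Biopython local alignment, match +1, mismatch −2, gap
open −5, extend −1, minimum score 0.6× probe length) stands in for a
BLASTN screen: it admits ~97%-identical homoeologs and rejects unrelated
sequences. The contig containing the probe as an exact substring is the
target genome.

GSP design places each primer's 3'-terminal base exactly on a
genome-discriminating site. This is deliberately stronger than "overlap a
discriminating site": under the binding rule below, an internal mismatch
alone does not prevent priming, so only a 3'-terminal discriminating base
guarantees the off-genomes yield zero bands. Primers are 18–26 nt, the SNP
sits at 1/3 ± 0.1 of the amplicon (either orientation; nearest-site
candidates tried first, deterministically), amplicons span 150–600 bp.

ASPs end on the SNP and carry a fixed transversion substitution
(A→C, C→A, G→T, T→G) at the third base from the 3' end — one engineered
mismatch against the matching allele, two (including the 3' terminus)
against the other. The original mismatch-choice recipe is a
strong/weak-pairing heuristic from the KASP literature; the deterministic
transversion map is adopted for reproducibility. Because the ASP 3' end is
pinned to the SNP, length (15–32 nt) is its only Tm lever, hence the wider
length range than GSPs.

Melting temperatures use the nearest-neighbour model with 50 mM
monovalent cation, 1.5 mM Mg²⁺ (the assay buffer), 200 nM primer and the
Owczarzy 2008 magnesium correction; under these parameters 18–26-mers land
in the 55–65 °C design window, and the reported annealing program is
55–62 °C. The in-silico PCR binding rule — 3'-terminal base exact, ≤ 1
mismatch in the 3'-terminal 5 bases, ≤ 3 overall, no gaps, products ≤ 2 kb
— is an engineering contract, not thermodynamics; it is checked against a
brute-force per-offset scan. On 200 simulated triplets (1 kb, 3%
divergence) design plus validation passes ≈ 94%, and every pass obeys the
two-band/one-band genotyping contract; failures are either Tm-infeasible
SNP contexts or genuinely off-target-prone designs that validation
correctly rejects.

## DH validation and prediction

Allele-mean tests are two-sided pooled-variance t-tests (the original
analysis names only a generic t-test; pooled is the standard choice for
balanced DH classes), with the focal parent's allele class reported first
and monomorphic markers yielding blank cells. The combined ("total")
regression includes population-specific intercepts to absorb the mean
differences between crosses — the interpretation adopted for "combined
populations", computable without intercepts via a flag. Markers without
variation among complete-data lines are excluded per fit with a warning;
rank-deficient designs raise an error naming the collinear markers. On
simulations where marker effects differ between genetic backgrounds,
per-population models beat the combined model on pooled prediction
accuracy in ≥ 80% of replicates, the behaviour that motivates fitting per
cross.

## Numerical conventions

Sequence offsets are 0-based half-open internally and 1-based inclusive in
human-readable reports. Genotype codes are {0, 1, −1 = missing}
throughout; readers reject any other token. All stochastic routines take
explicit seeds; nothing uses global random state, and the CLI pipeline is
byte-reproducible given a seed. Problem sizes in the test suite and
acceptance script (50–200 replicates, 1 000–1 200 markers, panels of 65,
DH populations of 150) were chosen as the smallest sizes at which the
studied properties have comfortable Monte-Carlo margins.
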