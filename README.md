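# pedqtl

Pedigree-based association mapping and PCR-marker validation for inbred
crop panels.

Breeding programs accumulate favourable alleles long before anyone maps
them. When a panel of lines related to an elite variety — its ancestors,
sibs and derived material — has been phenotyped across environments,
association mapping inside that panel can recover the quantitative trait
loci (QTLs) behind the elite trait, trace where each allele entered the
pedigree, and hand the breeder cheap PCR markers for selection. `pedqtl`
implements that workflow end to end for fully inbred material (the
motivating case is flour yield in soft winter wheat, a hexaploid), together
with a synthetic breeding-population generator so every stage is testable
without private trial data.

## The models

**Phenotype structure.** Replicate plots are averaged per (genotype,
environment) cell and a two-way random-effects ANOVA decomposes the cell
means via expected mean squares:

    σ̂²_ε = MS_err,  σ̂²_G = (MS_G − MS_err)/e,  σ̂²_E = (MS_E − MS_err)/g

with broad-sense heritability H² = σ²_G / (σ²_G + σ²_E + σ²_ε). The
per-accession mean over environments is the genotypic value used for
mapping.

**Association scan.** Per marker the kinship mixed model

    y = μ + β_k·kernel + β_m·x + u + ε,   u ~ N(0, σ²_g K),  ε ~ N(0, σ²_e I)

is fitted, where K is a marker-derived (allele-sharing, min-rescaled)
kinship matrix, the kernel-texture indicator (0 soft / 1 hard — a major
milling-trait covariate) is a fixed effect, and x ∈ {0, 1} since lines are
inbred, so β_m is the full homozygote substitution effect. The variance
ratio comes from REML via a one-time spectral decomposition of K under the
null model and is reused across markers; multiple testing uses Storey
q-values (smoother π₀ estimate), with the liberal q < 0.5 threshold of the
original workflow. Significant markers are grouped into QTLs per
(consensus map, linkage group) by merging neighbours within 15 cM.

**Pedigree tracing.** Around each QTL, a run of map-adjacent markers with
all adjacent-pair r² ≥ 0.7 is an LD block; pedigree members whose block
genotype matches the focal line (similarity ≥ 0.9) are carriers, and
carrier-only paths up the pedigree identify the introducing ancestor.

**Marker conversion.** An array SNP becomes a gel-readable assay by
aligning its probe against the three homoeologous contigs (A/B/D
subgenomes), anchoring a genome-specific primer pair (GSP) on sites where
the target genome differs from both homoeologs with the SNP at ~1/3 of the
amplicon, and adding two allele-specific primers (ASP) that end on the SNP
and carry an artificial transversion at the third base from the 3' end.
In-silico PCR predicts the read-out: two bands when the template matches
the reaction's ASP allele, one when it does not, none on the wrong
subgenome.

**Validation.** Doubled-haploid (DH) populations from crosses with the
focal line test each QTL by a pooled t-test between allele-class means and
feed multiple-regression trait prediction, fitted per population
("each") or on the combined populations with population intercepts
("total").

## Worked example

```sh
python examples/01_heritability.py
```

```
variance components: genotype 6.513, environment 7.268, residual 3.143
broad-sense heritability H^2 = 38.5%
-> about 38.5% of phenotypic variance across environments is genotypic;
   the trait is usable for selection but strongly environment-driven.

simulated 65x9 trials with components (6.5, 7.3, 3.1):
mean recovered H^2 over 200 replicates = 0.389 (truth 0.385)
```

The three variance components come from just three published numbers
(MS_G = 61.76 with F = 19.65, hence MS_err = 3.143, and MS_E = 475.57) for
65 accessions in 9 environments; the simulation confirms the estimator
recovers the truth on average. The remaining scripts in `examples/` walk
through panel simulation (`02`), the kernel-corrected kinship scan and QTL
classification (`03`), LD-block origin tracing (`04`), PCR-marker design
with in-silico validation (`05`), and DH validation with marker-based
prediction (`06`).

The same stages are runnable from a shell:

```sh
pedqtl --out run1 --seed 5 all        # simulate -> ... -> validate-dh
pedqtl --out run1 gwas                # or stage by stage
```

Every stage writes delimited-text reports plus a provenance sidecar
(config hash, seed, version); reruns with the same seed are byte-identical.

## Layout

```
src/pedqtl/
  core.py      shared containers (genotypes, maps, phenotypes, pedigree)
  io.py        delimited text / FASTA / newick readers and writers
  sim.py       synthetic breeding-population generator
  pheno.py     ANOVA, variance components, heritability, correlations
  assoc.py     filtering, kNN imputation, PCA, UPGMA, kinship, MLM, q-values
  qtl.py       QTL classification, LD blocks, pedigree origin tracing
  primers.py   homoeolog search, GSP/ASP design, in-silico PCR
  dh.py        DH allele-mean tests and marker regression prediction
  studies.py   replicated operating-characteristic studies
  cli.py       thin subcommand pipeline over the library
```

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
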