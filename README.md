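# pleioscape

Genome-by-phenome 3D landscapes from GWAS summary statistics.

A genome-wide association study (GWAS) relates many variants to one
phenotype; a phenome-wide association study (PheWAS) relates one variant to
many phenotypes. Researchers hunting pleiotropy — one locus driving several
traits — need both at once: many variants x many phenotypes. `pleioscape`
builds that combined view from summary statistics alone (no genotypes
anywhere): each phenotype's Manhattan plot becomes one ribbon of a 3D
landscape with chromosomes or chromosome segments on x, −log₁₀(p) on y and
the phenotypes stacked along z, plus a flyover heatmap projection. It is
aimed at statistical geneticists triaging multi-trait summary data — e.g. a
lipid panel (HDL, LDL, triglycerides, total cholesterol) — before committing
to formal colocalization or local genetic-correlation analyses.

## What it computes

* **Entire-genome view** — for each chromosome c and phenotype t, only the
  peak association is kept: argmax over SNPs of −log₁₀(p) within any chosen
  significance *stratum* [lo, hi) (a "sectional view" of the landscape,
  e.g. [100, ∞)).
* **Single-chromosome view** — the chromosome is partitioned into base-pair
  segments (fixed width, default 1 Mb, so segment *k* covers
  [k·10⁶ + 1, (k+1)·10⁶]; or population LD blocks from a BED file). A
  segment is displayed iff some phenotype has a peak with −log₁₀(p) > 6
  (configurable), and within a displayed segment each phenotype contributes
  its single highest peak.
* **Gene annotation** — SNP → gene by interval overlap against a
  user-supplied gene BED, with a ±100 kb window; the binary gene-view
  heatmap marks which phenotypes share above-threshold SNPs in the same
  gene with uniform brightness.
* **LD analytics from summary stats only** — given a pairwise LD source
  (offline PLINK-style `.ld` table, or an Ensembl-compatible REST service):
  the SNPs linked to a displayed lead (r² ≥ 0.75 and D′ ≥ 0.75 by default),
  the mutual-LD SNPs shared between phenotypes, the linked proportion
  |linked ∩ significant| / |significant|, and recursive *SNP thinning* —
  clumping without genotypes: take the top SNP, drop everything in LD with
  it, recurse to a chosen depth to surface independent signals buried under
  the main peak.
* **Concordance categories** — an externally reported lead SNP is classified
  against the displayed segment peak: **A** identical, **B** in LD with it
  (r² > 0.75 and D′ > 0.75), **C(k)** surfaced by thinning at depth k, else
  unmatched.
* **Regional export** — any segment or range across all phenotypes as a wide
  TSV of per-trait (beta, se, −log₁₀ p) triplets, the input layout of
  multi-trait colocalization tools.

P-values are parsed from their string form with arbitrary-precision decimal
arithmetic, so values far below double range (`1.6e-320`) keep their exact
−log₁₀(p) instead of collapsing to infinity.

## Worked example

The bundled generator plants known loci in a 4-trait lipid-like study
(`examples/` has one script per capability). Running
`python examples/01_prepare_landscape.py` followed by
`python examples/03_ld_and_thinning.py` prints:

```
harmonized table: 17643 records, phenotype axis ['HDL', 'LDL', 'TG', 'TC']
genome view: 88 (chromosome, phenotype) peaks
  chr19 HDL: top SNP rs19s45L -log10(p)=25.0  (planted lead recovered)
  chr19 LDL: top SNP rs19s45L -log10(p)=60.0  (planted lead recovered)
  ...
HDL: lead rs19s45L, SNPs in LD: ['rs19s45S0', ..., 'rs19s45S4']
  linked proportion = 0.50 (5 linked of 10 genome-wide-significant SNPs)
mutual LD SNPs across ['HDL', 'LDL', 'TC']: ['rs19s45S0', ...]
thinning (HDL): leads ['rs19s45L', 'rs19s45X', 'rs19s45W1']
reported SNP rs19s45L: category A
reported SNP rs19s45S0: category B
reported SNP rs19s45X: category C(2)
```

Reading: the pleiotropic chr19 locus (segment 45, an APOE-region analog) is
the genome-level peak for three of four traits; five satellite SNPs are in
LD with the displayed lead and shared across those traits; half of the ten
genome-wide-significant SNPs in the segment are linked to the lead; thinning
at depth 2 surfaces `rs19s45X`, an independent signal completely hidden
behind the main peak in every 2D view; and the three reported SNPs fall into
categories A, B and C(2) exactly as planted.

The same workflow is available from a shell:

```sh
pleioscape simulate --phenotypes 4 --seed 1 --out study/
pleioscape prepare  --config config.yaml --out landscape.tsv
pleioscape plot     --table landscape.tsv --chrom 19 --section 6.5:inf \
                    --genes study/genes.bed --out chr19.html
pleioscape export   --table landscape.tsv --chrom 19 --segment 45 --out region.tsv
pleioscape thin     --table landscape.tsv --ld-table study/ld_table.tsv \
                    --chrom 19 --segment 45 --phenotype LDL --depth 2
```

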