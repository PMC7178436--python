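# Methods

## The landscape model

The package operates entirely on GWAS *summary statistics*: per-SNP effect
size, standard error and p-value, one file per phenotype, no individual-level
genotypes. The core object is a long-format table of
(phenotype, snp_id, chrom, pos, −log₁₀ p, effect, se, alleles) rows over
autosomes 1–22. Everything downstream is peak selection under two reductions:

* **genome level** — argmax of −log₁₀(p) per (chromosome, phenotype);
* **chromosome level** — argmax per (segment, phenotype), where segments are
  fixed-width bins or externally defined LD blocks, and a segment is shown
  only if some phenotype's peak exceeds a display threshold.

Both reductions can be restricted to a *stratum*, a half-open significance
interval [lo, hi) on the −log₁₀(p) axis. Half-open intervals were chosen so
that adjacent strata partition the data exactly: merging per-stratum grids
cell-wise by max reproduces the unstratified grid, a property the test suite
checks directly. A user request like "the section above 100" maps to
[100, ∞).

Assumptions inherited from the summary-statistics setting: p-values are
taken as published (no re-weighting by sample size, no multiple-testing
adjustment — the tool visualizes, it does not adjust); effect sizes are
displayed as given (beta or odds ratio, flagged, never log-transformed);
allele harmonization across studies is out of scope, records are kept
verbatim per input file.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| segment width | 1,000,000 | bp | the conventional megabase bin for locus bookkeeping; segment k is [k·10⁶+1, (k+1)·10⁶], so "region 45" of chr19 covers 45,000,001–46,000,000 |
| retention threshold | 6.0 | −log₁₀(p) | just below genome-wide significance (5·10⁻⁸ ≈ 7.3); strict `>` comparison |
| sectional stratum | [0, ∞) | −log₁₀(p) | full view unless the user selects a band |
| gene window | 100,000 | bp | the window large lipid consortia use when assigning SNPs to genes |
| LD display thresholds | r² ≥ 0.75, D′ ≥ 0.75 | — | "reaching" semantics for pop-up membership |
| LD category-B thresholds | r² > 0.75, D′ > 0.75 | — | strict semantics for concordance categorization; the two rules are deliberately distinct |
| thinning depth cap (categorizer) | 3 | levels | buried signals deeper than 3 independent leads per megabase are rare; depth is user-settable everywhere else |

Tie-breaking for equal −log₁₀(p) is deterministic everywhere: smaller
position wins, then lexicographically smaller snp_id. This makes repeated
runs bit-identical, which the oracle-equivalence tests rely on.

## Coordinates and formats

Internal coordinates are 1-based closed. BED inputs (LD blocks, gene
intervals) are 0-based half-open and converted at the reading boundary only
— `segmentation.blocks_from_bed` and `annotation.load_gene_intervals`; no
other module performs conversions. Positions falling in gaps between LD
blocks have no segment: they are excluded from chromosome grids (and
counted) but remain visible in the genome view.

P-values are parsed from their string representation using
`decimal.Decimal.log10()` at 50-digit precision before any float conversion.
This is what keeps −log₁₀(p) exact for values below the smallest normal
double (p ≈ 1e-308): `1.6e-320` yields 319.79588…, not infinity. The test
suite compares against an independent arbitrary-precision oracle (sympy) to
1e-9 down to p = 1e-350.

## LD backends

LD comes through a small query contract (lead, candidates) → (r², D′) pairs,
with two implementations:

* an **offline table backend** over PLINK-style `.ld` files
  (`CHR_A BP_A SNP_A CHR_B BP_B SNP_B R2 [DP]`), symmetrized on load — the
  backend used by all tests;
* an **Ensembl-compatible REST client** (stdlib urllib) for live lookups,
  excluded from the test suite because live LD snapshots are not
  reproducible.

SNPs unknown to the backend count as "not in LD" — a conservative choice:
an unknown SNP can never be removed by clumping, so it can still surface
through thinning rather than silently disappearing. If a table lacks the D′
column, the D′ threshold check is skipped for those pairs (r² still
applies); tables written by the bundled generator always carry D′. Thinning
removes *all* in-segment records in LD with the current lead, significant or
not: removal is about signal membership, not display.

## The synthetic study generator

The generator emulates the input side of a multi-trait lipid study: one
summary file per phenotype (default panel HDL/LDL/TG/TC), a gene BED and a
pairwise LD table, with a truth record of every planted signal. Defaults:
500 background SNPs per chromosome (tests and the reproduction script use
60–200 to keep runs fast; the structure, not the count, carries the signal),
chromosome length 50 Mb, background −log₁₀(p) uniform on [0, 3) so
background can never cross the display threshold of 6, and planted loci:

* leads with declared per-phenotype significance (25–60 in the demo);
* strong satellites at r² = D′ = 0.9 (pop-up members, category B) and weak
  satellites at 0.3 (excluded by both thresholds), each below its lead;
* optional buried secondary leads at r² = 0.05 to the primary, placed in the
  significance band between the weak satellites (≤ 9.5) and the primary
  lead, so thinning must surface them at exactly depth 2.

Background positions never fall inside a planted segment, making planted
truth unambiguous: a displayed cell in a planted segment must be the planted
lead. Significance is generated directly on the −log₁₀ scale and printed as
scientific-notation p-value strings (10-digit mantissa), so re-ingestion
exercises the string parser; round-trip error is below 1e-8. A stress
variant (`background_max=7.0`) lets background cross the retention
threshold for robustness tests of the retention rule itself.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: realistic allele frequencies and effect-size
distributions, LD decay with distance (LD is declared pairwise, not derived
from a recombination map), overlapping-sample correlation between traits,
population stratification, and genome-scale SNP density (~2.5 M SNPs per
trait in real lipid consortium files). Results on real data additionally
depend on the gene-annotation snapshot and LD reference panel chosen, which
is why concordance counts against published locus lists are expected to
shift with those resources.

## Numerical and degenerate-input choices

* Empty chromosome grids are valid (the view renders nothing) rather than
  errors; empty figure specs carry a warning string.
* The linked proportion with zero significant candidates is `None`
  (undefined), never 0 — 0 would claim "nothing is linked" on no evidence.
* Heatmap cells with no record hold NaN, distinct from a genuine
  −log₁₀(p) = 0.
* Duplicate (snp_id, chrom, pos) rows within one file keep the most
  significant record; all drop paths (non-autosomal, unparseable,
  duplicates) are counted and the counts satisfy an exact conservation
  identity.
* A backend transport failure during thinning returns the partial lead list
  with an error flag instead of discarding completed work.

## Design choices where the design was open

* The 3D landscape is per-phenotype ribbons (line + markers), not an
  interpolated surface: a missing (segment, phenotype) cell must appear as a
  gap, and surface interpolation would invent data.
* Retention (> threshold) applies to segments, not cells: in a retained
  segment every phenotype's top in-stratum peak is shown even below
  threshold, because cross-trait context is the point of the view. The
  genome-level view applies no floor at all.
* Hover payloads join multiple overlapping gene symbols with ";" instead of
  truncating to one: gene-dense regions overlap several genes and silent
  truncation would misannotate.
* The HTML export embeds the figure data as canonical JSON (sorted keys)
  plus a small hand-written canvas renderer, so the file is self-contained,
  opens offline, and the data payload is byte-identical across runs.
* Gene annotation is a user-supplied file, not a live service, keeping runs
  hermetic and pinning the annotation snapshot explicitly.

## Problem sizes used by tests and the reproduction script

Unit and property tests run on studies of 60–200 background SNPs per
chromosome over 22 chromosomes (≈5k–18k rows across 4 phenotypes) and on
random tables of 300–2,000 rows; `scripts/acceptance.py` measures 20
simulated studies, 50 random grid fixtures, 10 partition fixtures and 1,050
parser points. These sizes were chosen so the full suite completes in well
under a minute while every code path (retention, strata, thinning depth,
categorization, export) is exercised; the quantities measured are
rates and mismatch counts, which are size-independent by construction.

## Known limitations

* No allele harmonization or build liftover; inputs must share a genome
  build (metadata records the label, nothing validates it).
* Sex chromosomes and non-numeric contigs are dropped.
* The REST LD backend is functional but untested against a live service in
  this repository; the offline table backend is the reference path.
* Colocalization and local genetic correlation are consumers of the regional
  export, not features of this package.
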