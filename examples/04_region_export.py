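"""Regional export: hand a shared locus to colocalization tools.

Selects the pleiotropic 1 Mb segment of the simulated study and exports its
summary statistics across all phenotypes as one wide TSV (per-phenotype
beta/se/-log10 p triplets), the layout multi-trait colocalization methods
consume.
"""

import tempfile
from pathlib import Path

import pleioscape as ps
from pleioscape.pipeline import ingest_study

out = Path(tempfile.mkdtemp(prefix="region_demo_"))
study = ps.synthetic.simulate_study(seed=1, out_dir=out, background_snps_per_chrom=200)
table = ingest_study(study)

locus = study.truth["loci"][0]
sel = ps.RegionSelection(chrom=locus["chrom"], segment=locus["segment"],
                         scheme=ps.fixed_bins(1_000_000))
path = out / "region.tsv"
counts = ps.export_region(table, sel, path)
chrom, start, end = sel.resolve()
print(f"exported chr{chrom}:{start}-{end} to {path}")
for pheno, n in counts.items():
    print(f"  {pheno}: {n} records")

back = ps.read_region_export(path)
print(f"re-imported {len(back)} long-format records "
      f"({back['snp_id'].nunique()} distinct SNPs)")
# A phenotype with 0 records has no association data in the region; its
# columns stay blank so the colocalization tool can decide how to handle it.
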