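"""Simulate a two-garden bisulfite cohort and write it as a fixture.

Builds a small synthetic genome (3 chromosomes; the last carries a
3-gene sex-determining-region panel whose middle gene is the planted
sex-linked gene), simulates 12 xylem methylomes (3 female + 3 male
genotypes, cloned at two gardens) and writes Bismark-style call files,
a GFF3 annotation and a metadata table.
"""

import tempfile
from pathlib import Path

import methylsex as mx

layout = mx.build_genome(
    n_chrom=3, chrom_length=30_000, genes_per_chrom=2, sdr_panel_size=3, seed=1
)
effects = mx.default_effects(layout, n_weak_background=2, seed=2)
cohort = mx.CohortSpec(n_female=3, n_male=3, seed=3)
samples = mx.simulate_cohort(layout, cohort, effects)

out = Path(tempfile.mkdtemp(prefix="methylsex_fixture_"))
manifest = mx.write_fixture(samples, layout, out)

print(f"planted sex-linked gene: {layout.sdr_gene_id} on {layout.sdr_gene.chrom}")
print(f"{len(samples)} samples x {len(samples[0].calls)} cytosine calls each")
print(f"{len(manifest)} files written to {out} "
      f"({len(samples)} call files + GFF3 + metadata)")
s = samples[0]
cov = s.calls["meth"] + s.calls["unmeth"]
print(f"example sample {s.sample_id}: sex {s.sex}, median coverage "
      f"{int(cov.median())}x, mean CG methylation "
      f"{s.calls.loc[s.calls.context == 'CG', 'meth'].sum() / cov[s.calls.context == 'CG'].sum():.2f}")
# The planted gene makes males hypermethylated at its promoter and first
# intron; everything else is genome-wide background.
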