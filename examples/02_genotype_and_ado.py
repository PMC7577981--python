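"""Call genotypes from raw read counts and estimate the allele-dropout rate.

Simulates per-cell depth/alt counts for 3 somatic loci plus a 10-locus panel
of germline-heterozygous SNPs (the standard ADO ruler), applies the depth/VAF
filter (DP >= 10, alt >= 3, VAF >= 15% at 20-99x / 10% at >= 100x), and
recovers the dropout rate from the SNP calls.
"""

import numpy as np

import clonalevo as ce
from clonalevo.containers import GenotypeMatrix, HET
from clonalevo.genotyping import sample_qc

n_cells, n_snps = 5000, 10
somatic = np.zeros((n_cells, 3), dtype=np.int8)
somatic[: n_cells // 2, 0] = HET          # trunk mutation in 50% of cells
somatic[: n_cells // 5, 1] = HET          # subclonal hit in 20%
snps = np.full((n_cells, n_snps), HET, dtype=np.int8)

truth = GenotypeMatrix(
    np.hstack([somatic, snps]),
    locus_ids=("NPM1 p.L287fs", "NRAS p.G12D", "FLT3-ITD",
               *[f"SNP{i}" for i in range(n_snps)]),
)
reads = ce.simulate_read_counts(
    truth, mean_depth=48, ado=0.058, seed=21,
    locus_class=("somatic",) * 3 + ("snp",) * n_snps,
)
genotypes = ce.call_genotypes_from_reads(reads)
qc = sample_qc(reads, genotypes)

print(f"estimated ADO rate : {qc.ado_rate:.4f}  (simulated at 0.058)")
print(f"mean depth         : {qc.mean_depth.mean():.1f}x")
print(f"missing fraction   : {qc.missing_fraction.mean():.4f}")
print(f"pooled scVAF, NPM1 : {ce.compute_scvaf(reads, 'NPM1 p.L287fs'):.4f} "
      "(50% het clone -> expect ~0.25)")

# The ADO estimate feeds the phylogeny error model as the false-negative
# rate; the pooled scVAF is the quantity compared against bulk VAF.
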