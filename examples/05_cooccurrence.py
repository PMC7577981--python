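"""Cell-level mutation co-occurrence and mutual exclusivity.

Simulates a sample where two RAS-pathway mutations occupy disjoint clones
(mutual exclusivity) while a trunk mutation co-occurs with both, then runs
the pairwise Fisher/odds-ratio analysis.
"""

import numpy as np

import clonalevo as ce
from clonalevo.containers import GenotypeMatrix, HET

rng = np.random.default_rng(51)
n = 6000
codes = np.zeros((n, 3), dtype=np.int8)
codes[: n // 2, 0] = HET              # DNMT3A trunk in 50% of cells
codes[: n // 4, 1] = HET              # NRAS in one half of the trunk
codes[n // 4 : n // 2, 2] = HET       # KRAS in the other half
# sprinkle platform noise
flip = rng.random(codes.shape) < 0.01
codes[flip & (codes == 0)] = HET

result = ce.cell_cooccurrence(
    GenotypeMatrix(codes, locus_ids=("DNMT3A", "NRAS", "KRAS"))
)
print(result[["mutation_a", "mutation_b", "a", "b", "c", "d",
              "log_or", "q_value"]].to_string(index=False))

# Positive log2 odds ratios mark co-occurrence (DNMT3A with each RAS hit),
# strongly negative ones mark mutual exclusivity (NRAS vs KRAS, the classic
# pattern of functionally redundant drivers); q is the BH-adjusted Fisher p.
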