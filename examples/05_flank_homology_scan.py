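"""Scanning CNV breakpoint flanks for recombination-capable homology.

Builds a random reference, plants a 1.2 kb ~95%-identity copy near both
breakpoints of one CNV out of ten, and scans each CNV's two 10 kb flank
windows for stretches of >=1 kb at >90% identity.  Only the engineered CNV
is flagged: deletions formed by homologous recombination would show such
flank homology, those formed by nonhomologous mechanisms do not.
"""

import numpy as np

from cnvstress.core_io import CnvCall, Genome
from cnvstress.junction_analysis import flank_homology_fraction
from cnvstress.synthetic_data import simulate_reference

genome = simulate_reference({"chrA": 1_200_000}, seed=4)
cnvs = [
    CnvCall("c", "WT", 0.6, "chrA", 30_000 + i * 100_000,
            80_000 + i * 100_000, "deletion")
    for i in range(10)
]

# plant a degenerate copy of CNV 0's left-flank sequence at its right flank
seq = genome.sequence["chrA"]
rng = np.random.default_rng(9)
copy = list(seq[cnvs[0].start - 3_000 : cnvs[0].start - 1_800])
for i in rng.choice(1_200, 60, replace=False):
    copy[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[i]]
edited = seq[: cnvs[0].end + 1_000] + "".join(copy) + seq[cnvs[0].end + 2_200 :]
genome = Genome(("chrA",), {"chrA": len(edited)}, {"chrA": edited})

result = flank_homology_fraction(cnvs, genome, window=10_000,
                                 min_len=1_000, min_ident=0.90)
print(f"CNVs with qualifying flank homology: {sum(result.flags)}/{len(result.flags)}"
      f" ({100 * result.fraction:.1f}%, "
      f"95% CI {100 * result.ci_low:.1f}-{100 * result.ci_high:.1f}%)")
print("per-CNV flags:", list(result.flags))
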