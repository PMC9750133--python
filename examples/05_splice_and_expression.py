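"""Splice-ratio, RPKM and relative-expression quantification.

Simulates junction-spanning reads from an intron-containing gene at a 72%
spliced fraction, classifies them against explicit junction references, and
prints the recovered fraction and spliced:unspliced ratio (72% corresponds
to roughly 3:1). Then shows RPKM normalisation and a delta-delta-Ct fold
change computed from synthetic Ct values.
"""

import numpy as np

from organedit import CtMeasurement, JunctionReference, relative_expression, rpkm, splice_ratio
from organedit.quantify import simulate_junction_reads

rng = np.random.default_rng(3)
ex1 = "".join(rng.choice(list("ACGT"), size=150))
intron = "".join(rng.choice(list("ACGT"), size=120))
ex2 = "".join(rng.choice(list("ACGT"), size=150))
j = JunctionReference(
    gene="petB_like",
    spliced_seq=ex1 + ex2, spliced_junction=len(ex1),
    unspliced5_seq=ex1 + intron, unspliced5_junction=len(ex1),
    unspliced3_seq=intron + ex2, unspliced3_junction=len(intron),
)

reads = simulate_junction_reads(j, 6000, spliced_fraction=0.72, read_length=100, seed=4)
counts = splice_ratio(reads, j, total_mapped=len(reads))
print(f"junction reads: {counts.spliced} spliced, {counts.unspliced} unspliced")
print(f"fraction spliced: {100 * counts.fraction_spliced:.1f}%   "
      f"ratio: {counts.ratio:.2f}:1 (simulated 72%; roughly three spliced "
      "reads per unspliced read)")

print(f"\nRPKM of a 1 kb transcript with 10 reads in a 1M-read library: "
      f"{rpkm(10, 1000, 1_000_000):.1f}")

target = [CtMeasurement(s, "transgene", [ct]) for s, ct in
          [("moderate#1", 24.0), ("moderate#2", 23.5), ("strong#1", 20.4)]]
ref = [CtMeasurement(s, "ACTIN", [18.0]) for s in
       ("moderate#1", "moderate#2", "strong#1")]
df = relative_expression(target, ref)  # calibrator = lowest-expressing sample
print("\nddCt fold changes (calibrator auto-selected as highest dCt):")
print(df.round(2).to_string())
print("The strong promoter drives ~12-fold higher transgene expression here.")
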