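"""Count off-targets in the packaged editing tables.

Loads the packaged site-by-library editing-percentage tables and applies the
discovery filter (edited to >= 5% in at least one factor-expressing library,
zero in the wild type). The counts printed — 31 chloroplast off-targets
beyond the focal site, per-library tallies rising with expression strength,
and the 24-site >=10% target panel — show how off-target breadth tracks the
expression level of the editing factor.
"""

from organedit import filter_matrix, load_fixtures, per_library_counts
from organedit.discovery import classify_affinity
from organedit.fixtures import (
    ARABIDOPSIS_TARGETS,
    TABLE2_LIBRARIES,
    TABLE2_MODERATE_LIBRARIES,
    TABLE2_OVEREXPRESSION_LIBRARIES,
)

fx = load_fixtures()
t2 = fx.table2

filtered = filter_matrix(t2, TABLE2_LIBRARIES, wt_column="WT", threshold=5.0)
cp = filtered[filtered.genome == "cp"].drop("ndhB-291")
print(f"total off-target rows (cp + mt): {len(filtered)}")
print(f"chloroplast off-targets beyond the focal site: {len(cp)}")
for lib, n in per_library_counts(cp, TABLE2_LIBRARIES).items():
    print(f"  {lib:<18} {n:>3} sites >= 5%")

tobacco_10 = set(t2.index[t2[list(TABLE2_LIBRARIES)].max(axis=1) >= 10.0])
panel = tobacco_10 | set(ARABIDOPSIS_TARGETS)
print(f"\n>=10% target panel (tobacco union endogenous, shared site once): {len(panel)}")

classes = classify_affinity(
    t2, TABLE2_MODERATE_LIBRARIES, TABLE2_OVEREXPRESSION_LIBRARIES
)
high = sorted(s for s, c in classes.items() if c == "high")
print(f"high-affinity sites (edited at moderate expression): {', '.join(high)}")
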