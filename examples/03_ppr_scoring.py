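"""Score cis-elements against a PPR protein's predicted binding site.

Constructs a 15-motif PLS-type editing factor, predicts its per-motif base
preferences from the two-amino-acid PPR code, anchors the last motif at
position -4 from the edited cytidine, and scores two cis-elements: one built
to satisfy every predictable position and one carrying two deliberate
violations. Mismatch totals count only positions where the code makes a
prediction (n.p. positions are excluded).
"""

from organedit import (
    CisElement,
    CodeTable,
    anchor_alignment,
    degenerate_consensus,
    frequency_matrix,
    predict_binding,
    score_cis_element,
)
from organedit.pprcode import PprMotif, PprProtein, QED1_MOTIF_CLASSES

# A synthetic motif array with the canonical 15-motif PLS structure;
# TN (position 5 = T, last = N) predicts adenosine at every repeat.
protein = PprProtein(
    id="demo_factor",
    motifs=[
        PprMotif(index=i + 1, mclass=c, aa5="T", aaLast="N")
        for i, c in enumerate(QED1_MOTIF_CLASSES)
    ],
)
code = CodeTable.default()
prediction = predict_binding(protein, code)
print("per-motif predictions:",
      " ".join("".join(sorted(p)) if p else "np" for p in prediction))

perfect = CisElement("perfect", "A" * 20 + "C" + "AAAAA")
violated = CisElement("violated", "A" * 8 + "G" + "A" * 5 + "G" + "A" * 5 + "C" + "AAAAA")
for cis in (perfect, violated):
    anchoring = anchor_alignment(protein, cis)
    card = score_cis_element(cis, prediction, anchoring)
    print(
        f"{cis.site_name:>9}: {card.total_mismatches} mismatches over "
        f"{card.evaluable_positions} evaluable positions"
    )

freqs = frequency_matrix([perfect, violated], span=(-20, 5))
print("degenerate consensus (threshold 0.25):", degenerate_consensus(freqs, 0.25))
print("The consensus fixes C at the edit and marks mixed columns with IUPAC codes.")
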