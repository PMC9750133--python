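"""Packaged editing-percentage tables used as small, exactly known inputs.

Three tables ship with the package as TSV:

* ``table2`` — the 33 chloroplast + mitochondrial off-target sites edited by
  the heterologously expressed Arabidopsis editing factor in tobacco, with
  per-library editing percentages (two moderate-promoter HPL lines, two
  strong-promoter UBQ lines) and the wild-type column;
* ``table4`` — 14 of those sites plus five endogenous control sites assayed
  in three lines expressing the cacao ortholog;
* ``table5`` — the same site panel assayed in a background that
  overexpresses the factor's genuine target transcript (pRB58).

Values are editing efficiencies in percent (T/(T+C) at the site). The five
endogenous Arabidopsis targets of the factor are provided as a constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

_DATA_PACKAGE = "organedit.data"

ARABIDOPSIS_TARGETS = (
    "ndhB-291",
    "matK-214",
    "rpoB-811",
    "accD_3UTR",
    "rps12_i1",
)

TABLE2_LIBRARIES = (
    "HPL::At-QED1#6",
    "HPL::At-QED1#1",
    "UBQ::At-QED1#3",
    "UBQ::At-QED1#1",
)
TABLE2_MODERATE_LIBRARIES = TABLE2_LIBRARIES[:2]
TABLE2_OVEREXPRESSION_LIBRARIES = TABLE2_LIBRARIES[2:]

TABLE4_LIBRARIES = ("UBQ::Tc-QED1#2", "UBQ::Tc-QED1#4", "UBQ::Tc-QED1#5")
TABLE5_LIBRARIES = ("HPL::At-QED1#12", "HPL::At-QED1#17", "UBQ::At-QED1#3")

# Relative transgene mRNA abundance (RPKM of non-organellar reads mapped to
# the factor's coding sequence) per RNA-seq library.
QED1_TRANSGENE_RPKM = {
    "HPL::At-QED1#6": 1.8,
    "HPL::At-QED1#1": 2.8,
    "UBQ::At-QED1#3": 24.3,
    "UBQ::At-QED1#1": 24.7,
    "WT": 0.0,
}


@dataclass(frozen=True)
class PaperFixtures:
    table2: pd.DataFrame
    table4: pd.DataFrame
    table5: pd.DataFrame
    arabidopsis_targets: tuple[str, ...] = ARABIDOPSIS_TARGETS


def _read(name: str, index_col: str) -> pd.DataFrame:
    with resources.files(_DATA_PACKAGE).joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=index_col)


def load_fixtures() -> PaperFixtures:
    """Load the packaged tables, indexed by site name."""
    return PaperFixtures(
        table2=_read("table2.tsv", "site"),
        table4=_read("table4.tsv", "site"),
        table5=_read("table5.tsv", "site"),
    )


def editing_value(table: pd.DataFrame, site: str, library: str) -> float:
    """Editing percentage of one site in one library."""
    return float(table.at[site, library])
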