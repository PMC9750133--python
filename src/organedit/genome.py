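"""Annotated organellar genomes and their on-disk representations.

Coordinates are 1-based inclusive in every file format and public record
(matching the convention of plastome position tables); internal slicing is
0-based half-open and confined to this module's helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError, DataError

# IUPAC codes used by the masked mapping reference.  Y marks a known edited C
# on the plus strand (C or T), R the minus-strand equivalent (A or G).
VALID_ALPHABET = set("ACGTYRN")

FEATURE_TYPES = {
    "CDS",
    "intron",
    "tRNA",
    "rRNA",
    "UTR5",
    "UTR3",
    "intergenic",
    "IR",
}

_COMPLEMENT = str.maketrans("ACGTYRNacgtyrn", "TGCARYNtgcaryn")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware for the masking codes Y/R/N."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeFeature:
    """A single annotated interval (1-based inclusive, stranded).

    ``parent`` links an intron to the transcription unit it interrupts;
    top-level features (no parent) are treated as transcription units by the
    read simulator.
    """

    name: str
    ftype: str
    start: int
    end: int
    strand: str
    parent: str | None = None
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConfigurationError(
                f"feature {self.name}: start {self.start} > end {self.end}"
            )
        if self.strand not in "+-":
            raise ConfigurationError(f"feature {self.name}: bad strand {self.strand!r}")
        if self.ftype not in FEATURE_TYPES:
            raise ConfigurationError(f"feature {self.name}: unknown type {self.ftype!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class KnownEditingSite:
    """A previously documented C-to-U editing site on a reference.

    ``transcript_strand`` is the strand of the edited transcript: a
    plus-strand site sits on a genomic C, a minus-strand site on a genomic G
    (plus-strand projection of the transcript C).
    """

    genome_id: str
    position: int
    transcript_strand: str
    name: str

    def __post_init__(self) -> None:
        if self.transcript_strand not in "+-":
            raise DataError(f"site {self.name}: bad strand {self.transcript_strand!r}")


@dataclass
class OrganelleGenome:
    id: str
    sequence: str
    circular: bool = False
    features: list[GenomeFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise DataError(f"genome {self.id}: invalid characters {sorted(bad)}")
        for f in self.features:
            if f.end > len(self.sequence):
                raise ConfigurationError(
                    f"feature {f.name} extends past genome end ({f.end} > {len(self.sequence)})"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Plus-strand base at a 1-based position."""
        return self.sequence[position - 1]

    def subseq(self, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end] (1-based inclusive), on the given strand."""
        s = self.sequence[start - 1 : end]
        return revcomp(s) if strand == "-" else s

    def features_at(self, position: int) -> list[GenomeFeature]:
        return [f for f in self.features if f.contains(position)]


# ---------------------------------------------------------------------------
# File I/O


def write_fasta(genome: OrganelleGenome, path: str | Path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description="")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path: str | Path, circular: bool = False) -> OrganelleGenome:
    recs = list(SeqIO.parse(str(path), "fasta"))
    if len(recs) != 1:
        raise DataError(f"{path}: expected exactly one FASTA record, found {len(recs)}")
    return OrganelleGenome(id=recs[0].id, sequence=str(recs[0].seq), circular=circular)


def write_gff3(genome: OrganelleGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
        for f in genome.features:
            attrs = f"ID={f.name}"
            if f.parent:
                attrs += f";Parent={f.parent}"
            if f.truncated:
                attrs += ";truncated=true"
            fh.write(
                "\t".join(
                    [
                        genome.id,
                        "organedit",
                        f.ftype,
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[GenomeFeature]:
    features = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise DataError(f"{path}: malformed GFF3 line: {line.rstrip()}")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            features.append(
                GenomeFeature(
                    name=attrs.get("ID", f"{cols[2]}_{cols[3]}"),
                    ftype=cols[2],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6],
                    parent=attrs.get("Parent"),
                    truncated=attrs.get("truncated") == "true",
                )
            )
    return features


def write_sites_bed(sites: Iterable[KnownEditingSite], path: str | Path) -> None:
    """6-column BED (0-based half-open intervals, name, score, strand)."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.genome_id}\t{s.position - 1}\t{s.position}\t{s.name}\t0\t{s.transcript_strand}\n"
            )


def read_sites_bed(path: str | Path) -> list[KnownEditingSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise DataError(f"{path}: BED line needs 6 columns: {line.rstrip()}")
            sites.append(
                KnownEditingSite(
                    genome_id=cols[0],
                    position=int(cols[1]) + 1,
                    transcript_strand=cols[5],
                    name=cols[3],
                )
            )
    return sites


def shift_feature(f: GenomeFeature, offset: int) -> GenomeFeature:
    return replace(f, start=f.start + offset, end=f.end + offset)
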