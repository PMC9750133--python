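"""Customized mapping-reference preparation.

Two transformations are applied before mapping organellar RNA-seq reads:

* known editing sites are replaced by IUPAC ambiguity codes (Y for a
  plus-strand C/T, R for a minus-strand A/G) so that edited and unedited
  reads align with equal score — masking removes the systematic bias a
  plain reference would impose for or against edited reads;
* the second copy of the plastid inverted repeat (IR) is removed, retaining
  a short flank (default 75 nt) on each border, so that IR reads map
  uniquely to the remaining copy.
"""

from __future__ import annotations

from dataclasses import replace

from .errors import ConfigurationError, DataError
from .genome import GenomeFeature, KnownEditingSite, OrganelleGenome

DEFAULT_IR_FLANK = 75


def mask_known_sites(
    genome: OrganelleGenome, sites: list[KnownEditingSite]
) -> OrganelleGenome:
    """Return a copy of ``genome`` with known editing sites masked to Y/R.

    Plus-strand sites (genomic C) become Y, minus-strand sites (genomic G)
    become R. A site whose reference base contradicts its strand raises a
    :class:`DataError` naming the site. Masking is idempotent: an already
    masked base passes the consistency check and is left unchanged.
    """
    seq = list(genome.sequence)
    for site in sites:
        if site.genome_id != genome.id:
            raise DataError(
                f"site {site.name} refers to genome {site.genome_id}, not {genome.id}"
            )
        if not 1 <= site.position <= genome.length:
            raise DataError(f"site {site.name}: position {site.position} out of range")
        base = seq[site.position - 1]
        if site.transcript_strand == "+":
            if base not in ("C", "Y"):
                raise DataError(
                    f"site {site.name}: expected C at +strand position "
                    f"{site.position}, found {base}"
                )
            seq[site.position - 1] = "Y"
        else:
            if base not in ("G", "R"):
                raise DataError(
                    f"site {site.name}: expected G at -strand position "
                    f"{site.position}, found {base}"
                )
            seq[site.position - 1] = "R"
    return OrganelleGenome(
        id=genome.id,
        sequence="".join(seq),
        circular=genome.circular,
        features=list(genome.features),
    )


def unmask_sites(
    genome: OrganelleGenome, sites: list[KnownEditingSite]
) -> OrganelleGenome:
    """Invert :func:`mask_known_sites` given the same site list."""
    seq = list(genome.sequence)
    for site in sites:
        base = seq[site.position - 1]
        if site.transcript_strand == "+" and base == "Y":
            seq[site.position - 1] = "C"
        elif site.transcript_strand == "-" and base == "R":
            seq[site.position - 1] = "G"
    return OrganelleGenome(
        id=genome.id,
        sequence="".join(seq),
        circular=genome.circular,
        features=list(genome.features),
    )


def collapse_inverted_repeat(
    genome: OrganelleGenome,
    ir_interval: tuple[int, int] | None,
    flank: int = DEFAULT_IR_FLANK,
) -> OrganelleGenome:
    """Remove the interior of one IR copy, retaining ``flank`` nt per border.

    ``ir_interval`` is the 1-based inclusive span of the IR copy to collapse
    (which copy is removed is the caller's choice). The removed block is
    ``[start + flank, end - flank]``; features downstream shift left by the
    removed length, features straddling a border are truncated and flagged,
    features fully inside the removed block are dropped. With
    ``ir_interval=None`` the genome is returned unchanged.
    """
    if ir_interval is None:
        return genome
    ir_start, ir_end = ir_interval
    if not (1 <= ir_start <= ir_end <= genome.length):
        raise ConfigurationError(f"IR interval {ir_interval} out of range")
    ir_len = ir_end - ir_start + 1
    if ir_len <= 2 * flank:
        raise ConfigurationError(
            f"IR length {ir_len} must exceed twice the flank ({flank})"
        )
    # removed block, 1-based inclusive
    rm_start = ir_start + flank
    rm_end = ir_end - flank
    removed = rm_end - rm_start + 1
    seq = genome.sequence[: rm_start - 1] + genome.sequence[rm_end:]

    new_features: list[GenomeFeature] = []
    for f in genome.features:
        if f.end < rm_start:  # entirely upstream
            new_features.append(f)
        elif f.start > rm_end:  # entirely downstream: shift
            new_features.append(replace(f, start=f.start - removed, end=f.end - removed))
        elif f.start >= rm_start and f.end <= rm_end:
            continue  # swallowed by the collapse
        elif f.start < rm_start and f.end > rm_end:
            # spans the whole removed block: shrink, flag
            new_features.append(
                replace(f, end=f.end - removed, truncated=True)
            )
        elif f.start < rm_start:  # right end truncated
            new_features.append(replace(f, end=rm_start - 1, truncated=True))
        else:  # left end truncated, shifted
            new_features.append(
                replace(f, start=rm_start, end=f.end - removed, truncated=True)
            )
    return OrganelleGenome(
        id=genome.id, sequence=seq, circular=genome.circular, features=new_features
    )
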