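"""Windowed pairwise sequence similarity around editing sites.

A set of ungapped windows (default -50..+50, 101 nt) anchored at edited
cytidines is compared by mean pairwise identity inside a sliding window
(default 14 nt, step 1). To avoid the trivial contribution of the shared
edited base, either position 0 alone ([C] mode) or positions -1..+1 ([nCn]
mode) are excluded from both numerator and denominator. Profiles are
reported at the window's left-edge offset.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .pprcode import rna

EXCLUSION_OFFSETS = {"C": (0,), "nCn": (-1, 0, 1), None: ()}


@dataclass
class ContextWindowSet:
    """Equal-length RNA windows anchored at an edited C (offset 0)."""

    names: list[str]
    sequences: list[str]
    anchor_index: int = 50

    def __post_init__(self) -> None:
        self.sequences = [rna(s) for s in self.sequences]
        if len(self.names) != len(self.sequences):
            raise DataError("names and sequences differ in length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise DataError(f"window lengths differ: {sorted(lengths)}")
        for name, seq in zip(self.names, self.sequences):
            if seq[self.anchor_index] != "C":
                raise DataError(f"{name}: anchor base is {seq[self.anchor_index]}, not C")

    @property
    def span(self) -> tuple[int, int]:
        width = len(self.sequences[0])
        return -self.anchor_index, width - self.anchor_index - 1

    def __len__(self) -> int:
        return len(self.sequences)


def similarity_profile(
    windows: ContextWindowSet,
    window: int = 14,
    exclusion: str | None = "C",
) -> pd.DataFrame:
    """Mean pairwise identity per sliding window placement.

    For every placement, each unordered sequence pair contributes
    (identical evaluable positions) / (evaluable positions), where excluded
    offsets are dropped from numerator and denominator alike; the profile is
    the mean over pairs. Ambiguity codes never count as identical. Columns:
    ``offset`` (left edge of the window) and ``similarity`` (NaN when a
    placement has no evaluable position).
    """
    if len(windows) < 2:
        raise DataError("similarity requires at least two sequences")
    lo, hi = windows.span
    if window > hi - lo + 1:
        raise ConfigurationError("window longer than the sequence span")
    if exclusion not in EXCLUSION_OFFSETS:
        raise ConfigurationError(f"unknown exclusion mode {exclusion!r}")
    excluded = {windows.anchor_index + off for off in EXCLUSION_OFFSETS[exclusion]}

    arr = np.array([list(s) for s in windows.sequences])
    valid = np.ones(arr.shape[1], dtype=bool)
    for idx in excluded:
        if 0 <= idx < arr.shape[1]:
            valid[idx] = False
    # pairwise identity per column; N (or any ambiguity) is never identical
    acgu = np.isin(arr, list("ACGU"))
    pairs = list(combinations(range(len(windows)), 2))
    ident = np.array(
        [(arr[i] == arr[j]) & acgu[i] & acgu[j] for i, j in pairs]
    )  # (n_pairs, width)

    rows = []
    for left in range(0, arr.shape[1] - window + 1):
        cols = np.arange(left, left + window)
        cols = cols[valid[cols]]
        if cols.size == 0:
            sim = np.nan
        else:
            sim = float(ident[:, cols].mean())
        rows.append({"offset": left - windows.anchor_index, "similarity": sim})
    return pd.DataFrame(rows)


def flank_composition(
    windows: ContextWindowSet, offsets: tuple[int, ...] = (-1, 1)
) -> pd.DataFrame:
    """Base counts and fractions at selected offsets relative to the edit."""
    lo, hi = windows.span
    for off in offsets:
        if not lo <= off <= hi:
            raise ConfigurationError(f"offset {off} outside span {lo}..{hi}")
    rows = []
    n = len(windows)
    for off in offsets:
        col = [s[windows.anchor_index + off] for s in windows.sequences]
        for base in "ACGU":
            count = col.count(base)
            rows.append(
                {
                    "offset": off,
                    "base": base,
                    "count": count,
                    "fraction": count / n if n else 0.0,
                }
            )
    return pd.DataFrame(rows)


def read_windows_fasta(path: str | Path, anchor_index: int = 50) -> ContextWindowSet:
    """Anchored windows from FASTA; header tag ``anchor=<n>`` overrides."""
    from Bio import SeqIO

    names, seqs = [], []
    anchor = anchor_index
    for rec in SeqIO.parse(str(path), "fasta"):
        for token in rec.description.split():
            if token.startswith("anchor="):
                anchor = int(token.split("=", 1)[1])
        names.append(rec.id)
        seqs.append(str(rec.seq))
    return ContextWindowSet(names=names, sequences=seqs, anchor_index=anchor)
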