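"""Maximal homopolymer run detection and occurrence tabulation.

A run of length 8 is a single 8mer, never also a 4mer: only maximal runs
are counted, and each contributes to exactly one (base, length-bin) cell.
Lengths above 8 are pooled into the ``>8`` bin. N never forms a run.
"""

from __future__ import annotations

from itertools import groupby
from typing import NamedTuple

import pandas as pd

from pyroqc.seqio import ReadSet

BASES = ("A", "T", "G", "C")
BINS = ("4", "5", "6", "7", "8", ">8")


class HomopolymerRun(NamedTuple):
    base: str
    length: int
    start: int


def find_runs(sequence: str, min_len: int = 4) -> list[HomopolymerRun]:
    """Maximal single-base runs of at least ``min_len`` in 5'-to-3' order."""
    runs: list[HomopolymerRun] = []
    pos = 0
    for base, group in groupby(sequence.upper()):
        length = sum(1 for _ in group)
        if length >= min_len and base in BASES:
            runs.append(HomopolymerRun(base, length, pos))
        pos += length
    return runs


def _bin_label(length: int) -> str:
    return str(length) if length <= 8 else ">8"


def tabulate(read_set: ReadSet, min_len: int = 4) -> pd.DataFrame:
    """Homopolymer occurrence counts per base (rows A/T/G/C) and length
    bin (columns 4..8, >8) aggregated over all reads."""
    table = pd.DataFrame(0, index=list(BASES), columns=list(BINS))
    for read in read_set:
        for run in find_runs(read.bases, min_len=min_len):
            table.loc[run.base, _bin_label(run.length)] += 1
    return table
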