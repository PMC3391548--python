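"""Sequence refinement: length trimming, quality filtering, ambiguous-base
and primer-error removal, with per-stage removal accounting.

The pipeline applies stages in a fixed order -- length, quality, ambiguous,
primer -- so a read failing several criteria is charged to the earliest
stage and the ledger rows are comparable across filter conditions.

Two quality-filter modes are provided:

``fraction``
    Keep a read iff the fraction of bases with Q strictly below the cutoff
    is at most ``allowed_fraction`` (a Q27/15% style filter).
``end_trim``
    Truncate each read at its first base with Q below the cutoff, then
    remove reads shorter than a minimum length (the harsher criterion).
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Optional

from pyroqc.seqio import QualifiedRead, ReadSet

STAGE_ORDER = ("length", "quality", "ambiguous", "primer")

#: IUPAC nucleotide degeneracy table used for primer matching.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass
class FilterConfig:
    """Parameterization of one refinement condition.

    ``trim_rule`` is ``"mean_minus_sd"``, ``"none"``, or ``"fixed:<L>"``.
    ``mode`` is ``"fraction"``, ``"end_trim"``, or ``"none"`` (skip the
    quality stage entirely).
    """

    q_cutoff: int = 27
    allowed_fraction: float = 0.10
    mode: str = "fraction"
    primer: Optional[str] = None
    strip_primer: bool = False
    trim_rule: str = "mean_minus_sd"

    def __post_init__(self) -> None:
        if not 0 <= self.q_cutoff <= 40:
            raise ValueError(f"q_cutoff {self.q_cutoff} outside [0, 40]")
        if not 0.0 <= self.allowed_fraction <= 1.0:
            raise ValueError(f"allowed_fraction {self.allowed_fraction} outside [0, 1]")
        if self.mode not in ("fraction", "end_trim", "none"):
            raise ValueError(f"unknown quality mode {self.mode!r}")
        if self.trim_rule not in ("mean_minus_sd", "none") and not self.trim_rule.startswith("fixed:"):
            raise ValueError(f"unknown trim_rule {self.trim_rule!r}")

    def fixed_trim_length(self) -> Optional[int]:
        if self.trim_rule.startswith("fixed:"):
            return int(self.trim_rule.split(":", 1)[1])
        return None

    def label(self) -> str:
        if self.mode == "none":
            return "trim_noQ" if self.trim_rule != "none" else "full_noQ"
        if self.mode == "end_trim":
            return f"endtrim_Q{self.q_cutoff}"
        pct = round(self.allowed_fraction * 100)
        return f"Q{self.q_cutoff}_{pct}pct"


@dataclass
class RemovalLedger:
    """Ordered per-stage removal counts for one refinement run."""

    raw_count: int
    stage_removals: list[tuple[str, int]] = field(default_factory=list)

    @property
    def remaining(self) -> int:
        return self.raw_count - sum(n for _, n in self.stage_removals)

    @property
    def percent_removed(self) -> float:
        if self.raw_count == 0:
            return 0.0
        return 1.0 - self.remaining / self.raw_count

    def as_dict(self) -> dict[str, int]:
        return dict(self.stage_removals)

    def validate(self) -> None:
        total = sum(n for _, n in self.stage_removals)
        if total + self.remaining != self.raw_count:
            raise AssertionError("ledger does not conserve read counts")
        if any(n < 0 for _, n in self.stage_removals):
            raise AssertionError("negative stage removal")


def compute_trim_length(read_set: ReadSet) -> int:
    """Trim length: floor(mean - sample sd) of raw read lengths.

    Sample standard deviation uses the n-1 denominator; a single read has
    sd 0 by convention.
    """
    if len(read_set) == 0:
        raise ValueError("cannot compute trim length of an empty ReadSet")
    lengths = [len(r) for r in read_set]
    mean = statistics.fmean(lengths)
    sd = statistics.stdev(lengths) if len(lengths) > 1 else 0.0
    return math.floor(mean - sd)


def trim_reads(read_set: ReadSet, L: int) -> tuple[ReadSet, int]:
    """Remove reads shorter than ``L``; truncate survivors to ``L`` bases
    (and quality values) from the 5' end."""
    if L < 1:
        raise ValueError(f"trim length must be >= 1, got {L}")
    kept: list[QualifiedRead] = []
    removed = 0
    for r in read_set:
        if len(r) < L:
            removed += 1
        else:
            kept.append(
                QualifiedRead(r.read_id, r.bases[:L], r.quals[:L], r.taxon, r.template_id)
            )
    return ReadSet(kept, read_set.provenance), removed


def quality_filter_fraction(
    read_set: ReadSet, q_cutoff: int, allowed_fraction: float
) -> tuple[ReadSet, int]:
    """Keep reads where (# bases with Q < cutoff) / length <= allowance.

    The comparison with the cutoff is strict (a base at exactly the cutoff
    is not counted) and the comparison with the allowance is inclusive.
    """
    kept: list[QualifiedRead] = []
    removed = 0
    for r in read_set:
        n_below = sum(1 for q in r.quals if q < q_cutoff)
        if len(r) > 0 and n_below / len(r) <= allowed_fraction:
            kept.append(r)
        else:
            removed += 1
    return ReadSet(kept, read_set.provenance), removed


def quality_end_trim(
    read_set: ReadSet, q_cutoff: int, min_length: int
) -> tuple[ReadSet, int]:
    """Truncate each read at its first base with Q below the cutoff and
    remove reads whose truncated length falls below ``min_length``."""
    kept: list[QualifiedRead] = []
    removed = 0
    for r in read_set:
        cut = len(r)
        for i, q in enumerate(r.quals):
            if q < q_cutoff:
                cut = i
                break
        if cut < min_length:
            removed += 1
        else:
            kept.append(
                QualifiedRead(r.read_id, r.bases[:cut], r.quals[:cut], r.taxon, r.template_id)
            )
    return ReadSet(kept, read_set.provenance), removed


def ambiguous_filter(read_set: ReadSet) -> tuple[ReadSet, int]:
    """Remove reads containing one or more N bases."""
    kept = [r for r in read_set if "N" not in r.bases]
    return ReadSet(kept, read_set.provenance), len(read_set) - len(kept)


def matches_iupac(prefix: str, pattern: str) -> bool:
    """Position-by-position IUPAC match, case-insensitive, zero mismatches."""
    if len(prefix) < len(pattern):
        return False
    for base, code in zip(prefix.upper(), pattern.upper()):
        if base not in IUPAC.get(code, ""):
            return False
    return True


def primer_filter(
    read_set: ReadSet, primer_iupac: str, strip: bool = False
) -> tuple[ReadSet, int]:
    """Remove reads whose 5' prefix does not match the primer under IUPAC
    degeneracy; too-short reads count as primer errors. With ``strip``,
    the matched prefix (bases and quals) is cut from kept reads."""
    if not primer_iupac:
        raise ValueError("primer_iupac must be non-empty")
    plen = len(primer_iupac)
    kept: list[QualifiedRead] = []
    removed = 0
    for r in read_set:
        if not matches_iupac(r.bases, primer_iupac):
            removed += 1
            continue
        if strip:
            kept.append(
                QualifiedRead(r.read_id, r.bases[plen:], r.quals[plen:], r.taxon, r.template_id)
            )
        else:
            kept.append(r)
    return ReadSet(kept, read_set.provenance), removed


def run_refinement(
    read_set: ReadSet, config: FilterConfig
) -> tuple[ReadSet, RemovalLedger]:
    """Apply the refinement stages in order length -> quality -> ambiguous
    -> primer and return the surviving reads plus a :class:`RemovalLedger`.

    ``mode="none"`` skips the quality stage (a trimmed-no-Q baseline);
    ``trim_rule="none"`` skips trimming (a full-length baseline). Skipped
    stages are recorded with zero removals so ledgers stay comparable.
    """
    ledger = RemovalLedger(raw_count=len(read_set))
    current = read_set

    if config.trim_rule == "none":
        trim_length: Optional[int] = None
        n_len = 0
    else:
        trim_length = config.fixed_trim_length()
        if trim_length is None:
            trim_length = compute_trim_length(current) if len(current) else 1
        current, n_len = trim_reads(current, trim_length)
    ledger.stage_removals.append(("length", n_len))

    if config.mode == "none":
        n_q = 0
    elif config.mode == "fraction":
        current, n_q = quality_filter_fraction(
            current, config.q_cutoff, config.allowed_fraction
        )
    else:  # end_trim: the trim length doubles as the minimum surviving length
        min_len = trim_length if trim_length is not None else 1
        current, n_q = quality_end_trim(current, config.q_cutoff, min_len)
    ledger.stage_removals.append(("quality", n_q))

    current, n_amb = ambiguous_filter(current)
    ledger.stage_removals.append(("ambiguous", n_amb))

    if config.primer:
        current, n_prim = primer_filter(current, config.primer, config.strip_primer)
    else:
        n_prim = 0
    ledger.stage_removals.append(("primer", n_prim))

    ledger.validate()
    return current.with_provenance(f"refined[{config.label()}]"), ledger


def quality_summary(read_set: ReadSet) -> float:
    """Mean over reads of the per-read mean Phred score (unweighted by
    read length)."""
    if len(read_set) == 0:
        raise ValueError("quality_summary of an empty ReadSet")
    return statistics.fmean(r.mean_quality() for r in read_set)
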