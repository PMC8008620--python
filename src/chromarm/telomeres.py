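"""Telomeric repeat array detection and scaffold end-status classification.

Chordate telomeres are tandem arrays of the hexamer TTAGGG.  On the forward
strand of an assembled scaffold, an array appears either as exact TTAGGG
repeats (strand +) or as exact CCCTAA repeats (strand -, the reverse
complement).  A scaffold carrying terminal arrays at both ends is a
telomere-to-telomere chromosome; a single terminal array marks a chromosome
arm; interstitial arrays suggest unplaced subtelomeric or pericentromeric
fragments.

Matching is exact and case-insensitive (soft-masking is ignored): divergent
telomere-like repeats are left to dedicated repeat annotators, and exactness
keeps the scanner's behaviour fully checkable by brute force.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ParameterError
from .io import SequenceRecord, GenomicInterval, revcomp

TELOMERE_MOTIF = "TTAGGG"

PLACEMENTS = ("terminal_5p", "terminal_3p", "interstitial")


@dataclass(frozen=True)
class TelomereArray:
    """A chained run of exact telomere-motif matches on one strand."""

    seq_id: str
    start: int
    end: int
    strand: str
    n_units: int
    purity: float
    placement: str

    def as_interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.seq_id, self.start, self.end, strand=self.strand,
            label=self.placement,
        )


@dataclass
class ScaffoldTelomereStatus:
    seq_id: str
    status: str  # both_ends | one_end | interstitial_only | none
    arrays: list[TelomereArray] = field(default_factory=list)

    @property
    def n_terminal_5p(self) -> int:
        return sum(a.placement == "terminal_5p" for a in self.arrays)

    @property
    def n_terminal_3p(self) -> int:
        return sum(a.placement == "terminal_3p" for a in self.arrays)

    @property
    def n_interstitial(self) -> int:
        return sum(a.placement == "interstitial" for a in self.arrays)


def _match_starts(haystack: str, needle: str) -> list[int]:
    # overlapping matches via lookahead; general motifs may self-overlap
    return [m.start() for m in re.finditer(f"(?=({re.escape(needle)}))", haystack)]


def scan_telomere_arrays(
    record: SequenceRecord,
    motif: str = TELOMERE_MOTIF,
    min_units: int = 3,
    max_unit_gap: int = 6,
    end_window: int = 1000,
) -> list[TelomereArray]:
    """Find telomere arrays on both strands of one scaffold.

    Exact motif matches (strand +) and reverse-complement matches (strand -)
    whose starts on the same strand are separated by at most
    ``len(motif) + max_unit_gap`` are chained into a single array.  Chains
    with fewer than ``min_units`` matches are dropped.  Placement is
    ``terminal_5p`` when the array starts within ``end_window`` of the 5'
    end, ``terminal_3p`` when it ends within ``end_window`` of the 3' end,
    otherwise ``interstitial``.  Purity is matched bp over array span.

    Coordinates are always reported on the forward strand, so BED output is
    directly comparable to truth annotations regardless of strand.
    """
    motif = motif.upper()
    if len(motif) < 2:
        raise ParameterError("motif length must be >= 2")
    if any(c not in "ACGT" for c in motif):
        raise ParameterError(f"motif {motif!r} must be over ACGT")
    if min_units < 1:
        raise ParameterError("min_units must be >= 1")

    seq = record.sequence.upper()
    length = len(seq)
    arrays: list[TelomereArray] = []
    for strand, m in (("+", motif), ("-", revcomp(motif))):
        starts = _match_starts(seq, m)
        for chain in _chain(starts, len(motif) + max_unit_gap):
            if len(chain) < min_units:
                continue
            start, end = chain[0], chain[-1] + len(motif)
            n_units = len(chain)
            purity = min(1.0, n_units * len(motif) / (end - start))
            if start < end_window:
                placement = "terminal_5p"
            elif end > length - end_window:
                placement = "terminal_3p"
            else:
                placement = "interstitial"
            arrays.append(
                TelomereArray(record.id, start, end, strand, n_units, purity, placement)
            )
    arrays.sort(key=lambda a: (a.start, a.strand))
    return arrays


def _chain(starts: list[int], max_start_gap: int) -> list[list[int]]:
    """Group sorted match starts into runs with consecutive gaps <= threshold."""
    chains: list[list[int]] = []
    for s in starts:
        if chains and s - chains[-1][-1] <= max_start_gap:
            chains[-1].append(s)
        else:
            chains.append([s])
    return chains


def classify_scaffold(
    record: SequenceRecord, arrays: list[TelomereArray]
) -> ScaffoldTelomereStatus:
    """Classify a scaffold by telomere placement.

    ``both_ends`` when terminal arrays exist at both the 5' and 3' end
    (a telomere-to-telomere chromosome), ``one_end`` when exactly one
    terminal placement is occupied (a chromosome arm), ``interstitial_only``
    when arrays exist but none is terminal, ``none`` otherwise.
    """
    has5 = any(a.placement == "terminal_5p" for a in arrays)
    has3 = any(a.placement == "terminal_3p" for a in arrays)
    if has5 and has3:
        status = "both_ends"
    elif has5 or has3:
        status = "one_end"
    elif arrays:
        status = "interstitial_only"
    else:
        status = "none"
    return ScaffoldTelomereStatus(record.id, status, list(arrays))


def terminal_side(status: ScaffoldTelomereStatus) -> str | None:
    """Which end of a one-ended scaffold carries its telomere: '5p' or '3p'.

    Returns None when no terminal array exists; for a both-ended scaffold
    the 5' side is reported (callers pairing arms treat that as already
    oriented).
    """
    if status.n_terminal_5p:
        return "5p"
    if status.n_terminal_3p:
        return "3p"
    return None
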