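"""Readers and writers for every on-disk format chromarm consumes or emits.

All coordinates inside the package are 0-based half-open on the forward
strand.  The only 1-based format (GFF3) is converted at the file boundary,
so no other module ever performs coordinate arithmetic across conventions.

Soft-masking (repeat annotation) is carried as lowercase in the sequence
itself, exactly as RepeatMasker emits it; there is no separate mask object.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from gffutils.iterators import DataIterator

from .errors import FormatError, ParameterError

__version__ = "0.1.0"

_HEADER = f"# chromarm v{__version__}"

_VALID_BASES = frozenset("ACGTNacgtn")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(sequence: str) -> str:
    """Reverse complement preserving soft-mask case."""
    return sequence.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N} with case-encoded masking."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = _first_illegal_base(self.sequence)
        if bad is not None:
            raise FormatError(
                f"record {self.id!r}: illegal character "
                f"{self.sequence[bad]!r} at position {bad}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open span on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DepthTrack:
    """Per-step sequencing depth for one sequence.

    ``values[i]`` covers bases [i*resolution, (i+1)*resolution).  ``kind``
    records whether values are mean per-base coverage or read-start counts;
    the analyses treat either the same way.
    """

    seq_id: str
    resolution: int
    values: np.ndarray
    kind: str = "mean_per_base"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.resolution <= 0:
            raise ParameterError("resolution must be positive")
        if np.any(self.values < 0):
            raise FormatError(f"depth track {self.seq_id!r} has negative values")

    def n_steps(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class AlignmentBlock:
    """One pairwise alignment block; coordinates forward-strand on both sides."""

    query_id: str
    q_start: int
    q_end: int
    target_id: str
    t_start: int
    t_end: int
    strand: str
    score: int = 0

    def __post_init__(self) -> None:
        if self.q_start >= self.q_end:
            raise FormatError(
                f"empty query span {self.query_id}:{self.q_start}-{self.q_end}"
            )
        if self.t_start >= self.t_end:
            raise FormatError(
                f"empty target span {self.target_id}:{self.t_start}-{self.t_end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"invalid strand {self.strand!r}")
        if self.score < 0:
            raise FormatError("score must be >= 0")

    @property
    def q_len(self) -> int:
        return self.q_end - self.q_start

    @property
    def t_len(self) -> int:
        return self.t_end - self.t_start


def _first_illegal_base(sequence: str) -> int | None:
    for i, ch in enumerate(sequence):
        if ch not in _VALID_BASES:
            return i
    return None


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly wrapped) multi-FASTA into SequenceRecords.

    Case is preserved.  Duplicate ids and characters outside
    {A,C,G,T,N,a,c,g,t,n} raise :class:`FormatError` (ambiguity codes and
    U are rejected rather than converted).
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 as 0-based half-open intervals.

    Column 4 becomes ``label`` and column 6 ``strand`` when present;
    comment (#), track and empty lines are skipped.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinates") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: empty or inverted interval {start}-{end}"
                )
            label = cols[3] if len(cols) > 3 else ""
            strand = cols[5] if len(cols) > 5 else "."
            out.append(GenomicInterval(cols[0], start, end, strand=strand, label=label))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              score: Sequence[float] | None = None) -> None:
    """Write BED6 (BED3 plus name/score/strand columns)."""
    intervals = list(intervals)
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for i, iv in enumerate(intervals):
            sc = score[i] if score is not None else 0
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t{sc}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 (gene rows only)
# ---------------------------------------------------------------------------


def read_gff3_genes(path: str | Path) -> list[GenomicInterval]:
    """Extract type-``gene`` rows from a GFF3 file as 0-based half-open intervals.

    GFF3's 1-based inclusive (start, end) becomes (start-1, end).
    """
    out: list[GenomicInterval] = []
    for feat in DataIterator(str(path)):
        if feat.featuretype != "gene":
            continue
        if feat.end < feat.start:
            raise FormatError(
                f"gene with end < start on {feat.seqid}: {feat.start}-{feat.end}"
            )
        label = feat.attributes.get("ID", [""])[0]
        strand = feat.strand if feat.strand in ("+", "-") else "."
        out.append(
            GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand=strand, label=label)
        )
    return out


def write_gff3_genes(genes: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(_HEADER + "\n")
        for i, g in enumerate(genes):
            gid = g.label or f"gene{i + 1}"
            strand = g.strand if g.strand in ("+", "-") else "."
            fh.write(
                f"{g.seq_id}\tchromarm\tgene\t{g.start + 1}\t{g.end}\t.\t{strand}\t.\tID={gid}\n"
            )


# ---------------------------------------------------------------------------
# Depth TSV: seq_id <TAB> step_index <TAB> value
# ---------------------------------------------------------------------------


def read_depth(path: str | Path) -> dict[str, DepthTrack]:
    """Read a depth TSV into per-sequence DepthTracks.

    Header comments carry ``resolution=`` and ``kind=`` metadata; steps must
    be contiguous from 0 within each sequence.
    """
    resolution = None
    kind = "mean_per_base"
    per_seq: dict[str, list[float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ").strip()
                if body.startswith("resolution="):
                    resolution = int(body.split("=", 1)[1])
                elif body.startswith("kind="):
                    kind = body.split("=", 1)[1]
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            seq_id, idx, val = cols[0], int(cols[1]), float(cols[2])
            steps = per_seq.setdefault(seq_id, [])
            if idx != len(steps):
                raise FormatError(
                    f"{path}:{lineno}: step index {idx} out of order for {seq_id!r}"
                )
            steps.append(val)
    if resolution is None:
        raise FormatError(f"{path}: missing '# resolution=' header")
    return {
        sid: DepthTrack(sid, resolution, np.array(vals), kind=kind)
        for sid, vals in per_seq.items()
    }


def write_depth(tracks: Iterable[DepthTrack], path: str | Path) -> None:
    tracks = list(tracks)
    if not tracks:
        raise ParameterError("no depth tracks to write")
    res = {t.resolution for t in tracks}
    if len(res) != 1:
        raise ParameterError("all depth tracks must share one resolution")
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        fh.write(f"# resolution={tracks[0].resolution}\n")
        fh.write(f"# kind={tracks[0].kind}\n")
        for t in tracks:
            for i, v in enumerate(t.values):
                fh.write(f"{t.seq_id}\t{i}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Alignment-block TSV dialect
# ---------------------------------------------------------------------------

_ALN_COLS = 8


def read_alignment_blocks(path: str | Path) -> list[AlignmentBlock]:
    """Read the 8-column one-to-one alignment dialect.

    Columns: query_id, q_start, q_end, target_id, t_start, t_end, strand,
    score — 0-based half-open, forward-strand coordinates on both genomes,
    strand recording relative orientation.
    """
    out: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < _ALN_COLS:
                raise FormatError(f"{path}:{lineno}: expected {_ALN_COLS} columns")
            try:
                block = AlignmentBlock(
                    cols[0], int(cols[1]), int(cols[2]),
                    cols[3], int(cols[4]), int(cols[5]),
                    cols[6], int(cols[7]),
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            out.append(block)
    return out


def write_alignment_blocks(blocks: Iterable[AlignmentBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for b in blocks:
            fh.write(
                f"{b.query_id}\t{b.q_start}\t{b.q_end}\t{b.target_id}\t"
                f"{b.t_start}\t{b.t_end}\t{b.strand}\t{b.score}\n"
            )


# ---------------------------------------------------------------------------
# Contact matrices: triplet TSV (bin_i, bin_j, count) + companion bins BED,
# or dense TSV with a header row of bin indices.
# ---------------------------------------------------------------------------


def read_contacts_triplet(path: str | Path, n_bins: int) -> np.ndarray:
    """Read triplet contacts into a dense symmetric matrix of shape (n, n)."""
    counts = np.zeros((n_bins, n_bins))
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            i, j, c = int(cols[0]), int(cols[1]), float(cols[2])
            if not (0 <= i < n_bins and 0 <= j < n_bins):
                raise FormatError(f"{path}:{lineno}: bin index out of range")
            if c < 0:
                raise FormatError(f"{path}:{lineno}: negative count")
            counts[i, j] = c
            counts[j, i] = c
    return counts


def write_contacts_triplet(counts: np.ndarray, path: str | Path) -> None:
    counts = np.asarray(counts)
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for i in range(counts.shape[0]):
            for j in range(i, counts.shape[1]):
                if counts[i, j] != 0:
                    fh.write(f"{i}\t{j}\t{counts[i, j]:g}\n")


def read_contacts_dense(path: str | Path) -> np.ndarray:
    """Read a dense whitespace-separated matrix, skipping '#' comment lines."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            rows.append([float(x) for x in line.split()])
    mat = np.array(rows)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise FormatError(f"{path}: dense contact matrix must be square")
    return mat
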