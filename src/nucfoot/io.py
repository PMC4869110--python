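"""Readers and writers for FASTA, BED, bedGraph, PWM text, and midpoint sets.

Every reader/writer pair is a lossless round trip on simulator output.
BED is native (0-based half-open); nothing here is 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval

PAIRED_MIDPOINT = "paired_midpoint"
SINGLE_5PRIME = "single_5prime"


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into ``{chrom: SEQUENCE}`` with uppercased sequences.

    Ambiguity codes are preserved (uppercased), not resolved.
    """
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise ParseError(f"{path}: empty FASTA file (line 1)")
        if not first.startswith(">"):
            raise ParseError(f"{path}: line 1 does not start with '>'")
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise ParseError(f"{path}: no FASTA records parsed")
    return genome


def write_fasta(path, genome: dict[str, str], width: int = 60) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# PWM (JASPAR-style count matrices)

def read_pwm_counts(path) -> tuple[str, np.ndarray]:
    """Parse a JASPAR-style or plain 4-row (A, C, G, T) count matrix.

    Returns ``(name, counts)`` with ``counts`` of shape (L, 4).  Accepts the
    bracketed JASPAR layout (``A  [ 10  0 ... ]``), a bare 4-row numeric
    matrix, or a 4-column matrix (one row per motif position).
    """
    name = "motif"
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if len(line) > 1 else name
                continue
            line = line.replace("[", " ").replace("]", " ")
            parts = line.split()
            if parts and parts[0].upper() in "ACGT" and len(parts) > 1:
                parts = parts[1:]
            try:
                rows.append([float(x) for x in parts])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    mat = np.array(rows, dtype=float)
    if mat.ndim != 2:
        raise ParseError(f"{path}: ragged or empty matrix")
    if mat.shape[0] == 4 and mat.shape[1] != 4:
        mat = mat.T  # 4 rows (A,C,G,T) x L positions -> (L, 4)
    if mat.shape[1] != 4:
        raise ParseError(f"{path}: matrix is {mat.shape}, need 4 nucleotide rows/cols")
    if (mat < 0).any():
        raise ParseError(f"{path}: negative counts")
    if mat.shape[0] < 1:
        raise ParseError(f"{path}: empty matrix")
    return name, mat


def read_pwm(path, pseudocount: float = 0.5):
    """Read a count/frequency matrix and return a normalized :class:`Pwm`.

    ``pseudocount`` is added to every cell before row normalization so all
    probabilities are strictly positive.
    """
    from .motif_scan import Pwm

    name, counts = read_pwm_counts(path)
    return Pwm.from_counts(counts, name=name, pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# BED

def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 records as 0-based half-open intervals."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 BED fields")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from None
            if end <= start:
                raise ParseError(f"{path}: line {lineno}: end <= start")
            name = f[3] if len(f) > 3 and f[3] != "." else None
            score = float(f[4]) if len(f) > 4 and f[4] != "." else None
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], start, end, strand=strand, name=name, score=score))
    return out


def write_bed(path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Tracks (bedGraph)

@dataclass
class Track:
    """Per-chromosome numeric vector at a fixed bp resolution."""

    values: dict[str, np.ndarray]
    resolution: int = 1

    def chrom_length(self, chrom: str) -> int:
        return len(self.values[chrom]) * self.resolution

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Mean track value over [start, end) in bp coordinates."""
        v = self.values[chrom]
        i0 = start // self.resolution
        i1 = -(-end // self.resolution)
        return float(v[i0:i1].mean())

    @classmethod
    def constant(cls, chrom_lengths: dict[str, int], value: float = 1.0,
                 resolution: int = 1) -> "Track":
        return cls(
            {c: np.full(-(-n // resolution), value, dtype=float)
             for c, n in chrom_lengths.items()},
            resolution=resolution,
        )


def read_bedgraph_track(path, chrom_lengths: dict[str, int],
                        resolution: int = 1, fill: float = 0.0) -> Track:
    """Read a bedGraph into a dense per-chromosome vector.

    Gaps take ``fill``; overlapping segments are an error naming both lines.
    Segment bounds must align to ``resolution``.
    """
    vals = {c: np.full(-(-n // resolution), fill, dtype=float)
            for c, n in chrom_lengths.items()}
    last_end: dict[str, tuple[int, int]] = {}  # chrom -> (end, lineno)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) != 4:
                raise ParseError(f"{path}: line {lineno}: need 4 bedGraph fields")
            chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
            if end <= start:
                raise ParseError(f"{path}: line {lineno}: end <= start")
            if chrom not in vals:
                raise ParseError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
            if chrom in last_end and start < last_end[chrom][0]:
                raise ParseError(
                    f"{path}: line {lineno} overlaps line {last_end[chrom][1]}"
                )
            if start % resolution or end % resolution:
                raise ParseError(
                    f"{path}: line {lineno}: bounds not aligned to {resolution} bp"
                )
            vals[chrom][start // resolution: end // resolution] = value
            last_end[chrom] = (end, lineno)
    return Track(vals, resolution=resolution)


def write_bedgraph(path, track: Track) -> None:
    """Write a track as run-length-encoded bedGraph (lossless round trip)."""
    res = track.resolution
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            v = track.values[chrom]
            if len(v) == 0:
                continue
            changes = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], changes])
            ends = np.concatenate([changes, [len(v)]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s * res}\t{e * res}\t{v[s]:.17g}\n")


# ---------------------------------------------------------------------------
# Midpoints

@dataclass
class MidpointSet:
    """Single-base digestion-fragment midpoints, sorted per chromosome.

    ``pos[c]`` holds sorted positions, ``strand[c]`` the strand of origin of
    each midpoint (True for '+').  ``mode`` records whether midpoints came
    from paired-end fragment centers or single-end 5' starts.
    """

    pos: dict[str, np.ndarray] = field(default_factory=dict)
    strand: dict[str, np.ndarray] = field(default_factory=dict)
    label: str = ""
    mode: str = PAIRED_MIDPOINT
    n_skipped: int = 0

    def __post_init__(self):
        for c in self.pos:
            order = np.argsort(self.pos[c], kind="stable")
            self.pos[c] = np.asarray(self.pos[c], dtype=np.int64)[order]
            self.strand[c] = np.asarray(self.strand[c], dtype=bool)[order]

    @property
    def n(self) -> int:
        return int(sum(len(p) for p in self.pos.values()))

    def union(self, other: "MidpointSet", label: str = "") -> "MidpointSet":
        """Pool two libraries (unweighted union of midpoints)."""
        chroms = set(self.pos) | set(other.pos)
        pos = {c: np.concatenate([self.pos.get(c, np.empty(0, np.int64)),
                                  other.pos.get(c, np.empty(0, np.int64))])
               for c in chroms}
        strand = {c: np.concatenate([self.strand.get(c, np.empty(0, bool)),
                                     other.strand.get(c, np.empty(0, bool))])
                  for c in chroms}
        return MidpointSet(pos, strand, label=label or f"{self.label}+{other.label}",
                           mode=self.mode)


def fragments_to_midpoints(fragments: Iterable[GenomicInterval], mode: str,
                           label: str = "") -> MidpointSet:
    """Reduce fragments to single-base midpoints.

    Paired mode takes ``floor((start+end)/2)``; single-end mode takes the 5'
    genomic start (+ strand: ``start``; - strand: ``end - 1``).  Zero-length
    records cannot occur (intervals validate), but records lacking a strand in
    single-end mode are skipped and counted.
    """
    if mode not in (PAIRED_MIDPOINT, SINGLE_5PRIME):
        raise ValueError(f"unknown midpoint mode {mode!r}")
    pos: dict[str, list[int]] = {}
    strands: dict[str, list[bool]] = {}
    n_skipped = 0
    for frag in fragments:
        if mode == PAIRED_MIDPOINT:
            m = (frag.start + frag.end) // 2
        else:
            if frag.strand == "+":
                m = frag.start
            elif frag.strand == "-":
                m = frag.end - 1
            else:
                n_skipped += 1
                continue
        pos.setdefault(frag.chrom, []).append(m)
        strands.setdefault(frag.chrom, []).append(frag.strand != "-")
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} strandless records in single-end mode")
    return MidpointSet(
        {c: np.array(v, dtype=np.int64) for c, v in pos.items()},
        {c: np.array(v, dtype=bool) for c, v in strands.items()},
        label=label, mode=mode, n_skipped=n_skipped,
    )


def write_midpoints_bed(path, mps: MidpointSet) -> None:
    """Write midpoints as 1 bp BED6 intervals, strand of origin in column 6."""
    with open(path, "w") as fh:
        for chrom in sorted(mps.pos):
            for p, s in zip(mps.pos[chrom], mps.strand[chrom]):
                fh.write(f"{chrom}\t{p}\t{p + 1}\t.\t.\t{'+' if s else '-'}\n")


def read_midpoints_bed(path, label: str = "", mode: str = PAIRED_MIDPOINT) -> MidpointSet:
    ivs = read_bed(path)
    pos: dict[str, list[int]] = {}
    strand: dict[str, list[bool]] = {}
    for iv in ivs:
        if len(iv) != 1:
            raise ParseError(f"{path}: midpoint record {iv.chrom}:{iv.start}-{iv.end} is not 1 bp")
        pos.setdefault(iv.chrom, []).append(iv.start)
        strand.setdefault(iv.chrom, []).append(iv.strand != "-")
    return MidpointSet(
        {c: np.array(v, dtype=np.int64) for c, v in pos.items()},
        {c: np.array(v, dtype=bool) for c, v in strand.items()},
        label=label, mode=mode,
    )
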