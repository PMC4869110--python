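"""Position-weight-matrix scanning and candidate-site selection.

Scores are log2 likelihood ratios of the PWM model against a uniform
background (0.25 per base), so a score of 13 bits means the window is
2^13 ~ 8000x more likely under the motif model than by chance.  A site
passes the default scan when its score exceeds 13 bits; candidate sets
are then narrowed by mappability and PWM-rank rules before footprinting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import Track
from .intervals import GenomicInterval

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PRIMARY = "primary"
EXTENDED = "extended"
CTCF_RELAXED = "ctcf-relaxed"


@dataclass
class Pwm:
    """Per-position nucleotide probability model of a factor's binding motif."""

    probs: np.ndarray  # (L, 4) over A, C, G, T
    name: str = "motif"
    motif_id: str = ""

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError(f"PWM matrix must be (L, 4), got {self.probs.shape}")
        if (self.probs <= 0).any():
            raise ValueError("PWM probabilities must be strictly positive; "
                             "normalize counts with a pseudocount")
        rowsums = self.probs.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1 within 1e-9")

    @classmethod
    def from_counts(cls, counts, name: str = "motif", motif_id: str = "",
                    pseudocount: float = 0.5) -> "Pwm":
        counts = np.asarray(counts, dtype=float)
        if (counts < 0).any():
            raise ValueError("negative counts in PWM matrix")
        probs = counts + pseudocount
        probs /= probs.sum(axis=1, keepdims=True)
        return cls(probs, name=name, motif_id=motif_id)

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(L, 5) log2(p / 0.25); column 4 scores an ambiguous base as the
        mean probability over the four nucleotides."""
        lo = np.log2(self.probs / 0.25)
        amb = np.log2(self.probs.mean(axis=1) / 0.25)
        return np.column_stack([lo, amb])

    @property
    def information_content(self) -> np.ndarray:
        """Per-position information content in bits (2 - entropy)."""
        return 2.0 + (self.probs * np.log2(self.probs)).sum(axis=1)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.probs[::-1, ::-1], name=self.name, motif_id=self.motif_id)


@dataclass
class MotifInstance:
    """One candidate binding site with its footprint-model covariates."""

    chrom: str
    start: int
    end: int
    strand: str
    pwm_score: float
    gc_flank: Optional[float] = None
    cons_score: Optional[float] = None
    mappability: Optional[float] = None
    selected: bool = False
    quintile_rank: Optional[float] = None
    name: str = ""

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, strand=self.strand,
                               name=self.name or None, score=self.pwm_score)

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence to integer codes A=0, C=1, G=2, T=3; anything else 4."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def score_pwm(window: str, pwm: Pwm) -> float:
    """log2 likelihood ratio of one window against the uniform background."""
    if len(window) != len(pwm):
        raise ValueError(f"window length {len(window)} != motif length {len(pwm)}")
    codes = encode_sequence(window.upper())
    lo = pwm.log_odds
    return float(lo[np.arange(len(pwm)), codes].sum())


def _scores_one_strand(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Score every window start on the encoded strand; vectorized over starts."""
    L = lo.shape[0]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for j in range(L):
        scores += lo[j, codes[j:j + n]]
    return scores


def scan_genome(genome: dict[str, str], pwm: Pwm,
                min_score: float = 13.0) -> list[MotifInstance]:
    """Scan both strands of every chromosome for windows scoring > min_score.

    Minus-strand hits are reported in forward coordinates.  Overlapping hits
    of the same PWM within one motif length are deduplicated, keeping the
    highest score (ties: '+' strand, then leftmost).
    """
    L = len(pwm)
    lo = pwm.log_odds
    lo_rc = pwm.reverse_complement().log_odds
    hits: list[MotifInstance] = []
    for chrom in sorted(genome):
        codes = encode_sequence(genome[chrom].upper())
        fwd = _scores_one_strand(codes, lo)
        rev = _scores_one_strand(codes, lo_rc)  # rc-PWM on fwd text == '-' hits
        cand: list[tuple[int, str, float]] = []
        for i in np.flatnonzero(fwd > min_score):
            cand.append((int(i), "+", float(fwd[i])))
        for i in np.flatnonzero(rev > min_score):
            cand.append((int(i), "-", float(rev[i])))
        # dedup within L bp: sort by priority, greedily keep non-conflicting.
        # Scores are rounded for ranking so that fwd/rev float summation
        # order cannot flip ties (palindromic-scoring positions).
        cand.sort(key=lambda t: (-round(t[2], 6), t[1] != "+", t[0]))
        taken_starts: list[int] = []
        taken = np.empty(0, dtype=np.int64)
        kept: list[tuple[int, str, float]] = []
        for start, strand, score in cand:
            if len(taken_starts):
                taken = np.asarray(sorted(taken_starts), dtype=np.int64)
                j = np.searchsorted(taken, start)
                near = []
                if j > 0:
                    near.append(taken[j - 1])
                if j < len(taken):
                    near.append(taken[j])
                if any(abs(int(t) - start) < L for t in near):
                    continue
            kept.append((start, strand, score))
            taken_starts.append(start)
        for start, strand, score in sorted(kept):
            hits.append(MotifInstance(chrom, start, start + L, strand, score,
                                      name=pwm.name))
    return hits


def annotate_covariates(instances: Sequence[MotifInstance], genome: dict[str, str],
                        conservation: Optional[Track] = None,
                        mappability: Optional[Track] = None,
                        flank: int = 200, window: int = 2000,
                        block: int = 5) -> list[MotifInstance]:
    """Annotate flanking GC, motif conservation, and window mappability.

    gc_flank is the mean GC fraction over consecutive ``block``-bp blocks
    within +/- ``flank`` bp of the motif (motif excluded); for complete
    blocks this equals the plain GC fraction of the flanks.  cons_score is
    mean conservation over motif bases; mappability is the mean over the
    ``window`` bp centered on the motif.  Instances whose flanks or window
    would leave the chromosome are dropped (and counted in a warning).
    """
    out: list[MotifInstance] = []
    n_dropped = 0
    half = window // 2
    for inst in instances:
        seq = genome[inst.chrom]
        lo = inst.start - flank
        hi = inst.end + flank
        c = inst.center
        if lo < 0 or hi > len(seq) or c - half < 0 or c + half > len(seq):
            n_dropped += 1
            continue
        gc_blocks = []
        for s in (seq[lo:inst.start], seq[inst.end:hi]):
            for i in range(0, len(s) - block + 1, block):
                chunk = s[i:i + block]
                gc_blocks.append(sum(b in "GC" for b in chunk) / block)
        inst.gc_flank = float(np.mean(gc_blocks))
        if conservation is not None:
            inst.cons_score = conservation.mean_over(inst.chrom, inst.start, inst.end)
        if mappability is not None:
            inst.mappability = mappability.mean_over(inst.chrom, c - half, c + half)
        out.append(inst)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} instances too close to a chromosome edge")
    return out


def select_instances(instances: Sequence[MotifInstance],
                     mode: str = PRIMARY) -> list[MotifInstance]:
    """Select the candidate set for footprinting.

    primary      -- window mappability >= 0.99, then the top quintile by PWM
                    score (boundary ties all kept);
    extended     -- mappability >= 0.90 and score >= 14, no quintile cut;
    ctcf-relaxed -- mappability >= 0.99 and score >= 13, no quintile cut.
    """
    if not instances:
        warnings.warn("select_instances: empty input")
        return []
    if any(inst.mappability is None for inst in instances):
        raise ValueError("instances must carry window mappability; run annotate_covariates")
    if mode == PRIMARY:
        pool = [i for i in instances if i.mappability >= 0.99]
        if not pool:
            return []
        scores = np.sort([i.pwm_score for i in pool])[::-1]
        k = max(1, -(-len(pool) // 5))  # ceil(n/5): top quintile
        cut = float(scores[k - 1])
        kept = [i for i in pool if i.pwm_score >= cut]
    elif mode == EXTENDED:
        kept = [i for i in instances
                if i.mappability >= 0.90 and i.pwm_score >= 14.0]
    elif mode == CTCF_RELAXED:
        kept = [i for i in instances
                if i.mappability >= 0.99 and i.pwm_score >= 13.0]
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    ranks = {id(i): r for r, i in enumerate(
        sorted(kept, key=lambda x: -x.pwm_score), start=1)}
    for inst in instances:
        inst.selected = False
    for inst in kept:
        inst.selected = True
        inst.quintile_rank = ranks[id(inst)]
    return kept
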