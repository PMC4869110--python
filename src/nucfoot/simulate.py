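"""Synthetic chromatin-digestion data with known ground truth.

The generator emulates what a nuclease-digestion library looks like around
transcription-factor motifs in condensed chromatin:

* motif instances planted with graded PWM scores (sites are drawn from the
  PWM itself, so realized scores vary realistically);
* latent occupancy driven by a logistic prior on the site covariates;
* fragment midpoints around occupied sites following a protected motif
  core flanked by phased nucleosome arrays (~160 bp period whose amplitude
  decays linearly to zero ~1.5 kb from the motif), with an overdispersed
  (negative binomial) total per site;
* a flat naked-DNA control digest over the same windows.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io import MidpointSet, Track, PAIRED_MIDPOINT
from .motif_scan import (MotifInstance, Pwm, annotate_covariates,
                         score_pwm)


@dataclass
class SimConfig:
    """Study conditions for one synthetic digestion experiment."""

    n_sites: int = 2000
    gc: float = 0.5
    genome_length: Optional[int] = None     # None: sized from n_sites and spacing
    prior_beta: tuple = (-7.0, 0.5, 0.0, 0.0)  # intercept, PWM, GC, conservation
    core_half_width: int = 15               # protected factor core, bp
    period: int = 160                       # nucleosome repeat length, bp
    decay_extent: int = 1500                # phasing dies out by here, bp
    array_amplitude: float = 0.8            # cosine modulation depth at the motif
    core_depletion: float = 0.1             # relative density inside the core
    mean_reads: float = 100.0               # mean midpoints per site window
    bound_multiplier: float = 3.0           # occupied sites draw deeper
    dispersion: float = 10.0                # NB: var = mu + mu^2 / dispersion
    background_rate: float = 0.002          # genome-wide stray midpoints per bp
    flank: int = 1000                       # analysis window = motif +/- flank
    gen_flank: Optional[int] = None         # digestion spread; None: past the array
    min_gap: Optional[int] = None           # None: windows never collide (>= 2 kb)
    mappability_gap_fraction: float = 0.0   # optional low-mappability patches
    cons_background: tuple = (2.0, 8.0)     # Beta(a, b) outside motifs
    cons_motif: tuple = (8.0, 2.0)          # Beta(a, b) inside motifs
    control: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.gc < 1.0:
            raise ValueError("GC fraction must lie in (0, 1)")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.decay_extent < self.period:
            raise ValueError("decay extent must be >= period")
        if self.mean_reads <= 0:
            raise ValueError("mean reads per site must be positive")

    @property
    def effective_gen_flank(self) -> int:
        """Half-width of the digestion footprint around a site.

        Midpoints must be placed out to where the nucleosome array has fully
        decayed, beyond the +/- 1 kb analysis window, or the array would be
        artificially truncated at the window edge.
        """
        if self.gen_flank is not None:
            return self.gen_flank
        return max(self.flank, self.decay_extent + 4 * self.period)

    @property
    def effective_min_gap(self) -> int:
        """Spacing so one site's digestion spread never reaches another's
        analysis window; at least the 2 kb floor."""
        if self.min_gap is not None:
            return self.min_gap
        return max(2000, self.flank + self.effective_gen_flank)

    def auto_genome_length(self, motif_length: int) -> int:
        margin = 2 * (self.effective_gen_flank + motif_length)
        spacing = self.effective_min_gap + motif_length + 400
        return self.n_sites * spacing + 2 * margin


def make_informative_pwm(length: int = 12, dominance: float = 0.85,
                         seed: int = 7, name: str = "synthfactor") -> Pwm:
    """A synthetic high-information PWM (one dominant base per position).

    Average per-position information is ~1.2 bits, so realized scores of
    sites drawn from the model spread over roughly 5-25 bits -- the same
    regime in which the 13-bit scan threshold operates on real motifs.
    """
    rng = np.random.default_rng(seed)
    probs = np.full((length, 4), (1.0 - dominance) / 3.0)
    for i, b in enumerate(rng.integers(0, 4, size=length)):
        probs[i, b] = dominance
    return Pwm(probs, name=name, motif_id=f"{name}.1")


# ---------------------------------------------------------------------------
# Genome, tracks, plants

def simulate_genome(config: SimConfig, motif_length: int = 12,
                    rng: Optional[np.random.Generator] = None,
                    ) -> tuple[dict[str, str], Track, Track]:
    """Draw an i.i.d. genome plus mappability and background conservation.

    Conservation inside planted motifs is elevated later by
    :func:`plant_motifs`, making the covariate informative about where real
    motifs sit.  Mappability defaults to 1.0 everywhere, with optional
    low-mappability patches.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.genome_length or config.auto_genome_length(motif_length)
    if n < 2 * config.flank + motif_length:
        raise ValueError("genome shorter than one footprint window")
    p = [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
    codes = rng.choice(4, size=n, p=p)
    seq = codes.astype(np.uint8)
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    genome = {"chr1": lut[seq].tobytes().decode("ascii")}
    mapp = np.ones(n)
    if config.mappability_gap_fraction > 0:
        n_patches = max(1, int(config.mappability_gap_fraction * n / 500))
        starts = rng.integers(0, n - 500, size=n_patches)
        for s in starts:
            mapp[s:s + 500] = rng.uniform(0.0, 0.9)
    a, b = config.cons_background
    cons = rng.beta(a, b, size=n)
    return genome, Track({"chr1": mapp}), Track({"chr1": cons})


def plant_motifs(genome: dict[str, str], pwm: Pwm, config: SimConfig,
                 conservation: Optional[Track] = None,
                 rng: Optional[np.random.Generator] = None,
                 ) -> tuple[list[MotifInstance], dict[str, str]]:
    """Plant ``n_sites`` motif instances with pairwise gaps >= min_gap.

    Planted sequences are drawn from the PWM (minus-strand plants insert the
    reverse complement), so rescored PWM values vary site to site.  If a
    conservation track is given, motif bases are re-drawn from the elevated
    Beta so the covariate separates motif from background.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    L = len(pwm)
    chrom = next(iter(genome))
    seq = np.frombuffer(genome[chrom].encode("ascii"), dtype=np.uint8).copy()
    n = len(seq)
    margin = config.effective_gen_flank + L
    spacing = config.effective_min_gap + L + 400
    max_feasible = max(0, (n - 2 * margin) // spacing)
    if config.n_sites > max_feasible:
        raise ValueError(
            f"cannot place {config.n_sites} sites with min gap {config.effective_min_gap} "
            f"in {n} bp; max feasible is {max_feasible}"
        )
    jitter_room = spacing - config.effective_min_gap - L
    starts = (margin + np.arange(config.n_sites) * spacing
              + rng.integers(0, jitter_room + 1, size=config.n_sites))
    strands = rng.random(config.n_sites) < 0.5
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    instances: list[MotifInstance] = []
    for k in range(config.n_sites):
        s = int(starts[k])
        draw = np.array([rng.choice(4, p=pwm.probs[i]) for i in range(L)])
        motif = lut[draw]
        strand = "+" if strands[k] else "-"
        if strand == "+":
            seq[s:s + L] = motif
        else:
            comp = np.array([3, 2, 1, 0])[draw[::-1]]
            seq[s:s + L] = lut[comp]
        planted = seq[s:s + L].tobytes().decode("ascii")
        window = planted if strand == "+" else _revcomp(planted)
        score = score_pwm(window, pwm)
        if conservation is not None:
            a, b = config.cons_motif
            conservation.values[chrom][s:s + L] = rng.beta(a, b, size=L)
        instances.append(MotifInstance(chrom, s, s + L, strand, score,
                                       name=pwm.name))
    genome = dict(genome)
    genome[chrom] = seq.tobytes().decode("ascii")
    return instances, genome


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# Occupancy and midpoints

def simulate_occupancy(instances: list[MotifInstance], prior_beta,
                       rng: Optional[np.random.Generator] = None,
                       seed: Optional[int] = None,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Draw latent occupancy ~ Bernoulli(logistic(b0 + b.covariates)).

    Returns ``(occupancy, p_bound)``.  Requires gc_flank and cons_score on
    every instance (run ``annotate_covariates`` first).
    """
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else 0)
    b0, b_pwm, b_gc, b_cons = prior_beta
    for inst in instances:
        if inst.gc_flank is None or inst.cons_score is None:
            raise ValueError("instances missing covariates; run annotate_covariates")
    eta = np.array([b0 + b_pwm * i.pwm_score + b_gc * i.gc_flank
                    + b_cons * i.cons_score for i in instances])
    p = 1.0 / (1.0 + np.exp(-eta))
    occ = (rng.random(len(instances)) < p).astype(np.int8)
    return occ, p


def bound_profile(config: SimConfig, motif_length: int) -> np.ndarray:
    """Generating spatial profile for an occupied site: (2, W) simplex.

    A depleted core over motif +/- core_half_width, flanked by a cosine
    modulation at the nucleosome period whose amplitude decays linearly to
    zero at the decay extent.  Symmetric about the motif midpoint and split
    50/50 between strands of origin.  The profile spans the full digestion
    spread (motif +/- gen_flank), wider than the analysis window.
    """
    W = 2 * config.effective_gen_flank + motif_length
    center = W / 2.0
    x = np.arange(W) + 0.5
    d = np.abs(x - center)
    core = config.core_half_width + motif_length / 2.0
    dens = np.ones(W)
    inside = d <= core
    dens[inside] = config.core_depletion
    amp = config.array_amplitude * np.clip(1.0 - d / config.decay_extent, 0.0, None)
    phase = np.cos(2.0 * np.pi * (d - core) / config.period)
    flank_region = ~inside
    dens[flank_region] = 1.0 + amp[flank_region] * phase[flank_region]
    dens = np.clip(dens, 1e-9, None)
    dens /= dens.sum()
    return np.vstack([dens, dens]) / 2.0


def uniform_profile(config: SimConfig, motif_length: int) -> np.ndarray:
    W = 2 * config.effective_gen_flank + motif_length
    return np.full((2, W), 1.0 / (2 * W))


def simulate_midpoints(instances: list[MotifInstance], occupancy: np.ndarray,
                       config: SimConfig, chrom_lengths: dict[str, int],
                       rng: Optional[np.random.Generator] = None,
                       control: bool = False, label: str = "sim",
                       ) -> tuple[MidpointSet, np.ndarray]:
    """Draw a digestion midpoint library over the planted sites.

    Per site the total is negative binomial (mean scaled by the bound
    multiplier when occupied and not a control digest) and positions are
    multinomial from the bound or uniform profile.  A Poisson background of
    stray midpoints is scattered genome-wide.  Returns the library and the
    per-site drawn totals.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    L = len(instances[0].interval) if instances else 12
    prof_bound = bound_profile(config, L).ravel()
    prof_flat = uniform_profile(config, L).ravel()
    W = prof_bound.size // 2
    r = config.dispersion
    pos_parts: list[np.ndarray] = []
    strand_parts: list[np.ndarray] = []
    totals = np.zeros(len(instances), dtype=np.int64)
    for k, inst in enumerate(instances):
        occupied = bool(occupancy[k]) and not control
        mu = config.mean_reads * (config.bound_multiplier if occupied else 1.0)
        t = rng.negative_binomial(r, r / (r + mu))
        totals[k] = t
        if t == 0:
            continue
        prof = prof_bound if occupied else prof_flat
        cells = rng.choice(2 * W, size=t, p=prof)
        strand_of_origin = cells >= W
        offset = np.where(strand_of_origin, cells - W, cells)
        if inst.strand == "-":
            offset = W - 1 - offset
            strand_of_origin = ~strand_of_origin
        pos_parts.append(inst.start - config.effective_gen_flank + offset)
        strand_parts.append(~strand_of_origin)  # True == '+'
    chrom = instances[0].chrom if instances else "chr1"
    n_chrom = chrom_lengths[chrom]
    if config.background_rate > 0:
        n_bg = rng.poisson(config.background_rate * n_chrom)
        if n_bg:
            pos_parts.append(rng.integers(0, n_chrom, size=n_bg))
            strand_parts.append(rng.random(n_bg) < 0.5)
    if pos_parts:
        pos = np.concatenate(pos_parts)
        strands = np.concatenate(strand_parts)
    else:
        pos = np.empty(0, dtype=np.int64)
        strands = np.empty(0, dtype=bool)
    keep = (pos >= 0) & (pos < n_chrom)
    mps = MidpointSet({chrom: pos[keep]}, {chrom: strands[keep]},
                      label=label, mode=PAIRED_MIDPOINT)
    return mps, totals


# ---------------------------------------------------------------------------
# Orchestrator

@dataclass
class SimData:
    """One complete synthetic experiment plus its ground truth."""

    config: SimConfig
    pwm: Pwm
    genome: dict[str, str]
    mappability: Track
    conservation: Track
    instances: list[MotifInstance]
    occupancy: np.ndarray
    p_bound: np.ndarray
    midpoints: MidpointSet
    totals: np.ndarray
    control_midpoints: Optional[MidpointSet] = None
    bound_profile: np.ndarray = field(default=None, repr=False)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def truth_profile(self, flank: int) -> np.ndarray:
        """Generating bound profile restricted to motif +/- flank, renormalized.

        The generator spreads midpoints over the full digestion footprint;
        this gives the truth on the same support as an analysis window.
        """
        full = self.bound_profile
        Wgen = full.shape[1]
        L = Wgen - 2 * self.config.effective_gen_flank
        cut = self.config.effective_gen_flank - flank
        if cut < 0:
            raise ValueError("analysis flank exceeds the generation flank")
        inner = full[:, cut: cut + 2 * flank + L]
        return inner / inner.sum()

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for k, inst in enumerate(self.instances):
            rows.append(dict(site=k, chrom=inst.chrom, start=inst.start,
                             end=inst.end, strand=inst.strand,
                             pwm_score=inst.pwm_score, gc_flank=inst.gc_flank,
                             cons_score=inst.cons_score,
                             p_bound=self.p_bound[k],
                             occupancy=int(self.occupancy[k]),
                             total_count=int(self.totals[k])))
        return pd.DataFrame(rows)


def simulate_dataset(config: SimConfig, pwm: Optional[Pwm] = None) -> SimData:
    """Run the full generator: genome, plants, occupancy, digestion, control."""
    rng = np.random.default_rng(config.seed)
    pwm = pwm if pwm is not None else make_informative_pwm()
    genome, mapp, cons = simulate_genome(config, motif_length=len(pwm), rng=rng)
    instances, genome = plant_motifs(genome, pwm, config, conservation=cons, rng=rng)
    instances = annotate_covariates(instances, genome, conservation=cons,
                                    mappability=mapp, window=2 * config.flank)
    if len(instances) != config.n_sites:
        warnings.warn(f"{config.n_sites - len(instances)} planted sites lost "
                      "to edge trimming")
    occ, p = simulate_occupancy(instances, config.prior_beta, rng=rng)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    mps, totals = simulate_midpoints(instances, occ, config, chrom_lengths,
                                     rng=rng, label="digest")
    ctrl = None
    if config.control:
        ctrl, _ = simulate_midpoints(instances, occ, config, chrom_lengths,
                                     rng=rng, control=True, label="naked")
    return SimData(config=config, pwm=pwm, genome=genome, mappability=mapp,
                   conservation=cons, instances=instances, occupancy=occ,
                   p_bound=p, midpoints=mps, totals=totals,
                   control_midpoints=ctrl,
                   bound_profile=bound_profile(config, len(pwm)))
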