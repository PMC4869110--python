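"""Coverage correlations and interval-level statistics.

Coverage tracks are midpoint counts in fixed genome-wide bins compared by
Spearman correlation; interval statistics cover region builders (promoters,
TAD boundaries), Fisher and circular-shift-empirical enrichment, Jaccard
similarity with hierarchical clustering, overlap categorization, and the
bound-versus-unbound conservation comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .intervals import (GenomicInterval, IntervalIndex,
                        intersection_length, merge_intervals, total_length)
from .io import MidpointSet, Track


# ---------------------------------------------------------------------------
# Coverage tracks and correlations

@dataclass
class CoverageTrack:
    """Midpoint counts in fixed bins, one vector per chromosome."""

    counts: dict[str, np.ndarray]
    bin_size: int
    label: str = ""

    def concatenated(self, chrom_order: Optional[Sequence[str]] = None) -> np.ndarray:
        order = chrom_order if chrom_order is not None else sorted(self.counts)
        return np.concatenate([self.counts[c] for c in order])


def bin_midpoints(midpoints: MidpointSet, bin_size: int,
                  chrom_lengths: dict[str, int], label: str = "") -> CoverageTrack:
    """Count midpoints into genome-wide bins of ``bin_size`` bp."""
    counts: dict[str, np.ndarray] = {}
    for chrom, n in chrom_lengths.items():
        nbins = -(-n // bin_size)
        pos = midpoints.pos.get(chrom)
        if pos is None:
            counts[chrom] = np.zeros(nbins, dtype=np.int64)
            continue
        if len(pos) and (pos.min() < 0 or pos.max() >= n):
            raise ValueError(f"midpoint outside chromosome {chrom} bounds")
        counts[chrom] = np.bincount(pos // bin_size, minlength=nbins)
    return CoverageTrack(counts, bin_size, label=label or midpoints.label)


def correlation_matrix(tracks: Sequence[CoverageTrack],
                       ) -> tuple[pd.DataFrame, list[int]]:
    """Pairwise Spearman rho over all genome-wide bins, plus a display order.

    The order comes from average-linkage hierarchical clustering on 1 - rho.
    Pairs involving a constant track have undefined rho (NaN).
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    if len({t.bin_size for t in tracks}) != 1:
        raise ValueError("tracks must share one bin size")
    chroms = sorted(tracks[0].counts)
    data = np.column_stack([t.concatenated(chroms) for t in tracks])
    labels = [t.label or f"track{i}" for i, t in enumerate(tracks)]
    k = data.shape[1]
    rho = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if np.ptp(data[:, i]) == 0 or np.ptp(data[:, j]) == 0:
                rho[i, j] = rho[j, i] = np.nan
            else:
                rho[i, j] = rho[j, i] = stats.spearmanr(data[:, i], data[:, j])[0]
    mat = pd.DataFrame(rho, index=labels, columns=labels)
    dist = 1.0 - np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(dist, 0.0)
    order = list(hierarchy.leaves_list(
        hierarchy.linkage(squareform(dist, checks=False), method="average")))
    return mat, order


def sliding_regional_correlation(tracks: Sequence[CoverageTrack],
                                 region: GenomicInterval,
                                 window: int = 5) -> pd.DataFrame:
    """Spearman rho in a sliding window of ``window`` consecutive bins.

    Tracks must already be binned (50 bp bins for the 20 kb regional
    comparison).  Steps where either track has zero variance yield NaN.
    Returns one row per window start with each pairwise rho and their mean.
    """
    bin_size = tracks[0].bin_size
    if len(region) < window * bin_size:
        raise ValueError("region shorter than the sliding window")
    b0 = region.start // bin_size
    b1 = region.end // bin_size
    segs = [t.counts[region.chrom][b0:b1] for t in tracks]
    labels = [t.label or f"track{i}" for i, t in enumerate(tracks)]
    nbins = b1 - b0
    rows = []
    for s in range(nbins - window + 1):
        row = {"position": region.start + s * bin_size}
        vals = []
        for i in range(len(tracks)):
            for j in range(i + 1, len(tracks)):
                a = segs[i][s:s + window]
                b = segs[j][s:s + window]
                if np.ptp(a) == 0 or np.ptp(b) == 0:
                    r = np.nan
                else:
                    r = stats.spearmanr(a, b)[0]
                row[f"rho_{labels[i]}_{labels[j]}"] = r
                vals.append(r)
        row["rho_mean"] = np.nanmean(vals) if not np.all(np.isnan(vals)) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Region builders

def make_promoters(tss: Iterable[GenomicInterval],
                   chrom_lengths: Optional[dict[str, int]] = None,
                   upstream: int = 5000, downstream: int = 250,
                   ) -> list[GenomicInterval]:
    """Strand-aware promoter windows: 5 kb upstream to 0.25 kb downstream.

    The TSS is the interval start on '+' and the last base on '-'.
    Windows are clipped to chromosome bounds.
    """
    out = []
    for rec in tss:
        if rec.strand == "+":
            t = rec.start
            s, e = t - upstream, t + downstream
        elif rec.strand == "-":
            t = rec.end - 1
            s, e = t - downstream + 1, t + upstream + 1
        else:
            raise ValueError(f"TSS record {rec.chrom}:{rec.start} lacks a strand")
        s = max(0, s)
        if chrom_lengths is not None:
            e = min(e, chrom_lengths[rec.chrom])
        out.append(GenomicInterval(rec.chrom, s, e, strand=rec.strand,
                                   name=rec.name))
    return out


def make_tad_boundaries(domains: Iterable[GenomicInterval], half_width: int = 2000,
                        merge: bool = False,
                        chrom_lengths: Optional[dict[str, int]] = None,
                        ) -> list[GenomicInterval]:
    """4 kb boundary windows centered on each domain's start and end."""
    out = []
    for dom in domains:
        if len(dom) < 2 * half_width:
            warnings.warn(f"domain {dom.chrom}:{dom.start}-{dom.end} shorter than "
                          "a boundary window; windows overlap")
        for edge in (dom.start, dom.end):
            s = max(0, edge - half_width)
            e = edge + half_width
            if chrom_lengths is not None:
                e = min(e, chrom_lengths[dom.chrom])
            out.append(GenomicInterval(dom.chrom, s, e, name=dom.name))
    if merge:
        out = merge_intervals(out)
    return out


# ---------------------------------------------------------------------------
# Enrichment

@dataclass
class EnrichmentResult:
    """2x2 overlap table with odds ratio and p-value."""

    in_region_query: int
    out_region_query: int
    in_region_rest: int
    out_region_rest: int
    odds_ratio: float
    p_value: float
    method: str
    n_shuffles: Optional[int] = None
    seed: Optional[int] = None

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.in_region_query, self.out_region_query],
                         [self.in_region_rest, self.out_region_rest]])


def _site_windows(sites: Sequence[GenomicInterval], site_mode: str,
                  window_flank: int) -> list[GenomicInterval]:
    if site_mode == "motif":
        return list(sites)
    if site_mode == "window":
        return [GenomicInterval(s.chrom, max(0, s.start - window_flank),
                                s.end + window_flank, strand=s.strand,
                                name=s.name) for s in sites]
    raise ValueError(f"unknown site mode {site_mode!r}")


def enrichment_fisher(query: Sequence[GenomicInterval],
                      regions: Sequence[GenomicInterval],
                      universe: Sequence[GenomicInterval],
                      site_mode: str = "motif",
                      window_flank: int = 1000) -> EnrichmentResult:
    """Two-sided Fisher exact test of query sites against a region set.

    The universe is the full set of tested sites (query must be a subset);
    a site overlaps a region at >= 1 bp intersection.  ``site_mode='window'``
    tests each site's footprint window (site +/- window_flank) instead of the
    motif itself.
    """
    if not universe:
        raise ValueError("empty universe")
    qkeys = {(s.chrom, s.start, s.end) for s in query}
    ukeys = {(s.chrom, s.start, s.end) for s in universe}
    if not qkeys <= ukeys:
        raise ValueError("query sites must be a subset of the universe")
    index = IntervalIndex(regions) if regions else None
    uwin = _site_windows(universe, site_mode, window_flank)
    hits = (index.overlaps_many(uwin) if index is not None
            else np.zeros(len(uwin), dtype=bool))
    is_query = np.array([(s.chrom, s.start, s.end) in qkeys for s in universe])
    a = int((hits & is_query).sum())
    b = int((~hits & is_query).sum())
    c = int((hits & ~is_query).sum())
    d = int((~hits & ~is_query).sum())
    if b * c == 0 and a * d > 0:
        odds = np.inf
    elif a * d == 0 and b * c > 0:
        odds = 0.0
    elif b * c == 0:
        odds = np.inf
    else:
        odds = (a * d) / (b * c)
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return EnrichmentResult(a, b, c, d, float(odds), p, method="fisher")


def circular_shift(sites: Sequence[GenomicInterval],
                   chrom_lengths: dict[str, int],
                   rng: np.random.Generator) -> list[GenomicInterval]:
    """Shift all sites on each chromosome by one random circular offset.

    Preserves the number of sites and their cyclic spacing.  A site that
    wraps past the chromosome end is placed at the wrapped start position.
    """
    out = []
    offsets = {c: int(rng.integers(0, n)) for c, n in chrom_lengths.items()}
    for s in sites:
        n = chrom_lengths[s.chrom]
        new_start = (s.start + offsets[s.chrom]) % n
        length = len(s)
        if new_start + length > n:
            new_start = (new_start + length) % n  # wrapped: re-enter at start
            new_start = min(new_start, n - length)
        out.append(GenomicInterval(s.chrom, new_start, new_start + length,
                                   strand=s.strand))
    return out


def enrichment_empirical(query: Sequence[GenomicInterval],
                         regions: Sequence[GenomicInterval],
                         chrom_lengths: dict[str, int],
                         n_shuffles: int = 1000, seed: int = 0,
                         site_mode: str = "motif",
                         window_flank: int = 1000) -> EnrichmentResult:
    """Empirical enrichment p-value from a circular-shift null.

    The statistic is the number of query sites overlapping the region set;
    the null shifts the query circularly within each chromosome, preserving
    inter-site spacing.  p = (1 + #{null >= observed}) / (n + 1).
    """
    if n_shuffles < 100:
        warnings.warn(f"only {n_shuffles} shuffles: minimum attainable p is "
                      f"{1.0 / (n_shuffles + 1):.3g}")
    index = IntervalIndex(regions)
    qwin = _site_windows(query, site_mode, window_flank)
    observed = int(index.overlaps_many(qwin).sum())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_shuffles):
        shifted = circular_shift(query, chrom_lengths, rng)
        swin = _site_windows(shifted, site_mode, window_flank)
        if int(index.overlaps_many(swin).sum()) >= observed:
            count += 1
    p = (1 + count) / (n_shuffles + 1)
    n_q = len(query)
    return EnrichmentResult(observed, n_q - observed, 0, 0,
                            odds_ratio=np.nan, p_value=float(p),
                            method="empirical", n_shuffles=n_shuffles, seed=seed)


# ---------------------------------------------------------------------------
# Jaccard clustering

@dataclass
class JaccardMatrix:
    matrix: pd.DataFrame
    order: list[int]
    empty_sets: list[str] = field(default_factory=list)


def jaccard_matrix(interval_sets: dict[str, Sequence[GenomicInterval]],
                   ) -> JaccardMatrix:
    """Pairwise bp-level Jaccard indices with a clustering display order.

    J(A, B) = |A n B| / |A u B| in total base pairs after merging each set
    internally.  J involving an empty set is 0 (flagged).  The order is from
    average-linkage clustering on 1 - J.
    """
    names = list(interval_sets)
    merged = {k: merge_intervals(v) for k, v in interval_sets.items()}
    lengths = {k: total_length(v) for k, v in merged.items()}
    empty = [k for k, n in lengths.items() if n == 0]
    k = len(names)
    J = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            if i == j:
                J[i, j] = 1.0 if lengths[names[i]] > 0 else 0.0
                continue
            inter = intersection_length(merged[names[i]], merged[names[j]])
            union = lengths[names[i]] + lengths[names[j]] - inter
            J[i, j] = J[j, i] = inter / union if union > 0 else 0.0
    mat = pd.DataFrame(J, index=names, columns=names)
    if k >= 2:
        dist = 1.0 - J
        np.fill_diagonal(dist, 0.0)
        order = list(hierarchy.leaves_list(
            hierarchy.linkage(squareform(dist, checks=False), method="average")))
    else:
        order = list(range(k))
    return JaccardMatrix(mat, order, empty_sets=empty)


# ---------------------------------------------------------------------------
# Overlap categorization and conservation

def categorize_overlap(query: Sequence[GenomicInterval],
                       peaks_a: Sequence[GenomicInterval],
                       peaks_b: Sequence[GenomicInterval],
                       include_b_only: bool = False) -> pd.DataFrame:
    """Assign each query site to {A-only, A-and-B, (B-only,) neither}.

    Categories are exhaustive and mutually exclusive; the table reports
    counts and percentages of the query total to one decimal.
    """
    ia = IntervalIndex(peaks_a)
    ib = IntervalIndex(peaks_b)
    in_a = ia.overlaps_many(query)
    in_b = ib.overlaps_many(query)
    counts = {
        "a_only": int((in_a & ~in_b).sum()),
        "a_and_b": int((in_a & in_b).sum()),
    }
    if include_b_only:
        counts["b_only"] = int((~in_a & in_b).sum())
        counts["neither"] = int((~in_a & ~in_b).sum())
    else:
        counts["neither"] = int(len(query) - counts["a_only"] - counts["a_and_b"])
    total = len(query)
    rows = [dict(category=k, count=v,
                 percent=round(100.0 * v / total, 1) if total else 0.0)
            for k, v in counts.items()]
    return pd.DataFrame(rows)


def compare_conservation(bound: Sequence[GenomicInterval],
                         unbound: Sequence[GenomicInterval],
                         conservation: Optional[Track] = None,
                         ) -> tuple[float, float, pd.DataFrame]:
    """Mann-Whitney U comparison of per-site conservation, bound vs unbound.

    Sites either carry their mean conservation in ``score`` or a track is
    given to compute it.  Returns (U, two-sided p, per-group quartile table).
    """
    def values(sites):
        if conservation is not None:
            return np.array([conservation.mean_over(s.chrom, s.start, s.end)
                             for s in sites])
        return np.array([s.score for s in sites], dtype=float)

    vb, vu = values(bound), values(unbound)
    if len(vb) < 3 or len(vu) < 3:
        raise ValueError("need at least 3 sites per group")
    u, p = stats.mannwhitneyu(vb, vu, alternative="two-sided")
    rows = []
    for name, v in (("bound", vb), ("unbound", vu)):
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append(dict(group=name, n=len(v), q1=q1, median=med, q3=q3,
                         mean=v.mean()))
    return float(u), float(p), pd.DataFrame(rows)
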