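# Methods

`nucfoot` infers transcription-factor occupancy in condensed (sperm-like)
chromatin from the spatial pattern of nuclease-digestion fragment
midpoints around candidate binding motifs, and provides the surrounding
statistics: motif scanning, factor triage, nucleosome-phasing profiling,
and interval enrichment. This note records the models, the parameters
that matter, and the design choices made where the design was open.

## Motif scanning

A motif is a position weight matrix (PWM): per-position probabilities
over {A, C, G, T}, built from a count matrix with a pseudocount of 0.5
per cell (so all probabilities are strictly positive; supply counts, not
frequencies, or the pseudocount will flatten the matrix). A window of
motif length L scores

&nbsp;&nbsp;&nbsp;&nbsp;S = Σᵢ log₂( pᵢ(baseᵢ) / 0.25 ),

the log₂ likelihood ratio of the motif model against a uniform
background; S = 13 bits means the window is 2¹³ ≈ 8,000-fold more likely
under the motif model than by chance, and the default scan keeps windows
scoring strictly above 13. An ambiguous base contributes
log₂(mean p / 0.25). Both strands are scanned; overlapping same-motif
hits within L bp are deduplicated keeping the highest score, with ties
(rounded at 10⁻⁶ bits, so summation order cannot flip them) resolved to
the '+' strand, then leftmost.

Candidate selection before footprinting: *primary* keeps instances whose
2 kb window has mappability ≥ 0.99, then the top PWM-score quintile
(k = ⌈n/5⌉-th largest score, boundary ties all kept); *extended* keeps
mappability ≥ 0.90 and score ≥ 14 with no quintile cut; *ctcf-relaxed*
keeps mappability ≥ 0.99 and score ≥ 13. Covariates per instance:
flanking GC (mean GC fraction over consecutive 5 bp blocks within
±200 bp, motif excluded — for complete blocks this equals the plain GC
fraction of the flanks; the block-mean form is kept because the flank
width need not be a multiple of five), motif conservation (mean track
value over motif bases), and window mappability.

## The footprint mixture model

Each selected instance l contributes a count window: midpoints per base
over motif ± 1 kb, split by strand of origin (a 2 × W matrix,
W = 2000 + L), with minus-strand instances flipped so all windows share
the motif's 5′→3′ frame. A latent indicator Z_l marks occupancy.

* Prior: P(Z_l = 1) = logistic(β₀ + β₁ · PWM_l). Only the PWM score
  enters the prior; GC and conservation are assessed post hoc in the
  triage stage, keeping the occupancy model and its evaluation separate.
* Given Z_l = 1: the window total T_l ~ NegBin(μ₁, r₁) (variance
  μ + μ²/r) and positions ~ Multinomial(T_l, λ) with λ a learned simplex
  over the 2W cells — together the negative-multinomial footprint model.
* Given Z_l = 0: T_l ~ NegBin(μ₀, r₀) and positions uniform. The
  background spatial profile is fixed uniform rather than learned; this
  matches the flat unbound/naked-DNA aggregate and stabilizes the EM.

EM details, all in log space (2W-cell multinomials underflow otherwise;
the multinomial coefficient cancels between components and is dropped):

* E-step: π_l = σ(prior logit + log-likelihood ratio).
* M-step: λ from posterior-weighted counts with Dirichlet smoothing
  0.1/cell (prevents zero cells at moderate depth); (μ, r) per component
  by posterior-weighted method of moments plus one Newton refinement on
  r, accepted only if the weighted NB likelihood does not decrease; β by
  Newton iterations on the weighted fractional-logistic objective,
  likewise accept-if-improved. Every step is therefore a
  generalized-EM ascent step, and the monitored objective (observed-data
  log likelihood plus the Dirichlet term) is asserted non-decreasing at
  every iteration.
* Initialization is deterministic and permutation-invariant: λ from the
  windows with totals at or above the 90th percentile, (μ, r) from a
  2-means split of the totals, β = (logit 0.1, 0.1).
* Components are labeled so μ₁ ≥ μ₀ (the bound component digests at
  least as deep); convergence at relative objective change < 10⁻⁶ or
  200 iterations.

Classification: bound if π ≥ 0.95, unbound if π ≤ 0.5, ambiguous
between.

### Degeneracy guards

A per-base profile over ~4,000 cells can lock onto sampling noise: on a
spatially flat library the windows that seed λ would be certified as
their own footprint. Two guards prevent this.

1. *Spatial informativeness.* The pooled counts of the initialization
   windows — selected on totals alone, hence uniform-multinomial under a
   flat library — are tested against uniform with Pearson's X²
   (p ≤ 0.01 to proceed). Pearson is used rather than the
   likelihood-ratio G because at a few reads per cell G is biased upward
   while X² keeps its exact null mean of k − 1. If the test fails, λ is
   fixed at uniform for the whole fit.
2. *Totals parsimony.* With a flat profile the only remaining evidence
   is the totals, and a two-component NB mixture fitted to
   single-component data will capture the tail. The converged mixture is
   therefore compared with a single NB by BIC (the mixture spends four
   extra parameters); if the mixture is not supported, the model reports
   "no footprint evidence" and the posteriors equal the logistic prior.

With both guards an all-unbound library yields 0% bound calls across
seeds while recovery on structured libraries is unchanged. Windows that
are literally identical short-circuit to the prior with the same flag.

### Operating range

The profile needs enough pooled depth to rise above its own estimation
noise: below roughly 500 windows at 100 midpoints each, the EM can
settle on a stable optimum in which the bound component holds only the
deepest sites (observed at 300–400 windows × 80 midpoints). All shipped
analyses use ≥ 600 windows; the fitter refuses fewer than 50 outright.

## Factor triage

Per factor, posteriors are regressed on (PWM, GC, conservation) with a
logit-link fractional-response GLM under a quasi-binomial variance (the
Pearson-χ² scale), covariates standardized internally and coefficients
reported back on the original scale; Z = coefficient / SE. A factor is
kept when Z_PWM ≥ 5 (the boundary value is kept): if the motif score
itself does not predict the footprint, the footprint is not credible
evidence for that factor. Complete separation is flagged with a +∞
sentinel. A binarized cross-check mode (π ≥ 0.95 → 1, π ≤ 0.5 → 0,
middle dropped) is exposed; it agrees in coefficient sign with the
fractional fit on all default simulations. No multiplicity correction is
applied — the rule is a fixed Z cutoff, not an FDR procedure.

## Profiles and nucleosome phasing

Aggregate profiles are per-position mean midpoint frequencies over the
window by group (bound / unbound / control), strands summed, optionally
depth-normalized per group. The phasing estimator folds the two flanks
into one distance axis (excluding a 50 bp core), smooths with a 21 bp
reflect-padded boxcar, and takes

* *period* — the argmax of the smoothed autocorrelation over lags
  100–250 bp (a range bracketing, not assuming, the nucleosome repeat);
* *significance* — the maximal autocorrelation in that lag window
  against 1,000 random position permutations of the profile. A
  circular-shift null is powerless here because autocorrelation is
  itself invariant under circular shifts; permutation destroys spatial
  order while preserving the value distribution;
* *extent* — the largest distance at which the oscillation amplitude
  (rolling RMS over one period of the locally detrended profile)
  exceeds 3× the control profile's amplitude, judged on the interior of
  the window (one period excluded at each end, where rolling statistics
  are edge-biased). An extent below one period is reported as undefined.

The 3×-control rule is a detection boundary, not an unbiased extent
estimator: with a linearly decaying array it crosses somewhat before the
true die-out distance, the more so the shallower the libraries
(~1,360 bp at the default depth for a 1,500 bp array). Profiles for
extent estimation should extend at least as far as the expected array
(the drivers use ±2 kb windows) and the profiled sites must be spaced so
that neighboring sites' digestion does not reach into the wide windows.

## Interval statistics

Coverage tracks are midpoint counts in fixed bins (500 bp genome-wide;
50 bp with a 5-bin sliding window for 20 kb regional comparisons),
compared by Spearman rank correlation — rank-based, so unnormalized
counts suffice — with average-linkage clustering on 1 − ρ for display
order. Promoters are strand-aware −5 kb/+0.25 kb windows around the
TSS; TAD boundaries are 4 kb windows centered on domain edges.

Enrichment uses a site-overlap rule of ≥ 1 bp intersection, with a
window mode that tests each site's 2 kb footprint window instead of the
motif (the default for single-coordinate peak sets such as enhancer
midpoints). The Fisher test conditions on the tested sites: the universe
is the full selected-instance set for that factor, not the genome. The
empirical alternative shifts the query circularly within each chromosome
(one offset per chromosome, preserving inter-site spacing; wrapped sites
re-enter at the start) and reports p = (1 + #{null ≥ observed})/(n + 1);
with heavy ties in the overlap statistic this p is conservative, so
calibration checks use configurations with wide statistic support.
Jaccard similarity is |A ∩ B| / |A ∪ B| in base pairs after merging each
set. The conservation comparison is a two-sided Mann–Whitney U with
midrank ties on per-site mean conservation.

## The synthetic-digestion generator

The generator emulates the features of a nuclease-digestion experiment
that the analysis relies on, with closed-form ground truth:

* i.i.d. genome at a stated GC (default 0.5), mappability 1.0 (optional
  low patches), conservation Beta(2, 8) background elevated to Beta(8, 2)
  inside planted motifs so the covariate is informative;
* motif instances drawn *from* the PWM (realized scores vary, mean
  ≈ 14 bits, SD ≈ 5 for the default 12-mer), planted on random strands
  with pairwise spacing such that no site's digestion spread reaches
  another's analysis window (≥ max(2 kb, flank + generation flank));
* occupancy ~ Bernoulli(logistic(β₀ + β·covariates)), default
  β = (−7, 0.5, 0, 0): a bound fraction near 0.5 driven by the PWM;
* per-site totals ~ NegBin(mean 100, dispersion 10; ×3 when occupied —
  protein-protected sites yield more nucleosomal fragments), positions
  multinomial on the bound profile (depleted core of relative density
  0.1 over motif ± 15 bp, flanks 1 + A(d)·cos(2πd/160) with A decaying
  linearly from 0.8 to zero at 1.5 kb, symmetric, strands split 50/50)
  or uniform when unoccupied; midpoints are spread over motif
  ± (decay extent + 4 periods) so the array is never truncated at the
  analysis-window edge;
* a flat naked-DNA control over the same sites at the unbound depth, and
  a genome-wide Poisson background (0.002 midpoints/bp).

Everything is deterministic under a fixed seed. What the generator does
*not* emulate: sequence-dependent nuclease cleavage bias, fragment-length
structure, PCR duplicates, mappability artifacts correlated with real
repeats, strand asymmetries, and inter-site heterogeneity of the
footprint shape. Passing recovery tests therefore demonstrates the
estimators' correctness under the stated statistical structure, not
robustness to those real-data complications.

## Worked-example inputs

The genome-scale counts from the mouse sperm analyses (the Ctcf/Boris
overlap partition 5,034/1,075/1,857, the 5,009/5,797 and 6,109/7,967
peak overlaps, the 354/1,130 homeobox–olfactory-promoter overlap) are
carried as reference inputs; the package reproduces their percentage
arithmetic through the same interval machinery used for synthetic data.
The three partition counts sum to 7,966 although the stated total is
7,967; percentages at one decimal are identical under either
denominator, and the reconstruction realizes the three counts exactly.

## Problem sizes

Shipped analyses and checks use: recovery at 2,000 sites × 100 (and 200)
midpoints/site, triage at 5,000 sites, phasing at 2,000 sites with
4.5 kb spacing, null calibration at 2,000 sites, oracle equivalences on
≤ 100 kb genomes and ≤ 200-site universes. These sizes give stable
estimates (recall/specificity vary by < 1 percentage point and the
period estimate is exact across seeds) while keeping any single run
under a minute.
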