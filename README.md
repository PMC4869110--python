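# nucfoot

Nuclease footprinting of condensed chromatin: infer which
transcription-factor motifs are occupied from the spatial pattern of
digestion-fragment midpoints around them.

Mature sperm replace most histones with protamines, yet nuclease
digestion (MNase or DFF) still releases nucleosome-protected DNA, and
around a *bound* regulatory factor the fragment midpoints form a
characteristic footprint: a protected core over the motif flanked by
phased nucleosome arrays (~160 bp repeat, decaying over ~1.5 kb). This
package implements that inference end to end for anyone analyzing
nuclease-seq libraries of highly condensed or unusual chromatin:

* **PWM scanning** — log₂ likelihood-ratio scores against a uniform
  background; sites with S > 13 bits (≈ 8,000× over chance) become
  candidates, filtered by mappability and PWM rank.
* **Footprint mixture model** — per site *l*, a latent occupancy
  indicator Z_l with prior P(Z_l=1) = σ(β₀ + β₁·PWM_l); given Z_l=1 the
  window total is NegBin(μ₁, r₁) and midpoint positions are multinomial
  on a learned footprint profile λ; given Z_l=0, NegBin(μ₀, r₀) and
  uniform. EM yields a posterior probability of binding π_l; sites with
  π_l ≥ 0.95 are called bound, π_l ≤ 0.5 unbound.
* **Factor triage** — a quasi-binomial fractional-logistic GLM of π on
  (PWM, flanking GC, conservation); factors are kept when Z_PWM ≥ 5.
* **Phasing profiles** — aggregate midpoint profiles by call group and
  an autocorrelation estimator of the nucleosome repeat length, its
  extent, and permutation significance.
* **Genomic statistics** — binned-coverage Spearman correlations,
  Fisher and circular-shift-empirical interval enrichment, bp-level
  Jaccard clustering, promoter/TAD-boundary builders, and
  bound-versus-unbound conservation comparison.
* **Synthetic digestion generator** — ground-truth experiments with
  planted motifs, logistic occupancy, footprint-shaped midpoints, and a
  flat naked-DNA control, used by every recovery test.

See `docs/methods.md` for the full model description and design choices.

## Worked example

The numbered drivers under `analysis/` run a complete synthetic study
(each builds on the previous one's files under `results/`):

```sh
python analysis/01_simulate_experiment.py
python analysis/02_scan_motifs.py
python analysis/03_fit_footprints.py
python analysis/04_triage_factors.py
python analysis/05_profile_periodicity.py
python analysis/06_enrichment_stats.py
python analysis/07_coverage_correlation.py
```

Driver 03 prints, for 1,000 planted sites at 100 midpoints each:

```
EM converged in 10 iterations; depth mu0=51.4 mu1=142.8; prior beta=(-6.47, 0.463)
status counts: {'bound': 509, 'unbound': 486, 'ambiguous': 5}
against truth: 98.5% of occupied sites bound (pi >= 0.95); 99.4% of unoccupied sites unbound (pi <= 0.5)
```

μ₀/μ₁ are the fitted unbound/bound mean window depths (the generating
values are 50 and 150 inside the ±1 kb window: half of each site's
midpoints land outside it) and the prior slope 0.463 recovers the
generating PWM effect of 0.5. Driver 04 then keeps the factor
(Z_PWM = +16.3) while a permuted negative control is dropped
(Z_PWM = −0.06), and driver 05 reports the phased array around bound
sites:

```
bound (n=509): period=160.0 bp, extent=1289.0 bp, permutation p=0.000999
unbound (n=486): period=250.0 bp, extent=None bp, permutation p=0.1109
control (n=1000): period=250.0 bp, extent=None bp, permutation p=0.3996
```

— the 160 bp nucleosome repeat is recovered exactly and is absent from
unbound sites and naked DNA. A subcommand CLI (`nucfoot simulate`,
`scan`, `footprint`, `triage`, `profile`, `enrich`, `corr`) wraps the
same library for shell use.

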