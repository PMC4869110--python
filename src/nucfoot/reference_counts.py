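"""Published overlap counts from mouse sperm nuclease-footprinting analyses.

These contingency counts are the worked-example inputs for the package's
interval statistics: the genome-scale analyses behind them need the real
sperm libraries, but the categorization and percentage arithmetic is fully
reproducible from the counts themselves.

* Ctcf sites called bound in mature sperm versus round-spermatid ChIP-seq
  peaks: under the primary selection, 5,009 of 5,797 bound motifs coincide
  with a spermatid Ctcf peak; relaxing the PWM floor to 13 bits adds 2,170
  footprints for a complete set of 7,967, of which 6,109 overlap a peak.
* The complete set partitions into sites overlapping spermatid peaks of
  Ctcf alone (5,034), of Ctcf co-occupied with its paralog Boris (1,075),
  and sites with no spermatid peak (1,857).  Note the three categories sum
  to 7,966 while the stated total is 7,967; percentages printed to one
  decimal are identical under either denominator.
* Merged homeobox-family footprints overlap 354 of the 1,130 olfactory
  receptor gene promoters.
"""

from __future__ import annotations

from .intervals import GenomicInterval

CTCF_COMPLETE_TOTAL = 7967
CTCF_SPERMATID_ONLY = 5034
CTCF_SPERMATID_WITH_BORIS = 1075
CTCF_NO_SPERMATID_PEAK = 1857

CTCF_PRIMARY_TOTAL = 5797
CTCF_PRIMARY_WITH_PEAK = 5009
CTCF_RELAXED_TOTAL = 7967
CTCF_RELAXED_WITH_PEAK = 6109

OLFACTORY_PROMOTERS = 1130
OLFACTORY_PROMOTERS_WITH_HOMEOBOX = 354

_SITE = 20      # toy site length, bp
_PITCH = 100    # toy site spacing, bp


def _site(i: int) -> GenomicInterval:
    return GenomicInterval("chrW", i * _PITCH, i * _PITCH + _SITE)


def _covering(i0: int, i1: int) -> GenomicInterval:
    """One peak covering toy sites i0..i1-1 and nothing else."""
    return GenomicInterval("chrW", i0 * _PITCH, (i1 - 1) * _PITCH + _SITE)


def realize_ctcf_categorization():
    """Interval sets realizing the three-way Ctcf/Boris partition.

    Returns (query_sites, ctcf_peaks, boris_peaks); the categorization
    {Ctcf-only, Ctcf-and-Boris, neither} reproduces the published counts.
    """
    n_only = CTCF_SPERMATID_ONLY
    n_both = CTCF_SPERMATID_WITH_BORIS
    n_none = CTCF_NO_SPERMATID_PEAK
    query = [_site(i) for i in range(n_only + n_both + n_none)]
    ctcf_peaks = [_covering(0, n_only + n_both)]
    boris_peaks = [_covering(n_only, n_only + n_both)]
    return query, ctcf_peaks, boris_peaks


def realize_binary_overlap(total: int, hits: int):
    """``total`` toy sites of which exactly ``hits`` fall inside regions."""
    sites = [_site(i) for i in range(total)]
    regions = [_covering(0, hits)] if hits else []
    return sites, regions
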