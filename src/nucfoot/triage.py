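"""Per-factor credibility triage of footprint posteriors.

For each motif, the posterior binding probabilities are regressed on the
three site covariates (PWM score, flanking GC, conservation) with a
logit-link fractional-response GLM under a quasi-binomial variance.  A
factor is kept for downstream analysis when the Z-score of its PWM
coefficient is >= 5: if the motif score itself does not predict the
footprint, the footprint is not credible evidence for that factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

Z_THRESHOLD = 5.0
COVARIATES = ("pwm", "gc", "cons")
_SEPARATION_Z = np.inf


@dataclass
class TriageResult:
    """Eq-style GLM fit for one factor/motif."""

    factor: str
    coef: np.ndarray          # intercept + slopes, original covariate scale
    se: np.ndarray
    z: np.ndarray
    kept: bool
    n_sites: int
    separation: bool = False
    terms: tuple = ("intercept",) + COVARIATES

    @property
    def z_pwm(self) -> float:
        return float(self.z[1])

    def as_row(self) -> dict:
        row = {"factor": self.factor, "n_sites": self.n_sites,
               "kept": self.kept, "separation": self.separation}
        for i, t in enumerate(self.terms):
            row[f"coef_{t}"] = self.coef[i]
            row[f"se_{t}"] = self.se[i]
            row[f"z_{t}"] = self.z[i]
        return row


def fit_covariate_glm(posteriors: np.ndarray, covariates: pd.DataFrame,
                      factor: str = "", z_threshold: float = Z_THRESHOLD,
                      binarize: bool = False) -> TriageResult:
    """Fit the fractional logistic GLM of posteriors on (PWM, GC, cons).

    Covariates are standardized internally for conditioning and the
    coefficients reported back on the original scale (Z-scores are
    invariant to that affine rescaling).  Standard errors are quasi-binomial
    (Pearson-chi-square scale).  With ``binarize`` the middle band of
    posteriors is dropped and the ends regressed as 0/1 outcomes -- a
    cross-check mode, not the default.
    """
    pi = np.asarray(posteriors, dtype=float)
    if ((pi < 0) | (pi > 1)).any():
        raise ValueError("posteriors must lie in [0, 1]")
    missing = [c for c in COVARIATES if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table missing columns {missing}")
    if len(pi) < 30:
        raise ValueError(f"need >= 30 sites to triage a factor, got {len(pi)}")
    Xraw = covariates.loc[:, list(COVARIATES)].to_numpy(dtype=float)
    y = pi
    if binarize:
        keep = (pi >= 0.95) | (pi <= 0.5)
        y = (pi[keep] >= 0.95).astype(float)
        Xraw = Xraw[keep]
    k = Xraw.shape[1]
    if np.ptp(y) < 1e-12:
        zeros = np.zeros(k + 1)
        return TriageResult(factor, zeros, zeros, zeros, kept=False,
                            n_sites=len(pi))
    mean = Xraw.mean(axis=0)
    sd = Xraw.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = sm.add_constant((Xraw - mean) / sd, has_constant="add")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, Xs, family=sm.families.Binomial()).fit(scale="X2")
        except Exception:
            separation = True
            res = None
    if res is not None and (np.abs(res.params).max() > 1e3
                            or not np.all(np.isfinite(res.bse))):
        separation = True
    if separation:
        z = np.full(k + 1, _SEPARATION_Z)
        warnings.warn(f"complete separation in triage GLM for {factor!r}")
        return TriageResult(factor, np.full(k + 1, np.nan),
                            np.full(k + 1, np.nan), z, kept=True,
                            n_sites=len(pi), separation=True)
    # back-transform standardized fit to the original covariate scale
    coef = np.empty(k + 1)
    se = np.empty(k + 1)
    coef[1:] = res.params[1:] / sd
    se[1:] = res.bse[1:] / sd
    coef[0] = res.params[0] - np.sum(res.params[1:] * mean / sd)
    se[0] = res.bse[0]
    z = np.zeros(k + 1)
    nonzero = se > 0
    z[nonzero] = coef[nonzero] / se[nonzero]
    kept = bool(z[1] >= z_threshold)
    return TriageResult(factor, coef, se, z, kept=kept, n_sites=len(pi))


def select_factors(results: Sequence[TriageResult],
                   ) -> tuple[list[str], pd.DataFrame]:
    """Apply the Z_PWM >= 5 filter and build the Z-score scatter table.

    The returned table has one row per motif with Z_PWM against Z_GC and
    Z_cons -- the backing data for covariate scatter displays.
    """
    kept = [r.factor for r in results if r.kept]
    table = pd.DataFrame([
        dict(factor=r.factor, n_sites=r.n_sites, z_pwm=r.z[1],
             z_gc=r.z[2], z_cons=r.z[3], kept=r.kept)
        for r in results
    ])
    return kept, table


def triage_table(results: Sequence[TriageResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])
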