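"""Two-component mixture model of digestion midpoints around motifs.

Each selected motif instance l contributes a count window: midpoints per
base over motif +/- 1 kb, split by strand of origin.  A latent indicator
Z_l says whether the site is occupied.  Given Z_l = 1 the total count is
negative binomial (mu1, r1) and positions are multinomial on a learned
footprint profile lambda; given Z_l = 0 the total is NB(mu0, r0) and
positions are uniform.  The prior P(Z_l = 1) is logistic in the site's
PWM score.  EM alternates posterior computation with closed-form or
guaranteed-ascent parameter updates, all in log space, and reports a
posterior probability of binding pi_l per site.

A site is called bound when pi_l >= 0.95 and unbound when pi_l <= 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import expit, psi
from scipy.stats import chi2, nbinom

from .io import MidpointSet
from .motif_scan import MotifInstance

BOUND_THRESHOLD = 0.95
UNBOUND_THRESHOLD = 0.5
DIRICHLET_SMOOTHING = 0.1


@dataclass
class CountWindows:
    """Midpoint counts for a batch of motif windows.

    ``matrix`` is a CSR matrix of shape (n_windows, 2 * W): the first W
    columns are '+'-origin midpoints, the last W are '-'-origin, both in
    the motif's 5'->3' frame (minus-strand instances are flipped).
    """

    instances: list[MotifInstance]
    matrix: sparse.csr_matrix
    flank: int
    motif_length: int

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def width(self) -> int:
        return self.matrix.shape[1] // 2

    @property
    def totals(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel().astype(np.int64)

    def dense_window(self, i: int) -> np.ndarray:
        """Counts for window i as a dense (2, W) array."""
        return np.asarray(self.matrix[i].todense()).reshape(2, self.width)

    def pwm_scores(self) -> np.ndarray:
        return np.array([inst.pwm_score for inst in self.instances])

    def subset(self, mask: np.ndarray) -> "CountWindows":
        idx = np.flatnonzero(mask)
        return CountWindows([self.instances[i] for i in idx],
                            self.matrix[idx], self.flank, self.motif_length)


def build_count_windows(instances: Sequence[MotifInstance], midpoints: MidpointSet,
                        chrom_lengths: dict[str, int], flank: int = 1000,
                        ) -> CountWindows:
    """Count midpoints into motif +/- flank windows, flipped to motif frame.

    Windows truncated by a chromosome edge are dropped.  All-zero windows
    are retained -- they carry signal for the unbound component.
    """
    if not instances:
        return CountWindows([], sparse.csr_matrix((0, 0)), flank, 0)
    L = len(instances[0].interval)
    W = 2 * flank + L
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    kept: list[MotifInstance] = []
    for inst in instances:
        w_start = inst.start - flank
        w_end = inst.end + flank
        if w_start < 0 or w_end > chrom_lengths[inst.chrom]:
            continue
        i = len(kept)
        kept.append(inst)
        pos = midpoints.pos.get(inst.chrom)
        if pos is None or len(pos) == 0:
            continue
        lo = np.searchsorted(pos, w_start, side="left")
        hi = np.searchsorted(pos, w_end, side="left")
        if hi == lo:
            continue
        offset = pos[lo:hi] - w_start
        plus = midpoints.strand[inst.chrom][lo:hi]
        if inst.strand == "-":
            offset = W - 1 - offset
            plus = ~plus
        cols.append(np.where(plus, offset, offset + W))
        rows.append(np.full(hi - lo, i, dtype=np.int64))
    n = len(kept)
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        mat = sparse.coo_matrix((np.ones(len(r)), (r, c)),
                                shape=(n, 2 * W)).tocsr()
    else:
        mat = sparse.csr_matrix((n, 2 * W))
    return CountWindows(kept, mat, flank, L)


@dataclass
class FootprintModel:
    """Fitted mixture parameters and convergence log."""

    lam: np.ndarray                 # (2, W) bound spatial profile, sums to 1
    lam0: np.ndarray                # (2, W) background profile (uniform)
    mu1: float
    r1: float
    mu0: float
    r0: float
    beta: np.ndarray                # (2,) prior: intercept, PWM slope
    loglik_trace: list = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    flags: list = field(default_factory=list)
    pool_strands: bool = False

    def prior_logit(self, pwm_scores: np.ndarray) -> np.ndarray:
        return self.beta[0] + self.beta[1] * np.asarray(pwm_scores)

    def posteriors(self, windows: CountWindows,
                   pwm_scores: Optional[np.ndarray] = None) -> np.ndarray:
        """P(Z_l = 1 | counts) for every window, computed in log space."""
        if pwm_scores is None:
            pwm_scores = windows.pwm_scores()
        X = _prepare_matrix(windows, self.pool_strands)
        T = windows.totals
        ll1 = X @ np.log(self.lam.ravel()) + _nb_logpmf(T, self.mu1, self.r1)
        ll0 = X @ np.log(self.lam0.ravel()) + _nb_logpmf(T, self.mu0, self.r0)
        return expit(self.prior_logit(pwm_scores) + (ll1 - ll0))


def _prepare_matrix(windows: CountWindows, pool_strands: bool):
    if not pool_strands:
        return windows.matrix
    W = windows.width
    return windows.matrix[:, :W] + windows.matrix[:, W:]


def _nb_logpmf(t: np.ndarray, mu: float, r: float) -> np.ndarray:
    return nbinom.logpmf(t, r, r / (r + mu))


def _weighted_nb_fit(t: np.ndarray, w: np.ndarray,
                     mu_old: float, r_old: float) -> tuple[float, float]:
    """Posterior-weighted method of moments plus one Newton refinement on r.

    The candidate is only accepted if it does not decrease the weighted NB
    log likelihood, preserving the generalized-EM ascent property.
    """
    wsum = w.sum()
    if wsum < 1e-8:
        return mu_old, r_old
    mu = float((w * t).sum() / wsum)
    mu = max(mu, 1e-6)
    var = float((w * (t - mu) ** 2).sum() / wsum)
    if var > mu * (1.0 + 1e-6):
        r = mu ** 2 / (var - mu)
    else:
        r = 1e4  # effectively Poisson
    r = float(np.clip(r, 1e-2, 1e6))
    # one Newton step on log r for the weighted NB profile likelihood
    def dll(rv: float) -> float:
        return float((w * (psi(t + rv) - psi(rv) + np.log(rv / (rv + mu))
                           + (mu - t) / (rv + mu))).sum())
    g = dll(r)
    h = (dll(r * 1.001) - g) / (r * 0.001)
    if np.isfinite(g) and np.isfinite(h) and h < 0:
        r_new = float(np.clip(r - g / h, 1e-2, 1e6))
    else:
        r_new = r

    def wll(muv, rv):
        return float((w * _nb_logpmf(t, muv, rv)).sum())

    best = max(((mu_old, r_old), (mu, r), (mu, r_new)), key=lambda p: wll(*p))
    return best


def _fit_logistic_prior(pwm: np.ndarray, pi: np.ndarray, beta0: np.ndarray,
                        n_newton: int = 25) -> np.ndarray:
    """Weighted logistic regression of fractional responses pi on PWM score.

    Newton iterations warm-started at the current beta; the caller keeps the
    old value if the Bernoulli objective did not improve.
    """
    X = np.column_stack([np.ones_like(pwm), pwm])
    beta = beta0.copy()
    for _ in range(n_newton):
        eta = X @ beta
        p = expit(eta)
        grad = X.T @ (pi - p)
        wdiag = np.clip(p * (1 - p), 1e-10, None)
        H = X.T @ (X * wdiag[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -5.0, 5.0)
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
    return beta


def _bernoulli_obj(pwm: np.ndarray, pi: np.ndarray, beta: np.ndarray) -> float:
    eta = beta[0] + beta[1] * pwm
    # sum pi*log sigma(eta) + (1-pi)*log sigma(-eta), numerically safe
    return float((pi * -np.logaddexp(0, -eta) + (1 - pi) * -np.logaddexp(0, eta)).sum())


def _two_means_split(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 2-means on totals; returns (low mask, high mask)."""
    lo, hi = np.quantile(t, [0.25, 0.75])
    if hi <= lo:
        hi = lo + 1.0
    for _ in range(100):
        assign = np.abs(t - lo) <= np.abs(t - hi)
        new_lo = t[assign].mean() if assign.any() else lo
        new_hi = t[~assign].mean() if (~assign).any() else hi
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = new_lo, new_hi
    assign = np.abs(t - lo) <= np.abs(t - hi)
    return assign, ~assign


def _spatial_uniformity_test(counts: np.ndarray) -> float:
    """Pearson chi-square p-value of pooled counts against uniform.

    Guards the per-base profile against locking onto sampling noise: if the
    pooled counts seeding the bound component are statistically
    indistinguishable from the flat background, the learned profile carries
    no footprint information.  Pearson's X^2 is used rather than the
    likelihood-ratio G: at the few-counts-per-cell depths typical of a
    2 kb-by-two-strand window, G is biased upward while X^2 keeps its exact
    null mean of k - 1.
    """
    total = counts.sum()
    k = counts.size
    if total < k:  # too shallow to say anything; treat as uninformative
        return 1.0
    expected = total / k
    x2 = float(((counts - expected) ** 2 / expected).sum())
    return float(chi2.sf(x2, df=k - 1))


def fit_footprint_model(windows: CountWindows,
                        pwm_scores: Optional[np.ndarray] = None,
                        max_iter: int = 200, tol: float = 1e-6,
                        pool_strands: bool = False,
                        ) -> tuple[FootprintModel, np.ndarray]:
    """Fit the mixture by EM and return (model, posterior probabilities).

    The monitored objective is the observed-data log likelihood plus the
    Dirichlet smoothing term on the footprint profile; it is asserted
    non-decreasing at every iteration (within float tolerance).  Components
    are labeled so that mu1 >= mu0 ("bound" draws at least as deep).
    """
    n = windows.n
    if n < 50:
        raise ValueError(f"need >= 50 windows to fit the mixture, got {n}; "
                         "pool libraries or relax selection")
    if pwm_scores is None:
        pwm_scores = windows.pwm_scores()
    pwm_scores = np.asarray(pwm_scores, dtype=float)
    X = _prepare_matrix(windows, pool_strands).astype(float)
    K = X.shape[1]
    T = windows.totals.astype(float)
    alpha = DIRICHLET_SMOOTHING
    flags: list[str] = []

    beta = np.array([np.log(0.1 / 0.9), 0.1])
    if np.ptp(T) == 0 and _all_rows_identical(X):
        model = FootprintModel(lam=np.full((2, K // 2), 1.0 / K),
                               lam0=np.full((2, K // 2), 1.0 / K),
                               mu1=float(T[0]), r1=1e4, mu0=float(T[0]), r0=1e4,
                               beta=beta, flags=["no spatial information"],
                               pool_strands=pool_strands)
        return model, expit(model.prior_logit(pwm_scores))

    # --- deterministic initialization -------------------------------------
    thresh = np.quantile(T, 0.9)
    top = T >= thresh  # permutation-invariant top decile (ties included)
    pooled = np.asarray(X[np.flatnonzero(top)].sum(axis=0)).ravel()
    # Spatial informativeness guard: the deep windows seeding the profile
    # are selected on totals alone, so under a spatially flat library their
    # pooled counts are uniform-multinomial and this G-test is unbiased.
    # Without it the 2W-cell profile locks onto sampling noise and the
    # windows it was seeded from get certified as their own footprint.
    spatial_informative = _spatial_uniformity_test(pooled) <= 0.01
    if not spatial_informative:
        flags.append("no spatial information")
    lam = (pooled + alpha)
    lam /= lam.sum()
    lam0 = np.full(K, 1.0 / K)
    if not spatial_informative:
        lam = lam0.copy()
    low, high = _two_means_split(T)
    mu0, r0 = _weighted_nb_fit(T, low.astype(float), T[low].mean() if low.any() else T.mean(), 10.0)
    mu1, r1 = _weighted_nb_fit(T, high.astype(float), T[high].mean() if high.any() else T.mean() + 1, 10.0)
    if mu1 < mu0:
        (mu0, r0), (mu1, r1) = (mu1, r1), (mu0, r0)

    log_lam = np.log(lam)
    log_lam0 = np.log(lam0)
    obj_prev = -np.inf
    trace: list[float] = []
    converged = False
    pi = np.full(n, 0.1)
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        ll1 = X @ log_lam + _nb_logpmf(T, mu1, r1)
        ll0 = X @ log_lam0 + _nb_logpmf(T, mu0, r0)
        eta = beta[0] + beta[1] * pwm_scores
        log_prior1 = -np.logaddexp(0, -eta)
        log_prior0 = -np.logaddexp(0, eta)
        a = log_prior1 + ll1
        b = log_prior0 + ll0
        loglik = float(np.logaddexp(a, b).sum())
        obj = loglik + alpha * log_lam.sum()
        if not np.isfinite(obj):
            raise FloatingPointError(
                f"non-finite mixture objective at iteration {it}: "
                f"mu=({mu0:.3g},{mu1:.3g}) r=({r0:.3g},{r1:.3g}) beta={beta}"
            )
        if obj < obj_prev - 1e-8 * (1.0 + abs(obj_prev)):
            raise AssertionError(
                f"EM objective decreased at iteration {it}: {obj_prev} -> {obj}"
            )
        trace.append(obj)
        pi = expit(a - b)
        if obj_prev > -np.inf and abs(obj - obj_prev) <= tol * abs(obj_prev):
            converged = True
            obj_prev = obj
            break
        obj_prev = obj
        # M-step
        if spatial_informative:
            wc = np.asarray(X.T @ pi).ravel() if sparse.issparse(X) else X.T @ pi
            lam = wc + alpha
            lam /= lam.sum()
            log_lam = np.log(lam)
        mu1, r1 = _weighted_nb_fit(T, pi, mu1, r1)
        mu0, r0 = _weighted_nb_fit(T, 1.0 - pi, mu0, r0)
        if mu1 < mu0:
            (mu0, r0), (mu1, r1) = (mu1, r1), (mu0, r0)
            pi = 1.0 - pi
            if spatial_informative:
                lam = np.asarray(X.T @ pi).ravel() + alpha
                lam /= lam.sum()
                log_lam = np.log(lam)
            flags.append(f"components relabeled at iteration {it}")
        cand = _fit_logistic_prior(pwm_scores, pi, beta)
        if _bernoulli_obj(pwm_scores, pi, cand) >= _bernoulli_obj(pwm_scores, pi, beta):
            beta = cand

    if not spatial_informative:
        # With a flat profile the only remaining evidence is the totals.
        # Ask whether two NB components are supported at all: compare the
        # fitted mixture to a single NB by BIC (mixture spends 4 extra
        # parameters: second NB pair + the two prior coefficients).  On a
        # spatially and depth-wise homogeneous library the mixture's gain
        # is pure overfit and the model collapses to "no footprint
        # evidence": posteriors equal the logistic prior.
        mu_s, r_s = _weighted_nb_fit(T, np.ones(n), float(T.mean()), 10.0)
        spatial_const = float(T.sum()) * np.log(1.0 / K)
        ll_single = float(_nb_logpmf(T, mu_s, r_s).sum()) + spatial_const
        ll1 = X @ log_lam + _nb_logpmf(T, mu1, r1)
        ll0 = X @ log_lam0 + _nb_logpmf(T, mu0, r0)
        eta = beta[0] + beta[1] * pwm_scores
        ll_mix = float(np.logaddexp(-np.logaddexp(0, -eta) + ll1,
                                    -np.logaddexp(0, eta) + ll0).sum())
        if 2.0 * (ll_mix - ll_single) < 4.0 * np.log(n):
            flags.append("no footprint evidence; posteriors equal the prior")
            mu1 = mu0 = float(mu_s)
            r1 = r0 = float(r_s)
            pi = expit(beta[0] + beta[1] * pwm_scores)

    W = K // 2 if not pool_strands else K
    if pool_strands:
        lam_full = np.vstack([lam, lam]) / 2.0
        lam0_full = np.full((2, K), 1.0 / (2 * K))
    else:
        lam_full = lam.reshape(2, W)
        lam0_full = lam0.reshape(2, W)
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations")
    model = FootprintModel(lam=lam_full, lam0=lam0_full, mu1=float(mu1),
                           r1=float(r1), mu0=float(mu0), r0=float(r0),
                           beta=beta.copy(), loglik_trace=trace,
                           converged=converged, n_iter=it, flags=flags,
                           pool_strands=pool_strands)
    return model, pi


def _all_rows_identical(X) -> bool:
    if X.shape[0] <= 1:
        return True
    d = X - sparse.vstack([X[0]] * X.shape[0]) if sparse.issparse(X) else X - X[0]
    if sparse.issparse(d):
        return d.nnz == 0 or np.abs(d.data).max() == 0
    return not np.any(d)


BOUND, UNBOUND, AMBIGUOUS = "bound", "unbound", "ambiguous"


def classify(posteriors: np.ndarray) -> tuple[np.ndarray, dict[str, int]]:
    """Status labels: bound if pi >= 0.95, unbound if pi <= 0.5, else ambiguous."""
    pi = np.asarray(posteriors, dtype=float)
    if ((pi < 0) | (pi > 1)).any():
        raise ValueError("posteriors must lie in [0, 1]")
    status = np.where(pi >= BOUND_THRESHOLD, BOUND,
                      np.where(pi <= UNBOUND_THRESHOLD, UNBOUND, AMBIGUOUS))
    counts = {s: int((status == s).sum()) for s in (BOUND, UNBOUND, AMBIGUOUS)}
    return status, counts


def posterior_table(windows: CountWindows, posteriors: np.ndarray) -> pd.DataFrame:
    """Tabulate per-site posteriors with coordinates and status labels."""
    status, _ = classify(posteriors)
    rows = []
    for i, inst in enumerate(windows.instances):
        rows.append(dict(chrom=inst.chrom, start=inst.start, end=inst.end,
                         strand=inst.strand, name=inst.name,
                         pwm_score=inst.pwm_score, posterior=posteriors[i],
                         status=status[i]))
    return pd.DataFrame(rows)


def footprint_intervals(windows: CountWindows, posteriors: np.ndarray,
                        ) -> list:
    """2 kb footprint windows (motif +/- flank) of bound sites."""
    from .intervals import GenomicInterval

    status, _ = classify(posteriors)
    out = []
    for i, inst in enumerate(windows.instances):
        if status[i] == BOUND:
            out.append(GenomicInterval(inst.chrom, inst.start - windows.flank,
                                       inst.end + windows.flank,
                                       strand=inst.strand, name=inst.name,
                                       score=float(posteriors[i])))
    return out
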