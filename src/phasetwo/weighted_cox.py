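"""Inverse-probability-weighted Cox regression with design-based variance.

The estimator maximizes the weighted Breslow partial log-likelihood

    l(beta) = sum_{i: event} w_i [ eta_i - log sum_{j: Z_j >= Z_i} w_j e^{eta_j} ]

by Newton-Raphson.  With unit weights this is the ordinary Cox partial
likelihood; with design weights w_i = 1/pi_i it is the weighted-cohort
(Horvitz-Thompson) estimator for two-phase samples.

Variance has two components: the inverse weighted information (the phase-I
part, what a full-cohort fit would give) plus a phase-II part built from
per-subject influence contributions d_i = I^{-1} w_i U_i, where U_i is the
score residual.  For stratified-without-replacement designs the phase-II part
carries finite-population corrections per stratum; risk-set designs (NCC/CM)
use the with-replacement sandwich sum of d_i d_i'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from phasetwo.inclusion_weights import WeightSet
from phasetwo.sampling_designs import Design, PhaseTwoSample

logger = logging.getLogger(__name__)

__all__ = ["FitResult", "fit_weighted_cox", "twophase_variance", "wald_test"]

Z_95 = float(stats.norm.ppf(0.975))

_MAX_ITER = 50
_SCORE_TOL = 1e-9
_LOGLIK_RTOL = 1e-9


@dataclass
class FitResult:
    """Weighted Cox fit: log-hazard-ratio estimates and design-based inference."""

    covariates: list[str]
    coefficients: np.ndarray
    variance: np.ndarray
    se: np.ndarray
    ci95: np.ndarray  # shape (p, 2)
    wald_p: np.ndarray
    converged: bool
    n_used: int
    iterations: int
    message: str = ""
    loglik: float = np.nan
    # internals consumed by twophase_variance
    info_inv: np.ndarray | None = field(default=None, repr=False)
    score_residuals: np.ndarray | None = field(default=None, repr=False)
    used_index: np.ndarray | None = field(default=None, repr=False)
    used_weights: np.ndarray | None = field(default=None, repr=False)

    def set_variance(self, variance: np.ndarray) -> "FitResult":
        """Replace the variance matrix and refresh se / CI / Wald p-values."""
        self.variance = variance
        self.se = np.sqrt(np.diag(variance))
        self.ci95 = np.column_stack(
            [self.coefficients - Z_95 * self.se, self.coefficients + Z_95 * self.se]
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.coefficients / self.se
        self.wald_p = 2.0 * stats.norm.sf(np.abs(z))
        return self

    def __getitem__(self, covariate: str) -> dict:
        k = self.covariates.index(covariate)
        return {
            "coef": float(self.coefficients[k]),
            "se": float(self.se[k]),
            "ci95": (float(self.ci95[k, 0]), float(self.ci95[k, 1])),
            "p": float(self.wald_p[k]),
        }

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "estimate": self.coefficients,
                "se": self.se,
                "ci_low": self.ci95[:, 0],
                "ci_high": self.ci95[:, 1],
                "p": self.wald_p,
                "n_used": self.n_used,
                "converged": self.converged,
            }
        )


def _as_weight_array(weights, n: int) -> np.ndarray:
    if weights is None:
        return np.ones(n)
    if isinstance(weights, WeightSet):
        return np.asarray(weights.weight, dtype=float)
    return np.asarray(weights, dtype=float)


def _breslow_core(times, events, X, w, beta):
    """Log-likelihood, score and information of the weighted Breslow partial
    likelihood, plus the per-subject pieces needed for residuals.

    Arrays must be pre-sorted ascending in time.
    """
    n, p = X.shape
    eta = X @ beta
    r = w * np.exp(np.clip(eta, -500, 500))
    # suffix sums over the risk set {j : Z_j >= t}; ties share the risk set,
    # so each position maps to the first index with its time
    first = np.searchsorted(times, times, side="left")
    s0_suf = np.cumsum(r[::-1])[::-1]
    s0 = s0_suf[first]
    rx = r[:, None] * X
    s1 = np.cumsum(rx[::-1], axis=0)[::-1][first]
    xbar = s1 / s0[:, None]

    ev = events.astype(bool)
    loglik = float(np.sum(w[ev] * (eta[ev] - np.log(s0[ev]))))
    score = (w[ev, None] * (X[ev] - xbar[ev])).sum(axis=0)

    info = np.zeros((p, p))
    for a in range(p):
        for b in range(a, p):
            s2ab = np.cumsum((rx[:, a] * X[:, b])[::-1])[::-1][first]
            val = np.sum(w[ev] * (s2ab[ev] / s0[ev] - xbar[ev, a] * xbar[ev, b]))
            info[a, b] = info[b, a] = val
    return loglik, score, info, s0, xbar, r


def _score_residuals(times, events, X, w, s0, xbar, r):
    """Martingale-form score residuals U_i at the fitted coefficients:
    U_i = D_i (x_i - xbar(Z_i)) - sum_{events t_e <= Z_i} w_e r_i (x_i - xbar(t_e)) / S0(t_e)
    with r_i = exp(eta_i); sum_i w_i U_i equals the (zero) score."""
    ev = events.astype(bool)
    ev_times = times[ev]
    inc = w[ev] / s0[ev]
    cum_a = np.cumsum(inc)
    cum_b = np.cumsum(inc[:, None] * xbar[ev], axis=0)
    counts = np.searchsorted(ev_times, times, side="right")
    a_at = np.where(counts > 0, cum_a[np.maximum(counts - 1, 0)], 0.0)
    b_at = np.where(
        (counts > 0)[:, None], cum_b[np.maximum(counts - 1, 0)], 0.0
    )
    # r = w * exp(eta); the residual needs exp(eta) alone
    with np.errstate(divide="ignore", invalid="ignore"):
        ee = np.where(w > 0, r / w, 0.0)
    U = -ee[:, None] * (X * a_at[:, None] - b_at)
    U[ev] += X[ev] - xbar[ev]
    return U


def fit_weighted_cox(
    data: pd.DataFrame,
    weights=None,
    covariates: list[str] | tuple[str, ...] = ("x_bm", "x_conf"),
    time_col: str = "obs_time",
    event_col: str = "event",
) -> FitResult:
    """Fit the weighted Cox model on subjects with positive weight.

    ``weights`` may be a :class:`WeightSet`, an array aligned with ``data``,
    or None (unit weights, ordinary Cox).  Breslow tie handling throughout,
    which makes an integer-weighted fit identical to a fit on row-duplicated
    data.  Non-convergence or a flat likelihood direction is flagged on the
    result rather than raised.
    """
    covariates = list(covariates)
    w_all = _as_weight_array(weights, len(data))
    used = np.flatnonzero(w_all > 0)
    if len(used) == 0:
        raise ValueError("no subjects with positive weight")
    sub = data.iloc[used]
    times = sub[time_col].to_numpy(dtype=float)
    events = sub[event_col].to_numpy(dtype=int)
    if events.sum() == 0:
        raise ValueError("no events among weighted subjects")
    X = sub[covariates].to_numpy(dtype=float)
    w = w_all[used]
    p = X.shape[1]

    order = np.argsort(times, kind="stable")
    times, events, X, w = times[order], events[order], X[order], w[order]
    used = used[order]

    beta = np.zeros(p)
    converged = False
    message = ""
    loglik, score, info, s0, xbar, r = _breslow_core(times, events, X, w, beta)
    it = 0
    for it in range(1, _MAX_ITER + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            message = "singular information matrix (no contrast in a covariate?)"
            break
        new_beta = beta + step
        new = _breslow_core(times, events, X, w, new_beta)
        # step-halving if the likelihood did not improve
        halvings = 0
        while new[0] < loglik - 1e-12 and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new = _breslow_core(times, events, X, w, new_beta)
            halvings += 1
        rel_change = abs(new[0] - loglik) / max(abs(loglik), 1.0)
        beta = new_beta
        loglik, score, info, s0, xbar, r = new
        if np.max(np.abs(score)) < _SCORE_TOL or rel_change < _LOGLIK_RTOL:
            converged = True
            break
    if converged and np.max(np.abs(beta)) > 30:
        converged = False
        message = "monotone likelihood (separation): estimate diverges"

    try:
        info_inv = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        info_inv = np.full((p, p), np.nan)
        converged = False
        message = message or "singular information matrix at solution"

    resid = _score_residuals(times, events, X, w, s0, xbar, r)
    fit = FitResult(
        covariates=covariates,
        coefficients=beta,
        variance=info_inv,
        se=np.full(p, np.nan),
        ci95=np.full((p, 2), np.nan),
        wald_p=np.full(p, np.nan),
        converged=converged,
        n_used=len(used),
        iterations=it,
        message=message,
        loglik=loglik,
        info_inv=info_inv,
        score_residuals=resid,
        used_index=used,
        used_weights=w,
    )
    if np.isfinite(info_inv).all():
        fit.set_variance(info_inv)
    return fit


def twophase_variance(
    fit: FitResult,
    sample: PhaseTwoSample | None,
    weights: WeightSet | None = None,
) -> np.ndarray:
    """Design-based variance: inverse weighted information plus a phase-II
    contribution from influence terms d_i = I^{-1} w_i U_i.

    Stratified designs get per-stratum finite-population-corrected terms
    sum_h (1 - f_h) n_h/(n_h - 1) sum_{i in h} (d_i - dbar_h)(d_i - dbar_h)';
    post-stratified weights use the post-strata as variance strata.  Risk-set
    designs (NCC/CM) use the independent-sampling (Poisson) approximation
    sum_i (1 - pi_i) d_i d_i', which treats inclusions as independent
    Bernoulli(pi_i): under that model Var(sum_i xi_i w_i U_i) =
    sum_i (1 - pi_i) (w_i U_i)(w_i U_i)', estimated on the realized sample.
    With every pi = 1 the phase-II part vanishes and the model-based variance
    is returned.
    """
    if fit.info_inv is None or fit.score_residuals is None:
        raise ValueError("fit does not carry influence internals")
    p = len(fit.covariates)
    d = (fit.used_weights[:, None] * fit.score_residuals) @ fit.info_inv
    if sample is None:
        return fit.info_inv.copy()

    design = sample.design_meta.get("design")
    if design in (Design.NCC, Design.CM):
        if weights is None:
            raise ValueError("risk-set designs need the WeightSet for the variance")
        pi_used = np.asarray(weights.inclusion_prob, dtype=float)[fit.used_index]
        v2 = (np.clip(1.0 - pi_used, 0.0, 1.0)[:, None] * d).T @ d
        return fit.info_inv + v2

    if weights is not None and weights.post_strata is not None:
        strata_all = np.asarray(weights.post_strata, dtype=object)
    else:
        strata_all = np.asarray(sample.stratum, dtype=object)
    strata_used = strata_all[fit.used_index]
    v2 = np.zeros((p, p))
    for lab in sorted(set(strata_used)):
        in_h = strata_used == lab
        n_h = int(in_h.sum())
        big_n_h = int((strata_all == lab).sum())
        if n_h < 2:
            logger.warning(
                "variance stratum %r has a single subject; its phase-II term is dropped",
                lab,
            )
            continue
        f_h = n_h / big_n_h
        dc = d[in_h] - d[in_h].mean(axis=0)
        v2 += (1.0 - f_h) * (n_h / (n_h - 1.0)) * (dc.T @ dc)
    return fit.info_inv + v2


def wald_test(fit: FitResult, covariate: str = "x_bm", alpha: float = 0.05):
    """Two-sided Wald test of beta = 0 with the fit's current (design-based)
    standard error.  Returns (reject, p); (None, nan) when not converged."""
    if not fit.converged:
        return None, float("nan")
    k = fit.covariates.index(covariate)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = fit.coefficients[k] / fit.se[k]
    pval = float(2.0 * stats.norm.sf(abs(z)))
    return bool(pval < alpha), pval
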