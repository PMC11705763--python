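"""Comparator methods for single-sample expression state calling.

Three baselines are provided for like-for-like benchmarking against the
Bayesian mixture method:

* fixed TPM thresholds (e.g. TPM < 1, TPM < 2);
* zFPKM-style z-scoring of log2 abundance against the active-expression
  peak, with the published activity threshold of -3;
* an exponential (inactive) + negative binomial (active) mixture ("EnB")
  whose state boundary is the abundance where the active-component
  posterior crosses a given probability (default 1%).

All three return a :class:`~statecall.mixture.StateCallSet` over the full
gene universe of the input vector, with zero-abundance genes always
called not expressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import gammaln
from scipy.stats import gaussian_kde

from .errors import (
    DegenerateInputError,
    NonConvergenceError,
    ParameterError,
)
from .mixture import ExpressionVector, StateCallSet

__all__ = [
    "fixed_threshold_states",
    "zfpkm_states",
    "enb_states",
    "EnBFit",
]

_MIN_POSITIVE = 500


def fixed_threshold_states(expr: ExpressionVector, cutoff: float) -> StateCallSet:
    """Hard-threshold baseline: state 0 iff TPM < ``cutoff``.

    The posterior column is the degenerate 0/1 indicator.
    """
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    state = (expr.values >= cutoff).astype(np.int8)
    return StateCallSet(
        sample_id=expr.sample_id,
        gene_ids=expr.gene_ids,
        tpm=expr.values,
        posterior=state.astype(float),
        state=state,
    )


def zfpkm_states(
    expr: ExpressionVector, threshold: float = -3.0, grid_size: int = 2048
) -> tuple[StateCallSet, float, float]:
    """zFPKM-style activity calling on log2 abundance.

    The active-expression peak location ``mu`` is the mode of a Gaussian
    kernel density over log2 of the positive abundances (Scott's rule
    bandwidth); the scale ``sigma`` is the RMS deviation of the values on
    the right flank of the mode, under the assumption that the active
    peak is symmetric. A gene is called expressed iff

        z = (log2(TPM) - mu) / sigma >= threshold

    with z = -inf (state 0) at TPM == 0. Returns
    ``(calls, mu, sigma)``.
    """
    pos = expr.values > 0
    if int(pos.sum()) < _MIN_POSITIVE:
        raise DegenerateInputError(
            f"need >= {_MIN_POSITIVE} positive abundances for the density "
            f"fit, got {int(pos.sum())}"
        )
    y = np.log2(expr.values[pos])
    if float(np.std(y)) <= 0:
        raise DegenerateInputError("flat log2 abundance density; no mode")
    try:
        # doubled Scott's-rule bandwidth: the peak of a symmetric mode is
        # invariant under Gaussian smoothing, while the wider kernel
        # roughly halves the sampling noise of the mode estimate
        kde = gaussian_kde(y, bw_method=lambda k: 2.0 * k.neff ** (-1 / 5))
    except np.linalg.LinAlgError as exc:  # singular covariance
        raise DegenerateInputError("degenerate density estimate") from exc
    grid = np.linspace(y.min(), y.max(), grid_size)
    dens = kde(grid)
    mu = float(grid[np.argmax(dens)])
    right = y[y > mu]
    if right.size == 0:
        raise DegenerateInputError("no observations above the density mode")
    sigma = float(np.sqrt(np.mean((right - mu) ** 2)))
    if sigma <= 0:
        raise DegenerateInputError("zero scale on the active peak")
    z = np.full(expr.values.shape, -np.inf)
    z[pos] = (y - mu) / sigma
    state = (z >= threshold).astype(np.int8)
    calls = StateCallSet(
        sample_id=expr.sample_id,
        gene_ids=expr.gene_ids,
        tpm=expr.values,
        posterior=state.astype(float),
        state=state,
    )
    return calls, mu, sigma


@dataclass(frozen=True)
class EnBFit:
    """Fitted exponential + negative binomial mixture.

    ``rate`` parameterizes the exponential (inactive) component on raw
    TPM; the negative binomial (active) component has mean ``nb_mean``
    and size ``nb_size`` (variance = mean + mean^2 / size) and is
    evaluated on rounded abundances. ``pi_active`` is the active-class
    mixing proportion.
    """

    pi_active: float
    rate: float
    nb_size: float
    nb_mean: float
    n_iter: int
    log_likelihood: float

    @property
    def nb_p(self) -> float:
        return self.nb_size / (self.nb_size + self.nb_mean)


def _nb_logpmf_continuous(k, size, mean):
    """Negative binomial log pmf with the gamma-function continuous
    extension in k (matches scipy.stats.nbinom at integers)."""
    k = np.asarray(k, dtype=float)
    p = size / (size + mean)
    return (
        gammaln(k + size) - gammaln(size) - gammaln(k + 1.0)
        + size * np.log(p) + k * np.log1p(-p)
    )


def _enb_loglik_terms(x, k, pi_active, rate, size, mean):
    lp_in = np.log1p(-pi_active) + np.log(rate) - rate * x
    lp_act = np.log(pi_active) + _nb_logpmf_continuous(k, size, mean)
    return lp_in, lp_act


def _fit_nb_weighted(k, w):
    """Weighted NB maximum likelihood: closed-form mean, 1-D search on
    log(size)."""
    wsum = w.sum()
    mean = float((w * k).sum() / wsum)
    mean = max(mean, 1e-6)

    def neg_ll(log_size):
        size = np.exp(log_size)
        return -float((w * _nb_logpmf_continuous(k, size, mean)).sum())

    res = minimize_scalar(neg_ll, bounds=(-6.0, 12.0), method="bounded",
                          options={"xatol": 1e-5})
    return float(np.exp(res.x)), mean


def enb_states(
    expr: ExpressionVector,
    prob_cutoff: float = 0.01,
    tol: float = 1e-7,
    max_iter: int = 300,
) -> tuple[StateCallSet, float, EnBFit]:
    """EnB baseline: exponential (inactive) + negative binomial (active)
    mixture over TPM abundances.

    The mixture is fitted by EM on the positive abundances; the
    exponential component is evaluated on raw values while the negative
    binomial, a count distribution, is evaluated on values rounded to the
    nearest integer (an explicit approximation for continuous TPM input).
    The state boundary is the abundance at which the active-component
    posterior crosses ``1 - prob_cutoff``; genes at or above the boundary
    are called expressed. Returns ``(calls, threshold_tpm, fit)``.
    """
    if not 0 < prob_cutoff < 1:
        raise ParameterError("prob_cutoff must be in (0, 1)")
    pos = expr.values > 0
    if int(pos.sum()) < _MIN_POSITIVE:
        raise DegenerateInputError(
            f"need >= {_MIN_POSITIVE} positive abundances, got {int(pos.sum())}"
        )
    x = expr.values[pos]
    k = np.round(x)

    # initial split at the 40th percentile of positive abundance
    split = np.quantile(x, 0.4)
    act0 = x > split
    if act0.sum() < 10 or (~act0).sum() < 10:
        raise DegenerateInputError("cannot form an initial two-way split")
    pi_active = float(np.mean(act0))
    rate = 1.0 / max(float(np.mean(x[~act0])), 1e-6)
    size, mean = _fit_nb_weighted(k[act0], np.ones(int(act0.sum())))

    ll_prev = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        lp_in, lp_act = _enb_loglik_terms(x, k, pi_active, rate, size, mean)
        lse = np.logaddexp(lp_in, lp_act)
        ll = float(lse.sum())
        w_act = np.exp(lp_act - lse)
        w_in = 1.0 - w_act

        pi_active = float(np.mean(w_act))
        if not 1e-4 < pi_active < 1 - 1e-4:
            raise NonConvergenceError(
                "EnB mixing proportion collapsed",
                diagnostics={"pi_active": pi_active, "iteration": n_iter},
            )
        rate = float(w_in.sum() / max((w_in * x).sum(), 1e-12))
        size, mean = _fit_nb_weighted(k, w_act)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1e-300):
            break
        ll_prev = ll
    fit = EnBFit(
        pi_active=pi_active,
        rate=rate,
        nb_size=size,
        nb_mean=mean,
        n_iter=n_iter,
        log_likelihood=ll,
    )
    threshold = enb_threshold(fit, prob_cutoff, x_max=float(x.max()))
    state = (expr.values >= threshold).astype(np.int8)
    calls = StateCallSet(
        sample_id=expr.sample_id,
        gene_ids=expr.gene_ids,
        tpm=expr.values,
        posterior=state.astype(float),
        state=state,
    )
    return calls, threshold, fit


def enb_posterior_active(x, fit: EnBFit):
    """P(active | x) under an EnB fit, using the continuous NB extension."""
    x = np.asarray(x, dtype=float)
    lp_in, lp_act = _enb_loglik_terms(
        x, x, fit.pi_active, fit.rate, fit.nb_size, fit.nb_mean
    )
    return np.exp(lp_act - np.logaddexp(lp_in, lp_act))


def enb_threshold(fit: EnBFit, prob_cutoff: float, x_max: float = 1e6) -> float:
    """Abundance where the active-component posterior crosses
    ``1 - prob_cutoff`` (larger ``prob_cutoff`` gives a smaller, more
    permissive threshold)."""
    target = 1.0 - prob_cutoff

    def g(x):
        return float(enb_posterior_active(x, fit)) - target

    lo, hi = 1e-9, x_max
    if g(lo) >= 0:
        return lo
    if g(hi) < 0:
        raise NonConvergenceError(
            "active posterior never reaches the cutoff",
            diagnostics={"posterior_at_max": g(hi) + target},
        )
    # the posterior is monotone increasing in x for these two families
    return float(brentq(g, lo, hi, xtol=1e-9, rtol=1e-12))
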