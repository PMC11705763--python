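"""Single-sample Bayesian gene expression state inference.

Within one RNA-seq sample, log2 abundances of genes are modelled as a
two-component normal mixture (equivalently, TPM follows a two-component
lognormal mixture): a low-abundance "not expressed" mode produced by
transcriptional noise and a high-abundance "expressed" mode. The mixture

    f(x) = pi_ne * f_ne(x) + pi_e * f_e(x)

is fitted per sample by expectation-maximization on the strictly positive
abundances; housekeeping genes, which are constitutively expressed, anchor
the expressed component's initial location and scale. The posterior
probability that a gene is expressed given its abundance x is

    P(expressed | x) = 0                                        if x == 0
                     = pi_e f_e(x) / (pi_ne f_ne(x) + pi_e f_e(x))  else

and the binary expression state is 1 iff the posterior is >= 0.5.

Because both component densities are lognormal, the Jacobian of the
log transform cancels in the posterior ratio, so all computations use
normal densities on the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from scipy.stats import norm

from .errors import (
    DegenerateInputError,
    DomainError,
    InitializationError,
    InvalidFitError,
    NonConvergenceError,
    ShapeError,
)

__all__ = [
    "ExpressionVector",
    "MixtureFit",
    "StateCallSet",
    "EMConfig",
    "fit_mixture",
    "posterior_expressed",
    "call_states",
]

_SIGMA_FLOOR = 1e-3


@dataclass(frozen=True)
class ExpressionVector:
    """TPM abundances for one sample.

    Parameters
    ----------
    gene_ids
        Ordered, unique gene identifiers.
    values
        Non-negative TPM abundance per gene, aligned with ``gene_ids``.
    sample_id
        Sample identifier.
    """

    gene_ids: np.ndarray
    values: np.ndarray
    sample_id: str = ""

    def __post_init__(self):
        gene_ids = np.asarray(self.gene_ids, dtype=object)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "values", values)
        if gene_ids.shape[0] != values.shape[0]:
            raise ShapeError(
                f"gene_ids ({gene_ids.shape[0]}) and values "
                f"({values.shape[0]}) differ in length"
            )
        if len(set(gene_ids)) != len(gene_ids):
            raise ShapeError("gene_ids must be unique")
        if not np.all(np.isfinite(values)):
            raise DomainError("abundances must be finite")
        if np.any(values < 0):
            bad = gene_ids[values < 0][:5]
            raise DomainError(f"negative abundances for genes {list(bad)}")

    @classmethod
    def from_series(cls, series: pd.Series) -> "ExpressionVector":
        """Build from a pandas Series indexed by gene id."""
        return cls(
            gene_ids=series.index.to_numpy(dtype=object),
            values=series.to_numpy(dtype=float),
            sample_id=str(series.name) if series.name is not None else "",
        )

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class MixtureFit:
    """Fitted two-component lognormal mixture for one sample.

    Locations (``mu``) and scales (``sigma``) are on the log2-TPM scale.
    The component with the higher location is, by convention, the
    expressed component, so ``mu_e > mu_ne`` always holds.
    """

    pi_ne: float
    pi_e: float
    mu_ne: float
    sigma_ne: float
    mu_e: float
    sigma_e: float
    n_iter: int = 0
    converged: bool = True
    log_likelihood: float = np.nan
    n_fitted: int = 0
    loglik_path: np.ndarray = field(
        default_factory=lambda: np.array([]), repr=False, compare=False
    )

    def validate(self) -> "MixtureFit":
        pars = (self.pi_ne, self.pi_e, self.mu_ne, self.sigma_ne,
                self.mu_e, self.sigma_e)
        if not all(np.isfinite(pars)):
            raise InvalidFitError(f"non-finite mixture parameters: {pars}")
        if not (0 < self.pi_ne < 1 and 0 < self.pi_e < 1):
            raise InvalidFitError("mixing proportions must lie in (0, 1)")
        if abs(self.pi_ne + self.pi_e - 1.0) > 1e-12:
            raise InvalidFitError("mixing proportions must sum to 1")
        if self.sigma_ne <= 0 or self.sigma_e <= 0:
            raise InvalidFitError("component scales must be positive")
        if not self.mu_e > self.mu_ne:
            raise InvalidFitError(
                "expressed component must have the higher location "
                f"(mu_e={self.mu_e}, mu_ne={self.mu_ne})"
            )
        return self


@dataclass(frozen=True)
class StateCallSet:
    """Per-gene posterior probabilities and binary states for one sample."""

    sample_id: str
    gene_ids: np.ndarray
    tpm: np.ndarray
    posterior: np.ndarray
    state: np.ndarray
    fit: MixtureFit | None = None

    def __post_init__(self):
        n = len(self.gene_ids)
        for name in ("tpm", "posterior", "state"):
            if len(getattr(self, name)) != n:
                raise ShapeError(f"{name} length differs from gene count")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: gene_id, sample_id, tpm, posterior, state."""
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "sample_id": self.sample_id,
                "tpm": self.tpm,
                "posterior": self.posterior,
                "state": self.state,
            }
        )

    @property
    def expressed_fraction(self) -> float:
        return float(np.mean(self.state))

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class EMConfig:
    """EM settings for :func:`fit_mixture`.

    ``tol`` is the relative log-likelihood change below which the fit is
    declared converged; ``n_restarts`` jittered re-initializations are
    attempted when a component collapses (vanishing weight, vanishing
    scale, or the two locations merging).
    """

    tol: float = 1e-8
    max_iter: int = 1000
    n_restarts: int = 3
    seed: int = 0
    min_positive: int = 500
    min_housekeeping: int = 10
    min_weight: float = 1e-3
    min_separation: float = 1e-2
    jitter_sd: float = 0.5


class _EMCollapse(Exception):
    def __init__(self, diagnostics: dict):
        self.diagnostics = diagnostics


def _log_density_matrix(y, pi, mu, sigma):
    # rows: observations, cols: components (ne, e)
    return np.log(pi)[None, :] + norm.logpdf(
        y[:, None], loc=mu[None, :], scale=sigma[None, :]
    )


def _run_em(y: np.ndarray, init: tuple, cfg: EMConfig):
    pi = np.array([1.0 - init[0], init[0]], dtype=float)  # (ne, e)
    mu = np.array([init[1], init[3]], dtype=float)
    sigma = np.array([init[2], init[4]], dtype=float)
    n = y.size
    ll_path = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        logdens = _log_density_matrix(y, pi, mu, sigma)
        lse = logsumexp(logdens, axis=1)
        ll = float(np.sum(lse))
        resp = np.exp(logdens - lse[:, None])
        ll_path.append(ll)

        w = resp.sum(axis=0)
        pi_new = w / n
        if np.min(pi_new) < cfg.min_weight:
            raise _EMCollapse(
                {"reason": "component weight collapse", "pi": pi_new.tolist(),
                 "iteration": it}
            )
        mu_new = (resp * y[:, None]).sum(axis=0) / w
        var_new = (resp * (y[:, None] - mu_new[None, :]) ** 2).sum(axis=0) / w
        sigma_new = np.sqrt(np.maximum(var_new, 0.0))
        if np.min(sigma_new) < _SIGMA_FLOOR:
            raise _EMCollapse(
                {"reason": "scale collapse", "sigma": sigma_new.tolist(),
                 "iteration": it}
            )
        if abs(mu_new[1] - mu_new[0]) < cfg.min_separation:
            raise _EMCollapse(
                {"reason": "location merge", "mu": mu_new.tolist(),
                 "iteration": it}
            )
        pi, mu, sigma = pi_new, mu_new, sigma_new
        if len(ll_path) >= 2:
            prev = ll_path[-2]
            if abs(ll - prev) <= cfg.tol * (abs(prev) + 1e-300):
                converged = True
                break
    # final log likelihood under the updated parameters
    final_ll = float(
        np.sum(logsumexp(_log_density_matrix(y, pi, mu, sigma), axis=1))
    )
    ll_path.append(final_ll)
    return pi, mu, sigma, it, converged, np.asarray(ll_path)


def _initial_values(y: np.ndarray, hk_mask: np.ndarray) -> tuple:
    """Housekeeping-anchored initial values.

    mu_e, sigma_e come from the housekeeping genes' log2 abundances;
    mu_ne, sigma_ne from the lowest quartile of the remaining positive
    genes; pi_e from the fraction of genes above the midpoint of the two
    initial locations.
    """
    y_hk = y[hk_mask]
    mu_e0 = float(np.mean(y_hk))
    sigma_e0 = max(float(np.std(y_hk, ddof=1)), _SIGMA_FLOOR)
    y_rest = y[~hk_mask]
    if y_rest.size < 4:
        y_rest = y
    q25 = np.quantile(y_rest, 0.25)
    y_low = y_rest[y_rest <= q25]
    mu_ne0 = float(np.mean(y_low))
    sigma_ne0 = max(float(np.std(y_low, ddof=1)), 10 * _SIGMA_FLOOR)
    if mu_e0 - mu_ne0 < 0.5:
        mu_ne0 = mu_e0 - 0.5
    mid = 0.5 * (mu_ne0 + mu_e0)
    pi_e0 = float(np.clip(np.mean(y > mid), 0.05, 0.95))
    return pi_e0, mu_ne0, sigma_ne0, mu_e0, sigma_e0


def fit_mixture(
    expr: ExpressionVector,
    housekeeping,
    config: EMConfig | None = None,
) -> MixtureFit:
    """Fit the per-sample two-component lognormal mixture by EM.

    Only strictly positive abundances enter the fit (zeros carry no
    information about the mixture on the log scale and receive posterior 0
    by definition). The observed-data log likelihood is non-decreasing
    across iterations; on component collapse the fit restarts with
    jittered initial values before raising
    :class:`~statecall.errors.NonConvergenceError`.

    Parameters
    ----------
    expr
        Abundances for one sample; needs >= ``config.min_positive``
        positive genes.
    housekeeping
        Iterable of gene ids of constitutively expressed genes; at least
        ``config.min_housekeeping`` must be present with positive
        abundance.
    config
        EM settings; defaults are suitable for genome-wide TPM vectors.
    """
    cfg = config or EMConfig()
    hk_set = set(housekeeping) if housekeeping is not None else set()
    if not hk_set:
        raise InitializationError(
            "housekeeping gene list is empty; supply a list of "
            "constitutively expressed gene ids"
        )
    pos = expr.values > 0
    n_pos = int(pos.sum())
    if n_pos < cfg.min_positive:
        raise DegenerateInputError(
            f"sample {expr.sample_id!r} has only {n_pos} genes with "
            f"positive abundance (< {cfg.min_positive}); mixture not "
            "identifiable"
        )
    y = np.log2(expr.values[pos])
    if float(np.std(y)) < _SIGMA_FLOOR:
        raise DegenerateInputError(
            "positive abundances have (near-)zero variance; two-component "
            "mixture is unidentifiable"
        )
    hk_mask = np.fromiter(
        (g in hk_set for g in expr.gene_ids[pos]), dtype=bool, count=n_pos
    )
    n_hk = int(hk_mask.sum())
    if n_hk < cfg.min_housekeeping:
        raise InitializationError(
            f"only {n_hk} housekeeping genes detected with positive "
            f"abundance in sample {expr.sample_id!r} "
            f"(need >= {cfg.min_housekeeping}); check the housekeeping list"
        )

    init = _initial_values(y, hk_mask)
    rng = np.random.default_rng(cfg.seed)
    last_diag: dict = {}
    for attempt in range(cfg.n_restarts + 1):
        if attempt > 0:
            pi_e0, mu_ne0, s_ne0, mu_e0, s_e0 = init
            init_try = (
                float(np.clip(pi_e0 + rng.normal(0, 0.05), 0.05, 0.95)),
                mu_ne0 + rng.normal(0, cfg.jitter_sd),
                s_ne0 * float(np.exp(rng.normal(0, 0.2))),
                mu_e0 + rng.normal(0, cfg.jitter_sd),
                s_e0 * float(np.exp(rng.normal(0, 0.2))),
            )
        else:
            init_try = init
        try:
            pi, mu, sigma, n_iter, converged, ll_path = _run_em(
                y, init_try, cfg
            )
        except _EMCollapse as exc:
            last_diag = dict(exc.diagnostics, attempt=attempt)
            continue
        # enforce the label convention: higher location is "expressed"
        order = np.argsort(mu)
        pi, mu, sigma = pi[order], mu[order], sigma[order]
        fit = MixtureFit(
            pi_ne=float(pi[0]),
            pi_e=float(pi[1]),
            mu_ne=float(mu[0]),
            sigma_ne=float(sigma[0]),
            mu_e=float(mu[1]),
            sigma_e=float(sigma[1]),
            n_iter=n_iter,
            converged=converged,
            log_likelihood=float(ll_path[-1]),
            n_fitted=n_pos,
            loglik_path=ll_path,
        )
        return fit.validate()
    raise NonConvergenceError(
        f"EM collapsed in all {cfg.n_restarts + 1} attempts for sample "
        f"{expr.sample_id!r}",
        diagnostics=last_diag,
    )


def posterior_expressed(x, fit: MixtureFit):
    """Posterior probability P(expressed | x) under a fitted mixture.

    Defined piecewise: exactly 0 at x == 0, otherwise the Bayes ratio of
    the two lognormal component densities. Accepts scalars or arrays.
    """
    fit.validate()
    x_arr = np.asarray(x, dtype=float)
    scalar = x_arr.ndim == 0
    x_arr = np.atleast_1d(x_arr)
    if np.any(x_arr < 0):
        raise DomainError("abundance must be non-negative")
    out = np.zeros_like(x_arr)
    pos = x_arr > 0
    if np.any(pos):
        y = np.log2(x_arr[pos])
        lp_e = np.log(fit.pi_e) + norm.logpdf(y, fit.mu_e, fit.sigma_e)
        lp_ne = np.log(fit.pi_ne) + norm.logpdf(y, fit.mu_ne, fit.sigma_ne)
        # logistic of the log odds; exact 0.5 at equal log densities
        out[pos] = expit(lp_e - lp_ne)
    return float(out[0]) if scalar else out


def call_states(expr: ExpressionVector, fit: MixtureFit) -> StateCallSet:
    """Binarize one sample's abundances with the 0.5 posterior cutoff.

    A gene is called expressed (state 1) iff its posterior is >= 0.5;
    zero-abundance genes always have posterior 0 and state 0.
    """
    posterior = posterior_expressed(expr.values, fit)
    state = (posterior >= 0.5).astype(np.int8)
    return StateCallSet(
        sample_id=expr.sample_id,
        gene_ids=expr.gene_ids,
        tpm=expr.values,
        posterior=posterior,
        state=state,
        fit=fit,
    )


def fit_and_call(
    expr: ExpressionVector, housekeeping, config: EMConfig | None = None
) -> StateCallSet:
    """Convenience: :func:`fit_mixture` then :func:`call_states`."""
    return call_states(expr, fit_mixture(expr, housekeeping, config))


def relabel(fit: MixtureFit) -> MixtureFit:
    """Return the fit with component labels swapped, then re-apply the
    mu_e > mu_ne convention (a no-op on any valid fit; used to verify
    relabeling invariance)."""
    swapped = replace(
        fit,
        pi_ne=fit.pi_e, pi_e=fit.pi_ne,
        mu_ne=fit.mu_e, mu_e=fit.mu_ne,
        sigma_ne=fit.sigma_e, sigma_e=fit.sigma_ne,
    )
    if swapped.mu_e > swapped.mu_ne:
        return swapped
    return fit
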