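"""Recursive Bayesian decoding of PERCLOS from selected neural features.

The filter discretizes PERCLOS on a uniform grid inside (0, 1) and runs the
classic predict/update recursion:

1. Chapman-Kolmogorov prediction: propagate the previous posterior through
   the state-transition kernel.
2. Likelihood: under the encoder models, the selected features are
   conditionally independent given PERCLOS, each Gaussian with mean linear
   in PERCLOS; the joint likelihood is the product over features, evaluated
   in log-space for stability.
3. Bayes update: multiply prediction by likelihood and renormalize.

The transition kernel follows from the tanh-squashed recursion by change of
variables: the conditional density of x' given x is the Gaussian density of
atanh(2x' - 1) around a*x + b (variance sigma_eps2) times the Jacobian
2 / (1 - (2x' - 1)^2).

Point estimate is the posterior mean; the credible interval is central 95%
by default, read off a piecewise-linear CDF that treats each grid point's
mass as spread uniformly over its cell (this keeps interval coverage honest
even when the posterior is only a few grid cells wide).  A highest-density
construction is available via ``interval="hpd"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as spstats

from .exceptions import DomainError
from .features import FeatureMatrix
from .observation import ObservationEntry, _apply_transform
from .state import PerclosSeries, StateModel, squash, unsquash

__all__ = [
    "Posterior",
    "make_grid",
    "transition_kernel",
    "likelihood",
    "bayes_filter",
    "predict_ahead",
    "evaluate",
    "PERCLOS_BINS",
]

logger = logging.getLogger(__name__)

#: Stratification intervals for per-level evaluation metrics.
PERCLOS_BINS = ((0.0, 0.25), (0.25, 0.5), (0.5, 0.75), (0.75, 1.0 + 1e-12))

_GRID_EPS = 1e-4


@dataclass
class Posterior:
    """Filtered posterior over the PERCLOS grid, one row per time step."""

    grid: np.ndarray
    pmf: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.pmf = np.atleast_2d(np.asarray(self.pmf, dtype=float))
        for name in ("mean", "ci_low", "ci_high"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not np.allclose(self.pmf.sum(axis=1), 1.0, atol=1e-9):
            raise DomainError("every posterior row must sum to 1")

    def __len__(self) -> int:
        return self.pmf.shape[0]


def make_grid(size: int = 201, eps: float = _GRID_EPS) -> np.ndarray:
    """Uniform grid of ``size`` points on [eps, 1 - eps]."""
    if size < 2:
        raise DomainError("grid needs at least 2 points")
    return np.linspace(eps, 1.0 - eps, size)


# ---------------------------------------------------------------------------
# Transition kernel
# ---------------------------------------------------------------------------

def transition_kernel(model: StateModel, grid: np.ndarray) -> np.ndarray:
    """Row-stochastic matrix K[g, j] = p(x_i = grid_j | x_{i-1} = grid_g).

    Built by change of variables from the latent Gaussian step; each row is
    normalized over the grid.  With zero process noise the kernel degenerates
    to a delta at the grid point nearest the deterministic image.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.min() <= 0.0 or grid.max() >= 1.0:
        raise DomainError("grid must lie strictly inside (0, 1)")
    G = grid.size
    mean = model.a * grid + model.b  # latent mean per source point
    if model.sigma_eps2 <= 0.0:
        K = np.zeros((G, G))
        target = squash(mean)
        nearest = np.abs(grid[None, :] - target[:, None]).argmin(axis=1)
        K[np.arange(G), nearest] = 1.0
        return K
    sd = float(np.sqrt(model.sigma_eps2))
    h = unsquash(grid)  # latent image of each target point
    jac = 2.0 / (1.0 - (2.0 * grid - 1.0) ** 2)
    dens = spstats.norm.pdf(h[None, :], loc=mean[:, None], scale=sd) * jac[None, :]
    rows = dens.sum(axis=1, keepdims=True)
    if np.any(rows <= 0):
        raise DomainError("transition kernel row vanished; grid too coarse")
    return dens / rows


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def likelihood(
    y_t: Sequence[float],
    entries: Sequence[ObservationEntry],
    grid: np.ndarray,
) -> np.ndarray:
    """Joint likelihood of one time step's feature values over the grid.

    Conditional independence given PERCLOS makes the joint a product of
    per-feature Gaussian densities N(y_c; alpha_c x + beta_c, sigma2_c);
    the product is accumulated in log-space and rescaled to max 1.  Missing
    (NaN) feature values are skipped; with no usable features the result is
    flat.
    """
    grid = np.asarray(grid, dtype=float)
    if len(y_t) != len(entries):
        raise DomainError("one feature value per observation entry required")
    loglik = np.zeros(grid.size)
    for y, e in zip(y_t, entries):
        if y is None or not np.isfinite(y):
            continue
        yv = float(_apply_transform(np.asarray(y, dtype=float), e.transform))
        if not np.isfinite(yv):
            continue
        sd = float(np.sqrt(e.sigma2)) if e.sigma2 > 0 else 0.0
        if sd == 0.0:
            continue  # a zero-variance encoder carries no usable density
        mu = e.alpha * grid + e.beta
        loglik += -0.5 * ((yv - mu) / sd) ** 2 - np.log(sd)
    return np.exp(loglik - loglik.max())


# ---------------------------------------------------------------------------
# Interval construction
# ---------------------------------------------------------------------------

def _cell_cdf_quantiles(grid, pmf_row, probs):
    """Quantiles of a piecewise-linear CDF spreading each mass over its cell."""
    h = grid[1] - grid[0]
    edges = np.concatenate(([grid[0] - h / 2], grid + h / 2))
    cdf = np.concatenate(([0.0], np.cumsum(pmf_row)))
    cdf[-1] = 1.0
    q = np.interp(probs, cdf, edges)
    return np.clip(q, max(grid[0] - h / 2, 0.0), min(grid[-1] + h / 2, 1.0))


def _hpd_interval(grid, pmf_row, level):
    order = np.argsort(pmf_row)[::-1]
    cum = np.cumsum(pmf_row[order])
    k = int(np.searchsorted(cum, level)) + 1
    members = grid[np.sort(order[:k])]
    return members[0], members[-1]


def _summaries(grid, pmf, interval, level):
    mean = pmf @ grid
    lo = np.empty(len(pmf))
    hi = np.empty(len(pmf))
    tail = (1.0 - level) / 2.0
    for t, row in enumerate(pmf):
        if interval == "central":
            lo[t], hi[t] = _cell_cdf_quantiles(grid, row, [tail, 1.0 - tail])
        elif interval == "hpd":
            lo[t], hi[t] = _hpd_interval(grid, row, level)
        else:
            raise DomainError(f"unknown interval type {interval!r}")
    lo = np.minimum(lo, mean)
    hi = np.maximum(hi, mean)
    return mean, lo, hi


# ---------------------------------------------------------------------------
# The filter
# ---------------------------------------------------------------------------

def bayes_filter(
    features: FeatureMatrix,
    entries: Sequence[ObservationEntry],
    model: StateModel,
    grid_size: int = 201,
    prior: str | np.ndarray = "uniform",
    interval: str = "central",
    level: float = 0.95,
) -> Posterior:
    """Run the predict/update recursion over a feature matrix.

    ``entries`` must correspond to columns of ``features`` (matched by
    feature id); typically these are the selected encoder models.  The
    filter is causal: the posterior at step t uses only observations up to
    and including t.  If the update annihilates all mass numerically, that
    step falls back to the prediction alone and a warning is logged.
    """
    entries = list(entries)
    cols = [features.feature_ids.index(e.feature_id) for e in entries]
    Y = features.values[:, cols]
    grid = make_grid(grid_size)
    K = transition_kernel(model, grid)
    G = grid.size
    if isinstance(prior, str):
        if prior != "uniform":
            raise DomainError(f"unknown prior {prior!r}")
        p = np.full(G, 1.0 / G)
    else:
        p = np.asarray(prior, dtype=float)
        p = p / p.sum()
    L = len(features)
    pmf = np.empty((L, G))
    for t in range(L):
        pred = p @ K
        lik = likelihood(Y[t], entries, grid)
        post = pred * lik
        s = post.sum()
        if not np.isfinite(s) or s <= 0.0:
            logger.warning("posterior underflow at step %d; using prediction only", t)
            post, s = pred, pred.sum()
        p = post / s
        pmf[t] = p
    mean, lo, hi = _summaries(grid, pmf, interval, level)
    return Posterior(grid=grid, pmf=pmf, mean=mean, ci_low=lo, ci_high=hi)


def predict_ahead(
    post_row: np.ndarray,
    kernel: np.ndarray,
    n_steps: int,
) -> np.ndarray:
    """Propagate a posterior row ``n_steps`` ahead without updates.

    Returns an (n_steps, G) array of predicted distributions for
    t+1 ... t+n; ``n_steps=0`` returns an empty array and leaves the input
    untouched.
    """
    if n_steps < 0:
        raise DomainError("n_steps must be >= 0")
    p = np.asarray(post_row, dtype=float).copy()
    out = np.empty((n_steps, p.size))
    for k in range(n_steps):
        p = p @ kernel
        p = p / p.sum()
        out[k] = p
    return out


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _metrics(mean, lo, hi, truth):
    rmse = float(np.sqrt(np.mean((mean - truth) ** 2)))
    hpd = float(100.0 * np.mean((lo <= truth) & (truth <= hi)))
    return rmse, hpd


def evaluate(estimate: Posterior, truth: PerclosSeries) -> dict:
    """RMSE, 95%-interval coverage, and PERCLOS-binned versions of both.

    ``hpd_pct`` is the percentage of time steps at which the true PERCLOS
    falls inside the estimated interval.  Time steps with missing truth are
    excluded pairwise; per-bin metrics stratify by the true value over
    [0,.25), [.25,.5), [.5,.75), [.75,1].
    """
    tv = truth.values
    if len(estimate) != tv.size:
        raise DomainError("estimate and truth must have equal length")
    keep = np.isfinite(tv)
    if not keep.any():
        raise DomainError("no overlapping valid time steps to evaluate")
    mean, lo, hi, tv = estimate.mean[keep], estimate.ci_low[keep], estimate.ci_high[keep], tv[keep]
    rmse, hpd = _metrics(mean, lo, hi, tv)
    bins = []
    for lo_b, hi_b in PERCLOS_BINS:
        sel = (tv >= lo_b) & (tv < hi_b)
        if sel.any():
            b_rmse, b_hpd = _metrics(mean[sel], lo[sel], hi[sel], tv[sel])
        else:
            b_rmse = b_hpd = float("nan")
        bins.append(
            {"lo": lo_b, "hi": min(hi_b, 1.0), "n": int(sel.sum()),
             "rmse": b_rmse, "hpd_pct": b_hpd}
        )
    return {"rmse": rmse, "hpd_pct": hpd, "n": int(tv.size), "bins": bins}
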