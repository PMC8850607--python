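"""Per-feature linear-Gaussian encoder models.

Each neural feature y is modelled, conditionally on PERCLOS x, as

    y_k = alpha * x_k + beta + v_k,       v_k ~ N(0, sigma2)

fitted independently per feature and per session by closed-form least
squares.  Features are kept on their natural scale (no z-scoring); a small
transform search (identity, log, exp applied to y) can be run per feature
and the best-fitting variant retained.

Feature selection is a two-sided t-test on the slope with L - 2 degrees of
freedom: the null hypothesis is alpha = 0, and a feature is selected when
its p-value falls below the threshold (0.05 by convention).  No
multiple-testing correction is applied by default; a Benjamini-Hochberg
option is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as spstats

from .exceptions import DomainError, SingularFitError
from .features import FeatureMatrix
from .state import PerclosSeries

__all__ = [
    "ObservationEntry",
    "fit_observation_model",
    "fit_observation_matrix",
    "search_transform",
    "select_features",
    "TRANSFORMS",
]

#: Candidate transforms applied to the feature before the linear fit.
TRANSFORMS = ("identity", "log", "exp")

#: Largest |y| for which exp(y) is entertained in the transform search.
_EXP_GUARD = 80.0


@dataclass
class ObservationEntry:
    """Fitted encoder model for one feature in one session."""

    feature_id: str
    alpha: float
    beta: float
    sigma2: float
    p_slope: float
    r2: float
    resid_acf1: float = 0.0
    transform: str = "identity"
    selected: bool = False
    n: int = 0
    session_id: str | int | None = None

    def __post_init__(self):
        if self.sigma2 < 0:
            raise DomainError("sigma2 must be >= 0")
        if not (0.0 <= self.p_slope <= 1.0):
            raise DomainError("p_slope must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "feature_id": self.feature_id,
            "alpha": self.alpha,
            "beta": self.beta,
            "sigma2": self.sigma2,
            "p_slope": self.p_slope,
            "r2": self.r2,
            "resid_acf1": self.resid_acf1,
            "transform": self.transform,
            "selected": self.selected,
            "n": self.n,
            "session_id": self.session_id,
        }


def _apply_transform(y: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return y
    if transform == "log":
        return np.log(y)
    if transform == "exp":
        return np.exp(y)
    raise DomainError(f"unknown transform {transform!r}")


def _paired(y, x) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    xv = x.values if isinstance(x, PerclosSeries) else np.asarray(x, dtype=float)
    if y.shape != xv.shape:
        raise DomainError("feature and PERCLOS series must have equal length")
    keep = np.isfinite(y) & np.isfinite(xv)
    y, xv = y[keep], xv[keep]
    if y.size < 3:
        raise DomainError("need at least 3 paired samples")
    return y, xv


def fit_observation_model(
    y,
    x,
    feature_id: str = "",
    transform: str = "identity",
    session_id=None,
) -> ObservationEntry:
    """Closed-form simple-regression fit of one feature on PERCLOS.

    Returns slope, intercept and residual variance together with the slope
    t-test p-value (two-sided, L-2 dof), R^2, and the lag-1 residual
    autocorrelation as goodness-of-fit diagnostics.

    A constant PERCLOS regressor is a singular fit.  A constant feature is
    handled by convention: alpha = 0, p = 1, r2 = 0.
    """
    y, xv = _paired(y, x)
    y = _apply_transform(y, transform)
    if not np.all(np.isfinite(y)):
        raise DomainError(f"transform {transform!r} produced non-finite values")
    L = y.size
    mu_x = xv.mean()
    mu_y = y.mean()
    sxx = float(np.sum((xv - mu_x) ** 2))
    # relative thresholds: rounding noise on constant inputs is not variation
    x_scale = max(float(np.abs(xv).max()), 1.0)
    if sxx <= L * (1e-9 * x_scale) ** 2:
        raise SingularFitError("PERCLOS regressor is constant; slope undefined")
    tss = float(np.sum((y - mu_y) ** 2))
    y_scale = max(float(np.abs(y).max()), 1e-300)
    if tss <= L * (1e-9 * y_scale) ** 2:
        # degenerate (constant) feature
        return ObservationEntry(
            feature_id=feature_id, alpha=0.0, beta=float(mu_y), sigma2=0.0,
            p_slope=1.0, r2=0.0, resid_acf1=0.0, transform=transform,
            n=L, session_id=session_id,
        )
    alpha = float(np.sum((xv - mu_x) * (y - mu_y)) / sxx)
    beta = float(mu_y - alpha * mu_x)
    resid = y - alpha * xv - beta
    rss = float(np.sum(resid ** 2))
    sigma2 = float(np.var(resid))
    r2 = float(np.clip(1.0 - rss / tss, 0.0, 1.0))
    if rss <= 0.0:
        p = 0.0
    else:
        se = math.sqrt(rss / (L - 2) / sxx)
        tstat = alpha / se
        p = float(2.0 * spstats.t.sf(abs(tstat), df=L - 2))
    denom = float(np.sum(resid ** 2))
    acf1 = float(np.sum(resid[:-1] * resid[1:]) / denom) if denom > 0 else 0.0
    return ObservationEntry(
        feature_id=feature_id, alpha=alpha, beta=beta, sigma2=sigma2,
        p_slope=p, r2=r2, resid_acf1=acf1, transform=transform,
        n=L, session_id=session_id,
    )


def fit_observation_matrix(
    fm: FeatureMatrix,
    x: PerclosSeries,
    transform_search: bool = False,
) -> list[ObservationEntry]:
    """Fit every column of a feature matrix against the paired PERCLOS series."""
    if len(fm) != len(x):
        raise DomainError("feature matrix and PERCLOS series must share the grid")
    fit = search_transform if transform_search else fit_observation_model
    return [
        fit(fm.values[:, j], x, feature_id=fid, session_id=fm.session_id)
        for j, fid in enumerate(fm.feature_ids)
    ]


def search_transform(
    y, x, feature_id: str = "", session_id=None,
    transforms: Sequence[str] = TRANSFORMS,
) -> ObservationEntry:
    """Fit identity/log/exp variants of a feature and keep the best R^2.

    The log candidate is only evaluated when the feature is strictly
    positive; the exp candidate only when its magnitude stays below an
    overflow guard.  Ties go to the earlier candidate, so the identity fit
    wins when nothing improves on it.
    """
    yv = np.asarray(y, dtype=float)
    finite = yv[np.isfinite(yv)]
    best: ObservationEntry | None = None
    for tr in transforms:
        if tr == "log" and (finite.size == 0 or finite.min() <= 0):
            continue
        if tr == "exp" and (finite.size == 0 or np.abs(finite).max() >= _EXP_GUARD):
            continue
        entry = fit_observation_model(
            yv, x, feature_id=feature_id, transform=tr, session_id=session_id
        )
        if best is None or entry.r2 > best.r2:
            best = entry
    if best is None:
        raise DomainError("no feasible transform candidate")
    return best


def pool_entries(
    tables: "dict[object, Sequence[ObservationEntry]]",
    feature_ids: Sequence[str],
    series_by_session: "dict[object, PerclosSeries]",
    scope: Sequence | None = None,
) -> list[ObservationEntry]:
    """Combine per-session encoder fits into one model per feature.

    Used when decoding a session for which no labelled data exist: the
    pooled model averages alpha and beta over the training sessions and
    inflates the noise variance by the cross-session spread of the fitted
    lines, so features whose slope is inconsistent across drivers are
    automatically down-weighted in the decoder::

        sigma2_pooled = mean_d[ sigma2_d + E_d((alpha_d - mean_alpha) x
                                               + (beta_d - mean_beta))^2 ]

    where the inner expectation uses that session's PERCLOS moments.  Only
    sessions whose fit used the feature's majority transform participate.
    """
    scope = list(tables.keys()) if scope is None else list(scope)
    if not scope:
        raise DomainError("pooling scope is empty")
    by_feat = {s: {e.feature_id: e for e in tables[s]} for s in scope}
    moments = {}
    for s in scope:
        xv = series_by_session[s].values
        xv = xv[np.isfinite(xv)]
        moments[s] = (float(xv.mean()), float(np.mean(xv ** 2)))
    pooled = []
    for fid in feature_ids:
        fits = [(s, by_feat[s][fid]) for s in scope if fid in by_feat[s]]
        if not fits:
            raise DomainError(f"feature {fid!r} fitted in no scope session")
        transforms = [e.transform for _, e in fits]
        majority = max(set(transforms), key=transforms.count)
        fits = [(s, e) for s, e in fits if e.transform == majority]
        a_bar = float(np.mean([e.alpha for _, e in fits]))
        b_bar = float(np.mean([e.beta for _, e in fits]))
        var_terms = []
        for s, e in fits:
            m1, m2 = moments[s]
            da, db = e.alpha - a_bar, e.beta - b_bar
            var_terms.append(e.sigma2 + da * da * m2 + 2 * da * db * m1 + db * db)
        pooled.append(
            ObservationEntry(
                feature_id=fid, alpha=a_bar, beta=b_bar,
                sigma2=float(np.mean(var_terms)), p_slope=0.0, r2=0.0,
                transform=majority, selected=True,
                n=int(sum(e.n for _, e in fits)), session_id="pooled",
            )
        )
    return pooled


def select_features(
    entries: Iterable[ObservationEntry],
    threshold: float = 0.05,
    method: str = "none",
) -> np.ndarray:
    """Mark entries whose slope is significant; returns the boolean mask.

    ``method="none"`` applies the raw per-feature threshold
    (selected iff p_slope < threshold); ``method="bh"`` applies a
    Benjamini-Hochberg step-up at FDR = threshold instead.  Entries are
    updated in place.
    """
    entries = list(entries)
    p = np.array([e.p_slope for e in entries])
    if method == "none":
        mask = p < threshold
    elif method == "bh":
        m = p.size
        order = np.argsort(p, kind="stable")
        ranked = p[order] <= threshold * (np.arange(1, m + 1) / m)
        k = np.flatnonzero(ranked)
        mask = np.zeros(m, dtype=bool)
        if k.size:
            mask[order[: k.max() + 1]] = True
    else:
        raise DomainError(f"unknown selection method {method!r}")
    for e, s in zip(entries, mask):
        e.selected = bool(s)
    return mask
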