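"""Bounded state-transition process for PERCLOS dynamics.

PERCLOS -- the fraction of time within a one-minute window that the eyes are
at least 80% closed -- is treated as a latent cognitive state evolving on a
30-second grid.  Its dynamic is a first-order Markov recursion squashed into
the open unit interval:

    X_i = 0.5 * (1 + tanh(a * X_{i-1} + b + eps_{i-1})),   eps ~ N(0, sigma_eps2)

The tanh squash keeps every trajectory strictly inside (0, 1) for any finite
parameters.  Because the squash is invertible, parameter identification is a
plain linear least-squares problem in the transformed variable
h_i = atanh(2 X_i - 1): the model says h_i = a X_{i-1} + b + eps_{i-1}, so
(a, b) come from the closed-form normal equations and sigma_eps2 from the
variance of the residuals.

Observed PERCLOS can touch 0 and 1 exactly (eyes fully open or closed for a
whole minute); atanh diverges there, so values are clipped into
[CLIP, 1 - CLIP] before the inverse transform.  The default CLIP = 1e-4
distorts nothing in the mid-range where the dynamics of interest live.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from ._rng import named_rng
from .exceptions import DomainError, SingularFitError

__all__ = [
    "CLIP",
    "StateModel",
    "PerclosSeries",
    "StateFit",
    "ResidualReport",
    "squash",
    "unsquash",
    "clip_unit",
    "simulate_states",
    "fit_state_model",
    "one_step_residuals",
]

#: Half-width of the exclusion zone at each end of [0, 1] before atanh.
CLIP = 1e-4


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateModel:
    """Parameters of the tanh-bounded PERCLOS transition process.

    Attributes
    ----------
    a : float
        Slope of the latent linear recursion.
    b : float
        Intercept of the latent linear recursion.
    sigma_eps2 : float
        Variance of the zero-mean Gaussian process noise (>= 0).
    """

    a: float
    b: float
    sigma_eps2: float

    def __post_init__(self):
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise DomainError("state parameters a, b must be finite")
        if not (np.isfinite(self.sigma_eps2) and self.sigma_eps2 >= 0):
            raise DomainError("sigma_eps2 must be finite and >= 0")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "sigma_eps2": self.sigma_eps2}

    @classmethod
    def from_dict(cls, d: dict) -> "StateModel":
        return cls(a=float(d["a"]), b=float(d["b"]), sigma_eps2=float(d["sigma_eps2"]))

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "StateModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class PerclosSeries:
    """A PERCLOS trajectory on the shared sliding-window grid.

    Values live in [0, 1]; NaN marks windows invalidated by missing eyelid
    data.  ``step_seconds`` is the hop between windows (30 s by convention)
    and ``window_seconds`` the window length (60 s), so consecutive windows
    overlap.
    """

    values: np.ndarray
    step_seconds: float = 30.0
    window_seconds: float = 60.0
    session_id: str | int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DomainError("PerclosSeries values must be one-dimensional")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise DomainError("PERCLOS values must lie in [0, 1]")
        if not (self.step_seconds > 0 and self.window_seconds > 0):
            raise DomainError("step_seconds and window_seconds must be positive")
        if self.step_seconds > self.window_seconds:
            raise DomainError("step_seconds must not exceed window_seconds")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Window start times in seconds."""
        return np.arange(len(self)) * self.step_seconds

    def dropna(self) -> "PerclosSeries":
        return replace(self, values=self.values[np.isfinite(self.values)])


@dataclass(frozen=True)
class StateFit:
    """Result of identifying the state-transition process by least squares."""

    model: StateModel
    mu_x: float          #: sample mean of the lagged PERCLOS regressor
    mu_h: float          #: sample mean of the transformed target h = atanh(2X-1)
    rss: float           #: residual sum of squares in h-space
    n_pairs: int         #: number of (X_{i-1}, h_i) pairs used

    # convenience pass-throughs so a StateFit can be used where only the
    # parameters matter
    @property
    def a(self) -> float:
        return self.model.a

    @property
    def b(self) -> float:
        return self.model.b

    @property
    def sigma_eps2(self) -> float:
        return self.model.sigma_eps2


@dataclass(frozen=True)
class ResidualReport:
    """One-step-ahead residuals on the PERCLOS scale and their RMSE."""

    residuals: np.ndarray
    rmse: float


# ---------------------------------------------------------------------------
# Squash / unsquash
# ---------------------------------------------------------------------------

def squash(z):
    """Map the real line into (0, 1): ``squash(z) = 0.5 * (1 + tanh(z))``."""
    return 0.5 * (1.0 + np.tanh(z))


def unsquash(x):
    """Exact inverse of :func:`squash`: ``atanh(2x - 1)``.

    Raises
    ------
    DomainError
        If any value lies outside the open interval (0, 1).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0) or np.any(x >= 1.0):
        raise DomainError("unsquash requires values strictly inside (0, 1)")
    out = np.arctanh(2.0 * x - 1.0)
    return float(out) if out.ndim == 0 else out


def clip_unit(x, clip: float = CLIP):
    """Clip values into [clip, 1 - clip] so that :func:`unsquash` is defined."""
    return np.clip(np.asarray(x, dtype=float), clip, 1.0 - clip)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_states(
    model: StateModel,
    n_steps: int,
    x0: float = 0.2,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    step_seconds: float = 30.0,
    window_seconds: float = 60.0,
    session_id=None,
) -> PerclosSeries:
    """Simulate ``n_steps`` values of the bounded transition process.

    The returned series contains X_1 ... X_{n_steps}; the initial condition
    ``x0`` (strictly inside (0, 1)) is not included.  Reproducible for a
    fixed ``seed``; pass ``rng`` to control the stream explicitly.
    """
    if n_steps < 1:
        raise DomainError("n_steps must be >= 1")
    if not (0.0 < x0 < 1.0):
        raise DomainError("x0 must lie strictly inside (0, 1)")
    if rng is None:
        rng = named_rng(seed, "simulate_states")
    sd = float(np.sqrt(model.sigma_eps2))
    eps = rng.normal(0.0, sd, size=n_steps) if sd > 0 else np.zeros(n_steps)
    x = np.empty(n_steps)
    prev = float(x0)
    for i in range(n_steps):
        prev = squash(model.a * prev + model.b + eps[i])
        x[i] = prev
    return PerclosSeries(
        x, step_seconds=step_seconds, window_seconds=window_seconds, session_id=session_id
    )


# ---------------------------------------------------------------------------
# Identification
# ---------------------------------------------------------------------------

def _pairs_from_series(
    series: Iterable[PerclosSeries] | PerclosSeries, clip: float
) -> tuple[np.ndarray, np.ndarray]:
    """Build (X_{i-1}, h_i) regression pairs, never spanning a session boundary."""
    if isinstance(series, PerclosSeries):
        series = [series]
    xs, hs = [], []
    for s in series:
        v = s.values[np.isfinite(s.values)]
        if v.size < 2:
            continue
        v = clip_unit(v, clip)
        xs.append(v[:-1])
        hs.append(unsquash(v[1:]))
    if not xs:
        raise DomainError("no usable (X_{i-1}, h_i) pairs in input")
    return np.concatenate(xs), np.concatenate(hs)


def fit_state_model(
    series: Iterable[PerclosSeries] | PerclosSeries, clip: float = CLIP
) -> StateFit:
    """Identify (a, b, sigma_eps2) by closed-form least squares.

    Values are clipped into [clip, 1-clip], transformed with
    h_i = atanh(2 X_i - 1), and (a, b) solve the normal equations of the
    regression of h_i on X_{i-1}.  When several sessions are supplied they
    are concatenated, but pairs that would span a session boundary are
    excluded -- there is no dynamical link between separate driving tests.
    ``sigma_eps2`` is the variance of the residuals
    eps_{i-1} = h_i - a X_{i-1} - b.
    """
    x_prev, h = _pairs_from_series(series, clip)
    if x_prev.size < 2:
        raise DomainError("need at least 3 samples (2 transition pairs) to fit")
    mu_x = float(x_prev.mean())
    mu_h = float(h.mean())
    sxx = float(np.sum((x_prev - mu_x) ** 2))
    if sxx <= x_prev.size * 1e-18:  # rounding noise, not variation
        raise SingularFitError("regressor X_{i-1} is constant; slope undefined")
    a = float(np.sum((x_prev - mu_x) * (h - mu_h)) / sxx)
    b = mu_h - a * mu_x
    resid = h - a * x_prev - b
    rss = float(np.sum(resid ** 2))
    sigma_eps2 = float(np.var(resid))
    model = StateModel(a=a, b=b, sigma_eps2=sigma_eps2)
    return StateFit(model=model, mu_x=mu_x, mu_h=mu_h, rss=rss, n_pairs=int(x_prev.size))


def one_step_residuals(x: PerclosSeries, model: StateModel, clip: float = CLIP) -> ResidualReport:
    """One-step-ahead prediction residuals on the PERCLOS scale.

    residual_i = X_i - squash(a X_{i-1} + b), i.e. the error of the
    noise-free one-step prediction from the previous observed value.
    """
    v = x.values[np.isfinite(x.values)]
    if v.size < 2:
        raise DomainError("need at least 2 values for one-step residuals")
    v = clip_unit(v, clip)
    pred = squash(model.a * v[:-1] + model.b)
    resid = v[1:] - pred
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    return ResidualReport(residuals=resid, rmse=rmse)
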