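"""Synthetic driving-session generator.

No public recording of the original driving-simulator study exists, so this
module generates sessions with exactly the statistical structure the
framework assumes, at two levels:

* **Feature level** -- PERCLOS trajectories from the bounded state
  recursion, and per-feature observations from the linear-Gaussian encoder
  y = alpha*x + beta + N(0, sigma2).  Ground-truth parameters are returned
  so fitting, selection, and decoding can be checked against them.

* **Raw-signal level** -- multichannel band-limited noise whose delta and
  theta amplitudes rise with the window's target PERCLOS (the "push"
  families) and whose alpha component mixes in skewed innovations that fade
  as PERCLOS rises (the "pull" direction), plus an eyelid trace whose
  windowed closure fraction reproduces the target.

Default study conditions mirror the framework's application setting:
15 training + 3 test sessions of 59 windows (30-minute drives on the
60 s / 30 s grid), state parameters a = 3.93, b = -1.79, sigma_eps2 = 0.03,
and 28 informative features out of 450, spread over the four biomarker
families with family-specific positive-slope probabilities (0.73 theta
power, 0.66 delta power, 0.488 alpha skewness, 0.444 delta mobility).

Under those state parameters a session's PERCLOS wanders in a narrow band
around one vigilance regime (the recursion is bistable with rare
transitions), so the informative couplings use an observation noise
standard deviation of 0.02 against a unit slope -- an encoder R^2 around
0.3, comparable to a decent real EEG feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from ._rng import named_seedseq
from .exceptions import DomainError
from .features import ANALYSIS_CHANNELS, FEATURE_CATALOG, Recording, bandpass_subbands
from .observation import ObservationEntry
from .state import PerclosSeries, StateModel, simulate_states
from .features import FeatureMatrix

__all__ = [
    "DEFAULT_STATE",
    "FamilyCoupling",
    "default_obs_catalog",
    "SyntheticSpec",
    "SessionData",
    "generate_feature_sessions",
    "generate_raw_session",
]

#: State-transition parameters used as the generating truth throughout.
DEFAULT_STATE = StateModel(a=3.93, b=-1.79, sigma_eps2=0.03)

_THETA_CHANNELS = ("Fz", "T7", "T8", "C3", "C4", "PO7", "EOG")
_MOBILITY_CHANNELS = ("T8", "PO8", "EOG")


@dataclass(frozen=True)
class FamilyCoupling:
    """Generating encoder parameters for one biomarker family."""

    channels: tuple[str, ...]
    alpha: float = 1.0          #: slope magnitude (sign drawn per session)
    beta: float = 0.0
    sigma2: float = 4e-4        #: observation noise variance (sd 0.02)
    positive_prob: float = 1.0  #: per-session probability of a positive slope


def default_obs_catalog() -> dict[str, FamilyCoupling]:
    """The four biomarker families, 9 + 9 + 7 + 3 = 28 informative features."""
    return {
        "alpha_skewness": FamilyCoupling(ANALYSIS_CHANNELS, positive_prob=0.488),
        "delta_power": FamilyCoupling(ANALYSIS_CHANNELS, positive_prob=0.66),
        "theta_power": FamilyCoupling(_THETA_CHANNELS, positive_prob=0.73),
        "delta_hjorth_mobility": FamilyCoupling(_MOBILITY_CHANNELS, positive_prob=0.444),
    }


@dataclass
class SyntheticSpec:
    """Conditions for feature-level session generation."""

    state: StateModel = DEFAULT_STATE
    n_sessions: int = 15
    steps_per_session: int = 59
    obs_catalog: Mapping[str, FamilyCoupling] = field(default_factory=default_obs_catalog)
    noise_sigma2: float = 4e-4   #: variance of the uninformative features
    informative_fraction: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.steps_per_session < 3:
            raise DomainError("steps_per_session must be >= 3")
        if self.informative_fraction is not None and not (
            0.0 <= self.informative_fraction <= 1.0
        ):
            raise DomainError("informative_fraction must lie in [0, 1]")

    def feature_ids(self) -> list[str]:
        return [f"{ch}__{feat}" for ch in ANALYSIS_CHANNELS for feat in FEATURE_CATALOG]

    def couplings(self) -> dict[str, FamilyCoupling]:
        """Map feature_id -> generating coupling for the informative set.

        By default the informative set comes from ``obs_catalog`` (feature
        family x channel).  When ``informative_fraction`` is given, that
        share of the 450 features is drawn at random instead (uniform
        couplings, consistent positive sign).
        """
        ids = self.feature_ids()
        if self.informative_fraction is not None:
            k = int(round(self.informative_fraction * len(ids)))
            rng = np.random.default_rng(named_seedseq(self.seed, "informative_set"))
            chosen = rng.choice(len(ids), size=k, replace=False)
            c = FamilyCoupling(channels=(), positive_prob=1.0)
            return {ids[j]: c for j in sorted(chosen)}
        out = {}
        for family, c in self.obs_catalog.items():
            for ch in c.channels:
                out[f"{ch}__{family}"] = c
        return out


@dataclass
class SessionData:
    """One generated session with its ground truth."""

    perclos: PerclosSeries
    features: FeatureMatrix
    true_entries: list[ObservationEntry]


def generate_feature_sessions(spec: SyntheticSpec) -> list[SessionData]:
    """Generate ``spec.n_sessions`` feature-level sessions.

    States come from the bounded recursion (independent substreams per
    session, initial PERCLOS drawn in the alert range [0.05, 0.35]);
    features from the linear-Gaussian encoder, with slope signs drawn per
    session and family.  Bit-identical for a fixed ``spec.seed``.
    """
    ids = spec.feature_ids()
    couplings = spec.couplings()
    root = named_seedseq(spec.seed, "feature_sessions")
    sessions = []
    for d, child in enumerate(root.spawn(spec.n_sessions)):
        rng = np.random.default_rng(child)
        sid = d + 1
        x0 = rng.uniform(0.05, 0.35)
        x = simulate_states(
            spec.state, spec.steps_per_session, x0=x0, rng=rng, session_id=sid
        )
        L = len(x)
        values = np.empty((L, len(ids)))
        entries = []
        for j, fid in enumerate(ids):
            c = couplings.get(fid)
            if c is None:
                sd = float(np.sqrt(spec.noise_sigma2))
                values[:, j] = rng.normal(0.0, sd, size=L)
                entries.append(
                    ObservationEntry(
                        feature_id=fid, alpha=0.0, beta=0.0,
                        sigma2=spec.noise_sigma2, p_slope=1.0, r2=0.0,
                        selected=False, n=L, session_id=sid,
                    )
                )
            else:
                sign = 1.0 if rng.random() < c.positive_prob else -1.0
                alpha = sign * c.alpha
                sd = float(np.sqrt(c.sigma2))
                values[:, j] = alpha * x.values + c.beta + rng.normal(0.0, sd, size=L)
                entries.append(
                    ObservationEntry(
                        feature_id=fid, alpha=alpha, beta=c.beta,
                        sigma2=c.sigma2, p_slope=0.0, r2=0.0,
                        selected=True, n=L, session_id=sid,
                    )
                )
        fm = FeatureMatrix(
            values, ids,
            step_seconds=x.step_seconds, window_seconds=x.window_seconds,
            session_id=sid,
        )
        sessions.append(SessionData(perclos=x, features=fm, true_entries=entries))
    return sessions


# ---------------------------------------------------------------------------
# Raw-signal generation
# ---------------------------------------------------------------------------

def _closure_fractions(target: np.ndarray) -> np.ndarray:
    """Per-step-block closure fractions whose overlapping-window means hit
    the targets.

    Window j averages blocks j and j+1, so the fractions solve the bounded
    least-squares system 0.5 (f_j + f_{j+1}) = t_j with f in [0, 1]; the
    solution is exact whenever the target is feasible (overlapping windows
    cannot change by more than 0.5 per step for any eyelid trace).
    """
    from scipy.optimize import lsq_linear

    L = target.size
    A = np.zeros((L, L + 1))
    idx = np.arange(L)
    A[idx, idx] = 0.5
    A[idx, idx + 1] = 0.5
    res = lsq_linear(A, target, bounds=(0.0, 1.0), method="bvls")
    return np.clip(res.x, 0.0, 1.0)


def generate_raw_session(
    perclos_target: PerclosSeries,
    fs: float = 500.0,
    seed: int = 0,
    channels: Sequence[str] = ANALYSIS_CHANNELS,
    drowsiness_gain: float = 1.0,
    session_id=None,
) -> Recording:
    """Raw multichannel recording plus eyelid trace for a target trajectory.

    Each channel is a sum of band-limited noise components; the delta and
    theta amplitudes scale as (1 + gain * PERCLOS) per 30-s block, the beta
    component is constant, and the alpha component blends symmetric with
    skewed innovations so its skewness falls as PERCLOS rises.  The eyelid
    trace concentrates each block's closure budget in one episode, so the
    windowed closure fraction reproduces the target up to sample rounding.
    """
    target = np.asarray(perclos_target.values, dtype=float)
    if np.any(~np.isfinite(target)) or target.min() < 0 or target.max() > 1:
        raise DomainError("perclos_target must be finite and within [0, 1]")
    L = target.size
    block = int(round(perclos_target.step_seconds * fs))
    n = (L + 1) * block
    # block-level drowsiness for amplitude modulation
    b = np.empty(L + 1)
    b[0] = target[0]
    b[-1] = target[-1]
    if L > 1:
        b[1:-1] = 0.5 * (target[:-1] + target[1:])
    gain_blocks = 1.0 + drowsiness_gain * b
    w_skew = 1.0 - b  # pull: alpha skewness fades with drowsiness

    root = named_seedseq(seed, "raw_session")
    streams = root.spawn(len(channels))
    samples = np.empty((len(channels), n))
    for ci, child in enumerate(streams):
        rng = np.random.default_rng(child)
        white = rng.standard_normal(n)
        skewed = rng.exponential(1.0, size=n) - 1.0
        comp = bandpass_subbands(white, fs)
        alpha_skewed = bandpass_subbands(skewed, fs)["alpha"]
        gain = np.repeat(gain_blocks, block)
        w = np.repeat(w_skew, block)
        sig = (
            comp["delta"] * gain
            + comp["theta"] * gain
            + comp["alpha"] * (1.0 - 0.5 * w)
            + alpha_skewed * w
            + 0.5 * comp["beta"]
        )
        samples[ci] = 10.0 * sig  # microvolt-ish scale

    f = _closure_fractions(target)
    eyelid = np.ones(n)
    for j in range(L + 1):
        n_closed = int(round(f[j] * block))
        eyelid[j * block : j * block + n_closed] = 0.0

    return Recording(
        samples=samples,
        fs=fs,
        channel_names=list(channels),
        eyelid=eyelid,
        session_id=session_id,
    )
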