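"""Windowed feature extraction: PERCLOS from the eyelid trace, and the
per-channel EEG/EOG feature catalog.

Both the drowsiness ground truth and the neural features are computed on the
same sliding-window grid -- one-minute windows advancing by 30 seconds -- so
that every feature row is paired with one PERCLOS value.

PERCLOS is the fraction of time within a window that the eyes are at least
80% closed.  Eye trackers report eyelid aperture on an arbitrary relative
scale, so "closed" is judged against a per-session open-eye baseline (the
95th percentile of the aperture trace): a sample counts as closed when the
aperture is at or below 20% of that baseline.

Each of the nine analysis channels (eight scalp EEG electrodes plus one
derived EOG) yields 50 features per window: eleven statistics for each of
the four canonical sub-bands (delta 0.5-4 Hz, theta 4-8 Hz, alpha 8-12 Hz,
beta 12-30 Hz) plus six broadband descriptors, for 9 x 50 = 450 columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .exceptions import ConfigurationError, DomainError
from .state import PerclosSeries

__all__ = [
    "BANDS",
    "EEG_CHANNELS",
    "ANALYSIS_CHANNELS",
    "FEATURE_CATALOG",
    "Recording",
    "FeatureMatrix",
    "feature_family",
    "derive_eog",
    "compute_perclos",
    "bandpass_subbands",
    "extract_features",
]

#: Canonical EEG sub-bands in Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
}

EEG_CHANNELS = ("Cz", "Fz", "T7", "T8", "C3", "C4", "PO7", "PO8")
ANALYSIS_CHANNELS = EEG_CHANNELS + ("EOG",)

_BAND_STATS = (
    "power",
    "relpower",
    "activity",
    "skewness",
    "kurtosis",
    "hjorth_mobility",
    "hjorth_complexity",
    "zcr",
    "line_length",
    "ptp",
    "rms",
)
_BROADBAND_STATS = (
    "total_power",
    "spectral_entropy",
    "hjorth_mobility",
    "hjorth_complexity",
    "skewness",
    "kurtosis",
)

#: The 50 per-channel feature names (band-prefixed stats + broadband stats).
FEATURE_CATALOG: tuple[str, ...] = tuple(
    f"{band}_{stat}" for band in BANDS for stat in _BAND_STATS
) + _BROADBAND_STATS

assert len(FEATURE_CATALOG) == 50


def feature_family(feature_id: str) -> str:
    """The catalog name of a ``CHANNEL__FEATURE`` column, ignoring channel."""
    return feature_id.split("__", 1)[1] if "__" in feature_id else feature_id


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """A multichannel recording with an optional time-aligned eyelid trace.

    ``samples`` is (n_channels, n_samples) in microvolts; ``eyelid`` is the
    per-sample aperture fraction (1 = fully open), NaN where the tracker
    dropped out.
    """

    samples: np.ndarray
    fs: float
    channel_names: Sequence[str]
    eyelid: np.ndarray | None = None
    session_id: str | int | None = None

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise DomainError("sampling rate must be positive")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ConfigurationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} sample rows"
            )
        self.channel_names = list(self.channel_names)
        if self.eyelid is not None:
            self.eyelid = np.asarray(self.eyelid, dtype=float)
            if self.eyelid.shape != (self.samples.shape[1],):
                raise ConfigurationError("eyelid trace must align with samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def _find(self, name: str) -> int | None:
        lowered = [c.lower() for c in self.channel_names]
        return lowered.index(name.lower()) if name.lower() in lowered else None

    def channel(self, name: str) -> np.ndarray:
        idx = self._find(name)
        if idx is None:
            raise ConfigurationError(f"channel {name!r} not in recording")
        return self.samples[idx]


@dataclass
class FeatureMatrix:
    """An (L, C) matrix of windowed neural features on the PERCLOS grid.

    Column names follow the ``CHANNEL__FEATURE`` convention, e.g.
    ``C4__theta_power``.
    """

    values: np.ndarray
    feature_ids: Sequence[str]
    step_seconds: float = 30.0
    window_seconds: float = 60.0
    session_id: str | int | None = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.feature_ids):
            raise ConfigurationError(
                f"{len(self.feature_ids)} feature ids for "
                f"{self.values.shape[1]} columns"
            )
        self.feature_ids = list(self.feature_ids)

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) * self.step_seconds

    def column(self, feature_id: str) -> np.ndarray:
        try:
            j = self.feature_ids.index(feature_id)
        except ValueError:
            raise ConfigurationError(f"feature {feature_id!r} not in matrix") from None
        return self.values[:, j]

    def select(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return replace(self, values=self.values[:, idx], feature_ids=list(feature_ids))


# ---------------------------------------------------------------------------
# EOG derivation
# ---------------------------------------------------------------------------

def derive_eog(rec: Recording) -> np.ndarray:
    """EOG = upper electrode minus lower electrode, sample-wise.

    If the recording already carries a precomputed ``EOG`` channel it is
    passed through unchanged.
    """
    direct = rec._find("EOG")
    if direct is not None:
        return rec.samples[direct]
    up, lo = rec._find("EOG_upper"), rec._find("EOG_lower")
    if up is None or lo is None:
        raise ConfigurationError(
            "recording has neither an EOG channel nor both EOG_upper/EOG_lower"
        )
    return rec.samples[up] - rec.samples[lo]


# ---------------------------------------------------------------------------
# PERCLOS from the eyelid trace
# ---------------------------------------------------------------------------

def _interpolate_gaps(x: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly fill NaN runs of length <= max_gap; leave longer runs NaN."""
    x = x.copy()
    isnan = np.isnan(x)
    if not isnan.any():
        return x
    # locate NaN runs
    edges = np.flatnonzero(np.diff(np.concatenate(([0], isnan.view(np.int8), [0]))))
    starts, stops = edges[::2], edges[1::2]
    idx = np.arange(x.size)
    valid = ~isnan
    if valid.sum() >= 2:
        filled = np.interp(idx, idx[valid], x[valid])
        for s, e in zip(starts, stops):
            if (e - s) <= max_gap and s > 0 and e < x.size:
                x[s:e] = filled[s:e]
    return x


def compute_perclos(
    eyelid: np.ndarray,
    fs: float,
    window_s: float = 60.0,
    step_s: float = 30.0,
    closure_frac: float = 0.8,
    baseline_quantile: float = 0.95,
    max_gap_s: float = 0.5,
    session_id=None,
) -> PerclosSeries:
    """Windowed fraction of time the eyes are at least ``closure_frac`` closed.

    A sample counts as closed when its aperture is at or below
    ``(1 - closure_frac)`` times the session's open-eye baseline (the
    ``baseline_quantile`` of the aperture trace).  Windows advance by
    ``step_s``; the number of windows is floor((T - window)/step) + 1.
    NaN gaps up to ``max_gap_s`` are interpolated linearly; windows still
    containing missing samples are flagged NaN.
    """
    eyelid = np.asarray(eyelid, dtype=float)
    win = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if eyelid.size < win:
        raise DomainError("eyelid trace shorter than one window")
    filled = _interpolate_gaps(eyelid, max_gap=int(round(max_gap_s * fs)))
    finite = filled[np.isfinite(filled)]
    if finite.size == 0:
        raise DomainError("eyelid trace is entirely missing")
    baseline = float(np.quantile(finite, baseline_quantile))
    threshold = (1.0 - closure_frac) * baseline
    closed = filled <= threshold
    n_win = (eyelid.size - win) // step + 1
    out = np.empty(n_win)
    for w in range(n_win):
        seg = filled[w * step : w * step + win]
        if np.isnan(seg).any():
            out[w] = np.nan
        else:
            out[w] = closed[w * step : w * step + win].mean()
    return PerclosSeries(
        out, step_seconds=step_s, window_seconds=window_s, session_id=session_id
    )


# ---------------------------------------------------------------------------
# Band-pass decomposition
# ---------------------------------------------------------------------------

def bandpass_subbands(
    x: np.ndarray, fs: float, bands: Mapping[str, tuple[float, float]] = BANDS,
    order: int = 4,
) -> dict[str, np.ndarray]:
    """Zero-phase Butterworth band-pass into the canonical sub-bands.

    Output arrays have the same length as the input.
    """
    x = np.asarray(x, dtype=float)
    top = max(hi for _, hi in bands.values())
    if fs <= 2 * top:
        raise DomainError(f"fs={fs} too low for the {top} Hz band edge")
    out = {}
    for name, (lo, hi) in bands.items():
        sos = sps.butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")
        out[name] = sps.sosfiltfilt(sos, x)
    return out


# ---------------------------------------------------------------------------
# Window statistics
# ---------------------------------------------------------------------------

def _hjorth_mobility(x: np.ndarray) -> float:
    v = np.var(x)
    if v <= 0:
        return 0.0
    return float(np.sqrt(np.var(np.diff(x)) / v))


def _hjorth_complexity(x: np.ndarray) -> float:
    m = _hjorth_mobility(x)
    if m <= 0:
        return 0.0
    md = _hjorth_mobility(np.diff(x))
    return float(md / m)


def _skew(x: np.ndarray) -> float:
    if np.var(x) <= 0:
        return 0.0
    return float(spstats.skew(x, bias=True))


def _kurt(x: np.ndarray) -> float:
    if np.var(x) <= 0:
        return 0.0
    return float(spstats.kurtosis(x, fisher=True, bias=True))


def _spectral_entropy(x: np.ndarray, fs: float) -> float:
    if np.var(x) <= 0:
        return 0.0
    _, psd = sps.periodogram(x, fs=fs)
    psd = psd[psd > 0]
    if psd.size < 2:
        return 0.0
    p = psd / psd.sum()
    return float(-(p * np.log(p)).sum() / np.log(p.size))


def _band_stats(seg: np.ndarray, total_power: float) -> list[float]:
    power = float(np.mean(seg ** 2))
    rel = power / total_power if total_power > 0 else 0.0
    d = np.diff(seg)
    return [
        power,
        rel,
        float(np.var(seg)),
        _skew(seg),
        _kurt(seg),
        _hjorth_mobility(seg),
        _hjorth_complexity(seg),
        float(np.mean(np.signbit(seg[:-1]) != np.signbit(seg[1:]))) if seg.size > 1 else 0.0,
        float(np.sum(np.abs(d))),
        float(np.ptp(seg)),
        float(np.sqrt(np.mean(seg ** 2))),
    ]


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def extract_features(
    rec: Recording,
    window_s: float = 60.0,
    step_s: float = 30.0,
    channels: Sequence[str] = ANALYSIS_CHANNELS,
) -> FeatureMatrix:
    """Evaluate the 50-feature catalog per analysis channel per window.

    The EOG analysis channel is derived (upper minus lower electrode) when
    not already present.  The window grid is identical to the PERCLOS grid,
    so the result pairs row-for-row with :func:`compute_perclos` output for
    the same recording.
    """
    win = int(round(window_s * rec.fs))
    step = int(round(step_s * rec.fs))
    if rec.n_samples < win:
        raise DomainError("recording shorter than one window")
    n_win = (rec.n_samples - win) // step + 1

    signals: dict[str, np.ndarray] = {}
    for ch in channels:
        signals[ch] = derive_eog(rec) if ch.upper() == "EOG" else rec.channel(ch)

    feature_ids = [f"{ch}__{feat}" for ch in channels for feat in FEATURE_CATALOG]
    values = np.empty((n_win, len(feature_ids)))

    col = 0
    for ch in channels:
        raw = signals[ch]
        banded = bandpass_subbands(raw, rec.fs)
        for w in range(n_win):
            sl = slice(w * step, w * step + win)
            raw_seg = raw[sl]
            total_power = float(np.var(raw_seg))
            row: list[float] = []
            for band in BANDS:
                row.extend(_band_stats(banded[band][sl], total_power))
            row.extend(
                [
                    total_power,
                    _spectral_entropy(raw_seg, rec.fs),
                    _hjorth_mobility(raw_seg),
                    _hjorth_complexity(raw_seg),
                    _skew(raw_seg),
                    _kurt(raw_seg),
                ]
            )
            values[w, col : col + 50] = row
        col += 50

    return FeatureMatrix(
        values,
        feature_ids,
        step_seconds=step_s,
        window_seconds=window_s,
        session_id=rec.session_id,
    )
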