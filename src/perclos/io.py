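"""Readers, writers, session bookkeeping, and the end-to-end pipeline.

All on-disk formats are plain text: PERCLOS and feature matrices as CSV on
the shared window grid (first column ``time_s``), models and reports as
JSON, recordings as a CSV sample matrix with a JSON sidecar carrying the
sampling rate and channel names (EDF input is supported when ``mne`` is
installed).  Floats round-trip losslessly (shortest-repr formatting).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarkers import ConsensusReport, consensus
from .decoder import Posterior, bayes_filter, evaluate
from .exceptions import ConfigurationError, DomainError, PipelineError
from .features import FeatureMatrix, Recording, compute_perclos, extract_features
from .observation import (
    ObservationEntry,
    fit_observation_matrix,
    pool_entries,
    select_features,
)
from .state import PerclosSeries, StateModel, fit_state_model
from .synthetic import SyntheticSpec, generate_feature_sessions

__all__ = [
    "SessionSet",
    "split_sessions",
    "write_perclos", "read_perclos",
    "write_features", "read_features",
    "write_entries", "read_entries",
    "write_recording", "read_recording",
    "write_posterior",
    "load_config", "run_pipeline",
]


# ---------------------------------------------------------------------------
# Simple round-trip formats
# ---------------------------------------------------------------------------

def write_perclos(series: PerclosSeries, path) -> None:
    pd.DataFrame({"time_s": series.times, "perclos": series.values}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_perclos(path, window_seconds: float = 60.0, session_id=None) -> PerclosSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    t = df["time_s"].to_numpy(dtype=float)
    step = float(t[1] - t[0]) if t.size > 1 else 30.0
    return PerclosSeries(
        df["perclos"].to_numpy(dtype=float),
        step_seconds=step,
        window_seconds=window_seconds,
        session_id=session_id,
    )


def write_features(fm: FeatureMatrix, path) -> None:
    df = pd.DataFrame(fm.values, columns=fm.feature_ids)
    df.insert(0, "time_s", fm.times)
    df.to_csv(path, index=False, float_format="%.17g")


def read_features(path, window_seconds: float = 60.0, session_id=None) -> FeatureMatrix:
    df = pd.read_csv(path, float_precision="round_trip")
    t = df.pop("time_s").to_numpy(dtype=float)
    step = float(t[1] - t[0]) if t.size > 1 else 30.0
    return FeatureMatrix(
        df.to_numpy(dtype=float),
        list(df.columns),
        step_seconds=step,
        window_seconds=window_seconds,
        session_id=session_id,
    )


_ENTRY_COLS = [
    "feature_id", "alpha", "beta", "sigma2", "p_slope", "r2",
    "resid_acf1", "transform", "selected", "n", "session_id",
]


def write_entries(entries: Sequence[ObservationEntry], path) -> None:
    pd.DataFrame([e.to_dict() for e in entries])[_ENTRY_COLS].to_csv(
        path, index=False, float_format="%.17g"
    )


def read_entries(path) -> list[ObservationEntry]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        sid = d["session_id"]
        if pd.isna(sid):
            sid = None
        out.append(
            ObservationEntry(
                feature_id=str(d["feature_id"]), alpha=float(d["alpha"]),
                beta=float(d["beta"]), sigma2=float(d["sigma2"]),
                p_slope=float(d["p_slope"]), r2=float(d["r2"]),
                resid_acf1=float(d["resid_acf1"]), transform=str(d["transform"]),
                selected=bool(d["selected"]), n=int(d["n"]), session_id=sid,
            )
        )
    return out


def write_recording(rec: Recording, csv_path, sidecar_path, eyelid_path=None) -> None:
    pd.DataFrame(rec.samples.T, columns=rec.channel_names).to_csv(
        csv_path, index=False, float_format="%.17g"
    )
    Path(sidecar_path).write_text(
        json.dumps({"fs": rec.fs, "channel_names": list(rec.channel_names)}, indent=2)
        + "\n"
    )
    if eyelid_path is not None and rec.eyelid is not None:
        pd.DataFrame({"aperture": rec.eyelid}).to_csv(
            eyelid_path, index=False, float_format="%.17g"
        )


def read_recording(
    path, sidecar=None, eyelid_path=None, session_id=None
) -> Recording:
    """Read a recording from CSV + JSON sidecar, or from EDF (needs mne)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        rec = _read_edf(path, session_id=session_id)
    else:
        if sidecar is None:
            raise ConfigurationError("CSV recordings need a JSON sidecar (fs, channels)")
        meta = json.loads(Path(sidecar).read_text())
        df = pd.read_csv(path, float_precision="round_trip")
        names = meta.get("channel_names", list(df.columns))
        rec = Recording(
            samples=df[names].to_numpy(dtype=float).T,
            fs=float(meta["fs"]),
            channel_names=names,
            session_id=session_id,
        )
    if eyelid_path is not None:
        rec.eyelid = pd.read_csv(eyelid_path, float_precision="round_trip")[
            "aperture"
        ].to_numpy(dtype=float)
        if rec.eyelid.shape != (rec.n_samples,):
            raise ConfigurationError("eyelid trace must align with samples")
    return rec


def _read_edf(path, session_id=None) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ConfigurationError(
            "reading EDF requires the optional 'mne' dependency"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        samples=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        session_id=session_id,
    )


def write_posterior(post: Posterior, path, step_seconds: float = 30.0) -> None:
    pd.DataFrame(
        {
            "time_s": np.arange(len(post)) * step_seconds,
            "mean": post.mean,
            "ci_low": post.ci_low,
            "ci_high": post.ci_high,
        }
    ).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Session bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionSet:
    """A disjoint train/test split of session ids."""

    train_ids: tuple
    test_ids: tuple

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ConfigurationError("train and test ids overlap")
        all_ids = list(self.train_ids) + list(self.test_ids)
        if len(set(all_ids)) != len(all_ids):
            raise ConfigurationError("duplicate session ids")


def split_sessions(
    all_ids: Sequence,
    test_ids: Sequence | None = (6, 9, 15),
    n_test: int | None = None,
    seed: int | None = None,
) -> SessionSet:
    """Deterministic split honoring explicit ``test_ids``; optionally a
    seeded random split of ``n_test`` sessions instead."""
    all_ids = list(all_ids)
    if len(set(all_ids)) != len(all_ids):
        raise ConfigurationError("session ids must be unique")
    if n_test is not None:
        if seed is None:
            raise ConfigurationError("a random split needs a seed")
        if not (0 < n_test < len(all_ids)):
            raise ConfigurationError("n_test must leave a non-empty training set")
        rng = np.random.default_rng(seed)
        test = sorted(rng.choice(len(all_ids), size=n_test, replace=False))
        test_ids = [all_ids[i] for i in test]
    else:
        test_ids = list(test_ids or [])
        unknown = [t for t in test_ids if t not in all_ids]
        if unknown:
            raise ConfigurationError(f"unknown test ids {unknown}")
    train = [s for s in all_ids if s not in set(test_ids)]
    if not train:
        raise ConfigurationError("empty training set")
    return SessionSet(train_ids=tuple(train), test_ids=tuple(test_ids))


# ---------------------------------------------------------------------------
# Configuration and pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 0,
    "window_seconds": 60.0,
    "step_seconds": 30.0,
    "threshold": 0.05,
    "selection_method": "none",
    "transform_search": False,
    "grid_size": 201,
    "interval": "central",
    "decode_mode": "pooled",       # or "calibrated"
    "calibration_fraction": 0.3,
    "consensus_scope": "train",    # or "all"
    "test_ids": [6, 9, 15],
    "out_dir": None,
}


def load_config(path) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    user = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(user) - set(DEFAULT_CONFIG) - {"synthetic", "sessions"}
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(user)
    return cfg


def _load_sessions(cfg) -> dict:
    """Stage 1: obtain {session_id: (PerclosSeries, FeatureMatrix)}."""
    data = {}
    if "synthetic" in cfg:
        syn = dict(cfg["synthetic"] or {})
        spec = SyntheticSpec(
            n_sessions=int(syn.get("n_sessions", 18)),
            steps_per_session=int(syn.get("steps_per_session", 59)),
            seed=int(cfg["seed"]),
        )
        for s in generate_feature_sessions(spec):
            data[s.perclos.session_id] = (s.perclos, s.features)
    elif "sessions" in cfg:
        for item in cfg["sessions"]:
            sid = item["session_id"]
            if "recording" in item:
                rec = read_recording(
                    item["recording"], sidecar=item.get("sidecar"),
                    eyelid_path=item.get("eyelid"), session_id=sid,
                )
                if rec.eyelid is None:
                    raise ConfigurationError(f"session {sid}: no eyelid trace")
                x = compute_perclos(
                    rec.eyelid, rec.fs,
                    window_s=cfg["window_seconds"], step_s=cfg["step_seconds"],
                    session_id=sid,
                )
                fm = extract_features(
                    rec, window_s=cfg["window_seconds"], step_s=cfg["step_seconds"]
                )
            else:
                x = read_perclos(
                    item["perclos"], window_seconds=cfg["window_seconds"], session_id=sid
                )
                fm = read_features(
                    item["features"], window_seconds=cfg["window_seconds"], session_id=sid
                )
            data[sid] = (x, fm)
    else:
        raise ConfigurationError("config needs either a 'synthetic' or 'sessions' block")
    # structural validation before any fitting
    ids = {sid: tuple(fm.feature_ids) for sid, (_, fm) in data.items()}
    ref = next(iter(ids.values()))
    for sid, cols in ids.items():
        if cols != ref:
            raise ConfigurationError(f"session {sid}: feature columns differ")
        x, fm = data[sid]
        if len(x) != len(fm):
            raise ConfigurationError(f"session {sid}: PERCLOS/feature grid mismatch")
    return data


def run_pipeline(config: Mapping | str | Path) -> dict:
    """Run the full encoder-decoder pipeline from a configuration.

    Stages: load/generate sessions -> train/test split -> state-model fit
    on the concatenated training PERCLOS -> per-session encoder fits ->
    slope-test selection -> cross-session consensus -> decoding of the test
    sessions -> evaluation.  Artifacts are returned as a dict and, when
    ``out_dir`` is set, written to disk together with a manifest.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else {
        **DEFAULT_CONFIG, **dict(config)
    }

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

    data = stage("load", _load_sessions, cfg)
    split = stage(
        "split", split_sessions, list(data.keys()), test_ids=cfg["test_ids"]
    )
    train_x = [data[sid][0] for sid in split.train_ids]
    state_fit = stage("fit-state", fit_state_model, train_x)

    def _fit_all():
        tables = {}
        for sid, (x, fm) in data.items():
            entries = fit_observation_matrix(
                fm, x, transform_search=cfg["transform_search"]
            )
            select_features(
                entries, threshold=cfg["threshold"], method=cfg["selection_method"]
            )
            tables[sid] = entries
        return tables

    tables = stage("fit-obs", _fit_all)
    scope = (
        list(split.train_ids) if cfg["consensus_scope"] == "train" else list(data.keys())
    )
    report = stage("consensus", consensus, tables, scope=scope)
    if not report.consensus_features:
        raise PipelineError("consensus", "no feature survived in every scope session")

    series_by_session = {sid: data[sid][0] for sid in data}
    decodes, metrics = {}, {}

    def _decode_all():
        for sid in split.test_ids:
            x, fm = data[sid]
            if cfg["decode_mode"] == "pooled":
                entries = pool_entries(
                    tables, report.consensus_features, series_by_session,
                    scope=list(split.train_ids),
                )
            elif cfg["decode_mode"] == "calibrated":
                k = max(3, int(round(cfg["calibration_fraction"] * len(x))))
                prefix_x = PerclosSeries(
                    x.values[:k], x.step_seconds, x.window_seconds, x.session_id
                )
                prefix_fm = FeatureMatrix(
                    fm.values[:k], fm.feature_ids, fm.step_seconds,
                    fm.window_seconds, fm.session_id,
                )
                entries = [
                    e for e in fit_observation_matrix(
                        prefix_fm.select(report.consensus_features), prefix_x
                    )
                ]
            else:
                raise ConfigurationError(f"unknown decode_mode {cfg['decode_mode']!r}")
            post = bayes_filter(
                fm, entries, state_fit.model,
                grid_size=cfg["grid_size"], interval=cfg["interval"],
            )
            decodes[sid] = post
            metrics[sid] = evaluate(post, x)

    stage("decode", _decode_all)

    artifacts = {
        "config": cfg,
        "split": split,
        "state_fit": state_fit,
        "entry_tables": tables,
        "consensus": report,
        "decodes": decodes,
        "metrics": metrics,
    }
    if cfg.get("out_dir"):
        stage("write", _write_artifacts, cfg, artifacts, data)
    return artifacts


def _write_artifacts(cfg, artifacts, data) -> None:
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    artifacts["state_fit"].model.to_json(out / "state_model.json")
    for sid, entries in artifacts["entry_tables"].items():
        write_entries(entries, out / f"entries_{sid}.csv")
    artifacts["consensus"].to_json(out / "consensus.json")
    for sid, post in artifacts["decodes"].items():
        write_posterior(post, out / f"decode_{sid}.csv", step_seconds=cfg["step_seconds"])
    (out / "metrics.json").write_text(
        json.dumps(artifacts["metrics"], indent=2, default=float) + "\n"
    )
    manifest = {
        "package_version": __version__,
        "seed": cfg["seed"],
        "parameters": {
            k: cfg[k]
            for k in (
                "window_seconds", "step_seconds", "threshold", "selection_method",
                "transform_search", "grid_size", "interval", "decode_mode",
                "consensus_scope", "test_ids",
            )
        },
        "sessions": {
            str(sid): {"n_steps": len(x), "n_features": fm.n_features}
            for sid, (x, fm) in data.items()
        },
        "train_ids": list(artifacts["split"].train_ids),
        "test_ids": list(artifacts["split"].test_ids),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
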