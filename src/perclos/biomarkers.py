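"""Cross-session biomarker consensus and slope-sign summaries.

A feature qualifies as a drowsiness biomarker when its encoder slope is
statistically significant in every session considered.  Grouping consensus
features by catalog name (ignoring the channel) yields family roll-ups such
as "theta_power: 7 channels".  Slope signs summarize the push-pull
structure: families whose power rises with drowsiness (theta, delta) push,
while families that fall (alpha skewness, delta Hjorth mobility) pull.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ConfigurationError, DomainError
from .features import feature_family
from .observation import ObservationEntry

__all__ = ["ConsensusReport", "consensus", "sign_summary"]


@dataclass
class ConsensusReport:
    """Features significant in every session of the scope, with summaries."""

    consensus_features: list[str]
    per_feature_sign_fraction: dict[str, float]
    family_rollup: dict[str, int]
    scope: list

    def __post_init__(self):
        for f, v in self.per_feature_sign_fraction.items():
            if np.isfinite(v) and not (0.0 <= v <= 1.0):
                raise DomainError(f"sign fraction for {f} outside [0, 1]")

    @property
    def size(self) -> int:
        return len(self.consensus_features)

    def to_dict(self) -> dict:
        return {
            "scope": list(self.scope),
            "consensus_features": self.consensus_features,
            "size": self.size,
            "per_feature_sign_fraction": self.per_feature_sign_fraction,
            "family_rollup": self.family_rollup,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _check_scope(selections: Mapping, scope) -> list:
    scope = list(selections.keys()) if scope is None else list(scope)
    if not scope:
        raise DomainError("consensus scope is empty")
    missing = [s for s in scope if s not in selections]
    if missing:
        raise ConfigurationError(f"sessions {missing} not present in selections")
    return scope


def _by_feature(entries: Sequence[ObservationEntry]) -> dict[str, ObservationEntry]:
    return {e.feature_id: e for e in entries}


def consensus(
    selections: Mapping[object, Sequence[ObservationEntry]],
    scope: Sequence | None = None,
) -> ConsensusReport:
    """Features selected in *all* sessions of ``scope``.

    ``selections`` maps session id to that session's fitted entry table
    (with ``selected`` flags set).  All sessions must share the same feature
    id set.  The report also carries, per consensus feature, the fraction of
    scope sessions with a positive slope, and counts by feature family.
    """
    scope = _check_scope(selections, scope)
    tables = {s: _by_feature(selections[s]) for s in scope}
    ref = set(tables[scope[0]])
    for s in scope[1:]:
        if set(tables[s]) != ref:
            raise ConfigurationError(f"session {s!r} has a mismatched feature set")
    cons = sorted(
        f for f in ref if all(tables[s][f].selected for s in scope)
    )
    sign_frac = {
        f: float(np.mean([tables[s][f].alpha > 0 for s in scope])) for f in cons
    }
    rollup = dict(Counter(feature_family(f) for f in cons))
    return ConsensusReport(
        consensus_features=cons,
        per_feature_sign_fraction=sign_frac,
        family_rollup=rollup,
        scope=scope,
    )


def sign_summary(
    selections: Mapping[object, Sequence[ObservationEntry]],
    features: Sequence[str],
    scope: Sequence | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Positive-slope fractions per feature and per family.

    For each feature, the fraction of scope sessions -- among those where
    the feature is significant -- whose fitted slope is positive; NaN when
    the feature is significant nowhere.  The family summary averages over
    the (feature, session) pairs in each family.
    """
    scope = _check_scope(selections, scope)
    tables = {s: _by_feature(selections[s]) for s in scope}
    for f in features:
        for s in scope:
            if f not in tables[s]:
                raise ConfigurationError(f"feature {f!r} missing in session {s!r}")
    per_feature: dict[str, float] = {}
    fam_pos: Counter = Counter()
    fam_tot: Counter = Counter()
    for f in features:
        signs = [
            tables[s][f].alpha > 0 for s in scope if tables[s][f].selected
        ]
        per_feature[f] = float(np.mean(signs)) if signs else float("nan")
        fam = feature_family(f)
        fam_pos[fam] += sum(signs)
        fam_tot[fam] += len(signs)
    per_family = {
        fam: (fam_pos[fam] / fam_tot[fam]) if fam_tot[fam] else float("nan")
        for fam in fam_tot
    }
    return per_feature, per_family
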