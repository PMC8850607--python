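"""Find drowsiness biomarkers: features significant in every training
session, summarized by family and slope sign (the push-pull structure).
"""

from perclos import (
    SyntheticSpec,
    consensus,
    fit_observation_matrix,
    generate_feature_sessions,
    select_features,
    sign_summary,
    split_sessions,
)

spec = SyntheticSpec(n_sessions=18, seed=0)
sessions = generate_feature_sessions(spec)
split = split_sessions([s.perclos.session_id for s in sessions], test_ids=[6, 9, 15])

tables = {}
for s in sessions:
    entries = fit_observation_matrix(s.features, s.perclos)
    select_features(entries)
    tables[s.perclos.session_id] = entries

report = consensus(tables, scope=list(split.train_ids))
print(f"{report.size} features significant in all {len(split.train_ids)} "
      "training sessions; by family:")
for fam, n in sorted(report.family_rollup.items(), key=lambda kv: -kv[1]):
    print(f"  {fam}: {n}")

_, per_family = sign_summary(tables, report.consensus_features,
                             scope=list(split.train_ids))
print("positive-slope fraction per family (push > 0.5 > pull):")
for fam, frac in sorted(per_family.items(), key=lambda kv: -kv[1]):
    print(f"  {fam}: {frac:.2f}")
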