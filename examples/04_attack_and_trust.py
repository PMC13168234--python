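"""Attack a record and gate inferences with the trust score.

Trains the intrusion detector on a synthetic benchmark, injects a replay
attack into a fresh record, and shows the per-window trust decision
T = 1 - p_attack with threshold tau = 0.5.
"""

from beatguard import (
    AttackScenario,
    RhythmSpec,
    attack_probability,
    inject_attack,
    synth_record,
    train_ids,
    trust_assess,
)
from beatguard.ids import build_attack_benchmark, record_window_features

bench = build_attack_benchmark(n_records=8, intensity=0.8, seed=0)
detector = train_ids(bench["clean"], bench["attacked"])
print(f"trained on {len(bench['clean'])} clean / "
      f"{len(bench['attacked'])} attacked windows")

record, _ = synth_record(RhythmSpec(duration=60.0, seed=99))
scenario = AttackScenario(type="replay", intensity=0.8,
                          start=20.0, end=40.0, seed=5)
attacked, mask = inject_attack(record, scenario)

windows = record_window_features(attacked)
p_attack = attack_probability(detector, windows)
flags = [trust_assess(float(p), tau=0.5) for p in p_attack]

n_untrusted = sum(not f.trusted for f in flags)
print(f"windows: {len(flags)}, flagged untrusted: {n_untrusted}")
mid = len(flags) // 2  # inside the attacked span
print(f"mid-record window: p_attack={flags[mid].p_attack:.2f} "
      f"trust={flags[mid].trust:.2f} -> {flags[mid].flag}")
print(f"first window:      p_attack={flags[0].p_attack:.2f} "
      f"trust={flags[0].trust:.2f} -> {flags[0].flag}")
# Windows inside the replayed span should be flagged untrusted; clean
# lead-in windows keep a high trust score.
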