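"""Replay the intervention engine over a simulated desk-work session.

While the wearer sits, sustained poor posture (>= 5 s) triggers a belt
vibration; a continuous sit/lie streak past the sedentary limit triggers
a walk-prompt notification. Each cause has a refractory period.
"""

import numpy as np

import beltsense as bs

rng = np.random.default_rng(1)
cfg = bs.EngineConfig(posture_debounce=5.0, sedentary_limit=10.0, refractory=60.0)

# 30 minutes at 1 Hz: mostly sitting with 20 s postural episodes
acts, posts = [], []
while len(acts) < 1800:
    if rng.random() < 0.1:
        acts += ["walk"] * 30
        posts += [None] * 30
    else:
        acts += ["sit"] * 20
        posts += ["poor" if rng.random() < 0.4 else "good"] * 20
acts, posts = acts[:1800], posts[:1800]

events, counts = bs.run(acts, posts, list(range(1800)), cfg)
print(f"session: 30 min, {acts.count('sit')} s sitting")
print(f"events emitted: {counts}")
for e in events[:5]:
    print(f"  t={e.timestamp:6.0f}s  {e.channel:12s} {e.cause:20s} {e.pattern}")
print("  ...")
gaps = np.diff([e.timestamp for e in events if e.cause == "poor_posture"])
if len(gaps):
    print(f"minimum gap between posture vibrations: {gaps.min():.0f} s "
          f"(refractory {cfg.refractory:.0f} s)")
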