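"""Assess sitting posture from attitude angles and score a session.

The attitude angles are computed from the gravity direction: an upright
sitter has the lateral tilt psi near 0 and the front/rear angle phi in
the 80-90 degree band; a slumped sitter violates the phi policy.
"""

import numpy as np

import beltsense as bs

for name, acc in [("upright", (1.0, 0.0, 0.05)),
                  ("slumped forward", (0.8, 0.0, 0.6)),
                  ("leaning sideways", (0.9, 0.45, 0.05))]:
    a = bs.attitude_angles(np.array(acc))
    verdict = bs.assess_posture(a)
    print(f"{name:17s} theta={a.theta:6.1f}  psi={a.psi:6.1f}  "
          f"phi={a.phi:5.1f}  -> {verdict}")

# a 10-minute block at 1 assessment/s, 30% of it slumped
rng = np.random.default_rng(0)
assessments = ["poor" if rng.random() < 0.3 else "good" for _ in range(600)]
stats = bs.poor_posture_rate(assessments, duration=600.0)
print(f"\npoor posture rate over 10 min: {stats.poor_posture_rate:.2f}")

# improvement between a no-intervention and an intervention block
print(f"improvement rate 0.50 -> 0.076: "
      f"{bs.improvement_rate(0.5, 0.076):.1f} % reduction of poor posture")
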