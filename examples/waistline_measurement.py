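"""Estimate belt insertion depth and waistline from a magnetometer trace.

Each 0.6 cm sawtooth tooth the buckle blade crosses leaves one peak in
the magnetometer trace; counting peaks quantizes the insertion depth to
the tooth pitch, so the error is bounded by 0.6 cm.
"""

import numpy as np

import beltsense as bs

belt = bs.BeltConfig(length_cm=110.0, pitch_cm=0.6, offset_cm=5.0)

truth = 30.3  # cm, mid-tooth on purpose
trace = bs.generate_mag_trace(truth, noise_sd=1.0, seed=2)  # 10% noise
est, err = bs.estimate_waistline(trace, belt, truth_insertion_cm=truth)

print(f"true insertion: {truth} cm")
print(f"counted peaks:  {est.peak_count} (one per 0.6 cm tooth)")
print(f"estimate:       {est.insertion_cm:.1f} cm "
      f"(absolute error {err['absolute_error_cm']:.2f} cm <= one pitch)")
print(f"waistline:      {est.waistline_cm:.1f} cm "
      f"(belt {belt.length_cm} - insertion - offset {belt.offset_cm})")

# resolution over many random depths: mean error well under half a pitch
rng = np.random.default_rng(0)
errs = []
for _ in range(100):
    depth = float(rng.uniform(5, 31))
    phase = float(rng.uniform(0, 0.6))
    tr = bs.generate_mag_trace(depth, tooth_phase_cm=phase)
    _e, e = bs.estimate_waistline(tr, belt, truth_insertion_cm=depth)
    errs.append(e["absolute_error_cm"])
print(f"\nmean |error| over 100 random depths: {np.mean(errs):.2f} cm "
      f"(max {np.max(errs):.2f} cm, resolution bound 0.6 cm)")
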