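"""Extract 561-element feature vectors from 50%-overlapping 128-sample windows.

Shows the window grid, the frozen feature enumeration, and train-set
standardization with frozen parameters.
"""

import beltsense as bs

rec = bs.generate_activity("run", duration=10.0, seed=7)
sigs = bs.derive_signals(rec)

starts = bs.make_windows(len(rec))
print(f"{len(rec)} samples -> {len(starts)} windows "
      f"(starts {starts[:4]}..., step 64)")

windows = bs.extract_all(sigs)
w = windows[0]
print(f"each window yields {len(w.features)} features; the first five:")
for name, value in zip(bs.feature_names()[:5], w.features[:5]):
    print(f"  {name:22s} = {value: .4f}")

params = bs.fit_standardizer(windows)
z = bs.apply_standardizer(params, windows[3])
print(f"\nstandardized window 3: mean {z.features.mean():+.3f}, "
      f"std {z.features.std():.3f} (near 0/1 by construction on train data)")
print(f"degenerate (constant) features given unit scale: {len(params.degenerate)}")
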