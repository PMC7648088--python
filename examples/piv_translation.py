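"""Recover a known flow with iterative PIV.

A speckle texture is advected by a pure (5, -3) px translation; the
64/32/16 px correlation cascade with normalized-median-test validation
should recover that displacement everywhere it is measurable.
"""

import numpy as np

import fibroswarm as fs

flow = fs.FlowSpec("translation", dx=5.0, dy=-3.0)
frame_a, frame_b = fs.advected_pair(flow, shape=(512, 512), seed=3)

field = fs.run_piv(frame_a, frame_b, fs.PIVConfig(window_sizes=(64, 32, 16)))
summary = fs.field_summary(field, dt=30.0)

err = np.hypot(field.u - 5.0, field.v + 3.0)
print(f"grid: {field.shape[0]} x {field.shape[1]} vectors, "
      f"{field.valid.mean() * 100:.1f}% valid")
print(f"mean (u, v) over valid vectors: "
      f"({field.u[field.valid].mean():.3f}, {field.v[field.valid].mean():.3f}) px  "
      f"[truth (5, -3)]")
print(f"max error over valid vectors: {err[field.valid].max():.3f} px")
print(f"mean speed at 30 min/frame-pair: {summary.mean_speed:.4f} px/min")
print("\nInvalid vectors sit where the pattern was advected out of the frame; "
      "the median test keeps locally inconsistent vectors out of the statistics.")
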