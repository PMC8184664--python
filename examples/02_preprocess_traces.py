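"""Preprocess fluorescence traces: trailing-average smoothing and F/F0.

Uses a tiny hand-checkable matrix so every number can be verified mentally.
"""

import numpy as np

import isletconn as ic

t = ic.TraceMatrix(
    cell_ids=["cell_a", "cell_b"],
    frame_times_s=np.arange(4) * 2.0,
    values=np.array([[1.0, 2.0], [2.0, 2.0], [3.0, 4.0], [4.0, 6.0]]),
)

smoothed = ic.smooth_retrospective(t, window=2)
print("raw cell_a:     ", t.values[:, 0])
print("smoothed (w=2): ", smoothed.values[:, 0])  # trailing mean -> 1, 1.5, 2.5, 3.5

norm = ic.normalise_f0(smoothed, f0_frames=2)
print("F/F0 cell_a:    ", norm.values[:, 0])
print("baseline means ->", norm.values[:2].mean(axis=0))  # exactly 1 per cell

# Each sample is replaced by the mean of the trailing window (causal, no
# look-ahead), then divided by that cell's baseline F0 (mean of the first
# f0_frames samples), making traces dimensionless and comparable.
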