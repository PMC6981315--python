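"""Compute the three kinematic indices for one tracked trajectory.

Builds a small pixel-coordinate tracking CSV, reads it back with an
explicit pixels-per-cm calibration, and prints path length (L, cm),
average movement (A, cm/frame) and the extreme-movement count (J).
"""

import tempfile
from pathlib import Path

import lapmotion as lm

# steady 6 px steps in x with an occasional 15 px excursion in y:
# at 10 px/cm most steps are 0.6 cm and the excursions exceed 1.0 cm
ys, y = [], 200
for i in range(30):
    ys.append(y)
    y += 15 if i % 10 == 9 else 1
csv_text = "frame,x,y\n" + "\n".join(
    f"{i},{100 + 6 * i},{ys[i]}" for i in range(30)
)
path = Path(tempfile.mkdtemp()) / "track.csv"
path.write_text(csv_text, encoding="utf-8")

# 10 px/cm: the 1.0 cm extreme-step threshold depends on this being right
traj = lm.read_trajectory_csv(path, lm.Calibration(pixels_per_cm=10, frame_rate_hz=30))
indices = lm.compute_indices(traj)

print(f"L = {indices.path_length_cm:.2f} cm total tip travel")
print(f"A = {indices.avg_move_cm_per_frame:.3f} cm per frame step")
print(f"J = {indices.extreme_moves} steps longer than 1.0 cm")
# Shorter paths, slower average movement and fewer extreme steps are the
# economical, expert-like end of each index.
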