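"""Quantify joint motion from a synthetic gait video (ground-truth track).

Derives joint-height series, splits the gait cycle into falling/lifting
hind-limb phases, detects stride peaks and measures per-phase limb travel.
With a trained model the same analysis runs on tracked landmarks
(``ratpose.track_video``).
"""

import ratpose as rp

gait = rp.GaitConfig(period_frames=24, duty_factor=0.6)
frames, traj = rp.generate_video(24 * 5, None, gait=gait, seed=3)
print(f"video: {len(frames)} frames at {traj.frame_rate:.0f} frames/s "
      f"({gait.period_frames}-frame stride period, 5 cycles)")

summary = rp.summarize_gait(traj)
print(f"\nstride peaks at frames {[int(i) for i in summary.stride_peaks]}")
print(f"estimated stride period: {summary.period_frames:.1f} frames "
      f"({traj.frame_rate / summary.period_frames:.1f} strides/s)")

n_fall = sum(1 for l in summary.phase_labels if l == "falling")
print(f"phase split: {n_fall} falling / {len(traj) - n_fall} lifting frames "
      f"(duty factor {gait.duty_factor:.1f}: stance frames count as falling)")

d = summary.displacement_by_phase
print("\nhorizontal travel per phase (px):")
print(f"  falling: fore {d['falling']['fore']:6.1f}  hind {d['falling']['hind']:6.1f}")
print(f"  lifting: fore {d['lifting']['fore']:6.1f}  hind {d['lifting']['hind']:6.1f}")
print("\nthe hind limb out-travels the forelimb while it falls and plants,")
print("matching the configured longer hind-limb stride.")
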