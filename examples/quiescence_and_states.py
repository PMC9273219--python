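"""Global quiescence bouts and state-space organization of an aged trial.

Classifies per-frame quiescence (neurons below 1/3 of the trial's high
activity reference; globally quiescent when >70% of neurons are quiet),
extracts a 700-frame quiescence-free segment, and quantifies trajectory
smoothness as the mass of angular direction changes below 30 degrees.
Aged trials spend several percent of the trial in sleep-like global
quiescence and trace erratic PCA trajectories (low small-angle mass).
"""

import numpy as np

import wormdyn as w

traces, truth = w.generate_population(w.age_preset(9, seed=14))
dff = w.normalize_dff(traces)

prof = w.quiescence_profile(dff)
print(f"planted bout frames : {truth.time_in_quiescence * 100:.1f}% of trial")
print(f"measured quiescence : {prof.time_in_quiescence * 100:.1f}% of trial")

segment = w.extract_subset(traces, prof, segment_frames=700,
                           want_quiescence=False)
print(f"quiescence-free 700-frame segment: "
      f"{'found ' + segment.trial_id if segment else 'none'}")

traj = w.run_pca(dff, k=3)
angles = w.angular_changes(traj, traces.sampling_rate, window_s=3.0)
print(f"variance explained by PC1-3: "
      f"{traj.explained_var[:3].sum() * 100:.0f}%")
print(f"angular changes below 30 deg: "
      f"{w.low_angle_mass(angles) * 100:.0f}% "
      f"(smooth young trials sit above 55%)")

rm = w.recurrence_map(dff)
print(f"recurrence map: {rm.dist.shape[0]}x{rm.dist.shape[1]}, "
      f"median normalized distance {np.median(rm.dist):.2f}")
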