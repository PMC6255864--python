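"""Rotational dynamics of the weakly held lattice trimer.

Idealizes a two-state height telegraph, measures rotation times and
directions from a simulated line-scan kymograph, and converts the dwell
and rotation times into a free-energy barrier and rotational velocity.
"""
import numpy as np

import hsafm as H

# --- height-spectroscopy telegraph on one rotor protomer ---
cfg = H.TelegraphConfig(seed=5, jitter=(0.0, 0.0), transition_duration=0.002)
trace = H.simulate_telegraph_trace(cfg, 20.0)
ideal = H.idealize_two_state(trace)   # boxcar 30 + hysteresis
stats = H.dwell_statistics(ideal)
print(f"idealized levels       : {ideal.levels[1]:.2f} / {ideal.levels[0]:.2f} nm "
      "(configured 2.00 / 1.72)")
print(f"state dwells           : {stats.mean * 1e3:.1f} ± {stats.sem * 1e3:.2f} ms "
      f"(s.e.m., n = {stats.n}; generator mean 26 ms)")

# --- line-scan kymograph with known rotation schedule ---
rng = np.random.default_rng(2)
schedule, angle, t = [], 0.0, 0.0
while t < 2.0:
    dwell = float(rng.exponential(0.035))
    schedule.append((angle, dwell))
    angle += 60.0 * float(rng.choice([-1.0, 1.0]))
    t += dwell + 0.018
kym = H.simulate_rotation_kymograph(schedule, noise=H.NoiseModel(0.05), seed=2)
trans = H.measure_rotation_transitions(kym)
resolved = trans.table[trans.table["resolvable"]]
gt = kym.transitions["direction"].tolist()
got = trans.table["direction"].tolist()
agree = np.mean([a == b for a, b in zip(got, gt)])
print(f"\nkymograph transitions  : {len(resolved)} resolved, "
      f"mean rotation {trans.mean_duration * 1e3:.1f} ms (scheduled 18 ms)")
print(f"direction labels       : {100 * agree:.0f}% agree with the schedule "
      f"({gt.count('cw')} cw / {gt.count('ccw')} ccw)")

# --- energetics from the two measured timescales ---
st = H.rotation_energetics(tau_state=0.035, tau_rotation=0.018)
print(f"\nbarrier dG             : {st.delta_g:.3f} kBT (~0.7 at one decimal)")
print(f"rotational velocity    : {st.angular_velocity:.0f} deg/s = {st.rpm:.0f} rpm")
print("each 60-deg hop takes ~18 ms, so while rotating the trimer turns at "
      "~3300 deg/s,\nyet it waits ~35 ms between hops -- a barrier of well "
      "under 1 kBT.")
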