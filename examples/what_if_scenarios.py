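"""What-if studies: which physiological change buys the most time?

Re-solves a world-class miler's optimal 1500 m with one parameter changed
at a time — more anaerobic store, higher VO2, more force, quicker or
better-sustained aerobic kinetics — and reports the finishing-time
deltas.  Mirrors the classic coaching question of where training effort
pays off most.
"""

from paceopt import build_track, preset_athletes
from paceopt.scenario import kinetics_scenario, perturb_and_compare

track = build_track(1500)
athlete = preset_athletes()["miler_m"]

experiments = [
    ("anaerobic store e0 +5%", {"e0": 1.05}),
    ("VO2 (peak and final) +5%", {"sigma_max": 1.05, "sigma_f": 1.05}),
    ("max force f_M +10%", {"f_M": 1.10}),
]
print(f"baseline: optimal 1500 m")
for label, changes in experiments:
    cmp_res = perturb_and_compare(athlete, changes, track, n_nodes=90)
    print(f"  {label:28s} delta_T = {cmp_res.delta_T:+.2f} s")

for mode, label in [
    ("faster_kinetics", "quicker VO2 kinetics"),
    ("flatter_decline", "smaller end-race VO2 decline"),
]:
    cmp_res = kinetics_scenario(athlete, mode, track, delta=0.05, n_nodes=90)
    print(f"  {label:28s} delta_T = {cmp_res.delta_T:+.2f} s")

print("\nNegative deltas are improvements. Energy-side gains (anaerobic "
      "store, VO2) dominate force-side gains for middle-distance racing.")
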