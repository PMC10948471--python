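"""Parameter recovery from a synthetic 10 Hz tracking-feed trace.

Generates a noisy instantaneous-velocity trace from known parameters (the
kind of data an in-stadium athlete tracking system broadcasts), then
recovers the anaerobic store and friction coefficient by fitting the
optimal-race model back to the trace.  This is the self-contained check
that identification works when the data-generating model is known.
"""

from paceopt import build_track, generate_trace, preset_athletes
from paceopt.identify import ObservedRace, SearchSpace, identify_parameters

track = build_track(1500)
truth = preset_athletes()["miler_m"]

trace = generate_trace(truth, track, rate=10.0, noise_sd=0.08, seed=7, n_nodes=60)
print(f"synthetic trace: {len(trace.times)} samples at 10 Hz, "
      f"noise sd 0.08 m/s, race time {trace.metadata['T']:.2f} s")

obs = ObservedRace(event_distance=1500.0, track=track, trace=trace)
space = SearchSpace.around(truth, 0.5, ["e0", "tau"])
result = identify_parameters(obs, space, swarm_size=8, iterations=6, seed=5,
                             n_nodes=60, polish_evals=80)

for name in ("e0", "tau"):
    got = getattr(result.best_params, name)
    want = getattr(truth, name)
    print(f"{name}: recovered {got:.1f}, truth {want:.1f} "
          f"({100 * abs(got - want) / want:.1f}% off)")
print(f"objective (speed MSE) {result.objective:.4f} (m/s)^2 — close to the "
      f"injected noise variance {0.08**2:.4f}, i.e. the fit explains "
      "everything but the noise")
print("per-parameter sensitivity of the objective to a 1% perturbation:",
      {k: round(v, 5) for k, v in result.sensitivity.items()})
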