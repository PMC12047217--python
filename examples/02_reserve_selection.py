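"""Select a reserve system by simulated annealing and inspect the objective.

Uses the ~1,500-unit test-profile seascape: anneals one run, shows the
objective decomposition (cost + BLM x boundary + penalty), then repeats the
run 50 times to turn per-unit selection counts into 0-1000 irreplaceability
scores.
"""

import numpy as np

from reefplan import ScenarioConfig, SeascapeSpec, anneal, build_seascape, run_repeats

spec = SeascapeSpec.test_profile(rng_seed=11)
tess, features = build_seascape(spec)

scenario = ScenarioConfig(
    name="EV2",            # the 40% protection-target scenario
    target_fraction=0.40,
    blm=0.05,              # boundary length modifier: compactness pressure
    spf=100.0,             # species penalty factor: target enforcement
    n_runs=50,
    iterations_per_run=10_000,
    rng_seed=42,
)

solution = anneal(tess, features, scenario, seed=1)
obj = solution.objective
print(f"single run: {solution.n_selected} planning units selected")
print(f"  cost term:     {obj.cost_term:.1f}")
print(f"  boundary term: {obj.boundary_term:.0f} m exposed edge")
print(f"  penalty term:  {obj.penalty_term:.4f}")
print(f"  total:         {obj.total:.3f}  (= cost + BLM*boundary + penalty)")
for f in features.features:
    held = features.held(f.id, solution.selected)
    print(f"  {f.name:<9} held {held:5.2f} ha of {scenario.target_for(f):5.2f} ha target")

freq, best, summary = run_repeats(tess, features, scenario)
score = freq.score
print(f"\n{scenario.n_runs} repeated runs; best system: {summary['n_selected']} units, "
      f"total {summary['total']:.3f}")
print(f"irreplaceability scores: {np.sum(score >= 750)} units score >=750 "
      f"(always-selected core), {np.sum(score == 0)} never selected")
# Units scoring 750-1000 are selected in at least three quarters of the
# independent restarts: the irreplaceable backbone of the reserve design.
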