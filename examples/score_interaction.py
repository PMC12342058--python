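"""Score a social-interaction test from simulated arena trajectories.

Runs the two consecutive 3 min trials (empty cage, then caged novel
aggressor) for three attraction biases and prints zone times, the
social-interaction ratio SIR = t_f / t_e, and the resulting phenotype
call: SIR > 1.1 resilient, SIR < 0.9 susceptible, otherwise excluded
from sleep analyses.
"""

import somnostress as ss

arena = ss.ArenaSpec()
for label, bias in (("approach (resilient-like)", 0.25),
                    ("indifferent", 0.0),
                    ("avoidant (susceptible-like)", -0.25)):
    empty, target = ss.simulate_arena(arena, bias, seed=8)
    res = ss.score_interaction_test(empty, target)
    print(f"{label:<28} t_e={res['t_e']:6.1f} s  t_f={res['t_f']:6.1f} s  "
          f"SIR={res['sir']:5.2f}  -> {res['phenotype']}")
    print(f"{'':<28} distance: empty {res['distance_empty_cm']:.0f} cm, "
          f"target {res['distance_target_cm']:.0f} cm")

grid = ss.occupancy_grid(ss.simulate_arena(arena, 0.4, seed=8)[1], cell_cm=5.0)
print("\noccupancy (s per 5 cm cell, strong approach; cage at bottom center):")
for row in grid.T[::-1]:
    print(" ".join(f"{v:5.1f}" for v in row))
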