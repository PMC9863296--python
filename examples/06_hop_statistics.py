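"""Hopping analysis: gap-criterion replay, populations, hop geometries.

The simplified surface-hopping scheme switches states deterministically
when the gap to the adjacent lower state drops under 2 kcal/mol. This
example replays a designed crossing, builds population curves for an
ensemble with an exponential S1→S0 hop-time law, and reports the
geometry statistics at the hopping events.
"""

import numpy as np

from tirspec.hopping import apply_gap_criterion, hop_geometry_stats, mean_hop_time, population_curves
from tirspec.synth import PROXY_COORDS, designed_crossing_energies, generate_ensemble, pedalo_recipe

# 1) deterministic replay of a designed two-state crossing
energies = designed_crossing_energies(600, crossing_frame=137)
states = apply_gap_criterion(energies, active_state_0=1)
print(f"designed gap crossing at frame 137 → replayed hop at frame {np.argmax(states == 0)}")

# 2) population decay of an exponential-hop ensemble
recipe = pedalo_recipe(
    n_traj=50, duration=2000.0, initial_state=1,
    hop_schedule={(1, 0): ("exponential", 200.0)}, with_energies=False, seed=4,
)
ens, _, _ = generate_ensemble(recipe)
pops = population_curves(ens)
mean_t, se = mean_hop_time(ens, (1, 0))
print(f"designed mean hop time 200 fs → MLE {mean_t:.0f} ± {se:.0f} fs (n = {len(ens)})")
for t in (0, 100, 200, 400, 800):
    row = pops.loc[float(t)]
    print(f"  t = {t:4d} fs:  S1 {row['S1']:.2f}  S0 {row['S0']:.2f}")

# 3) geometry at the hops: the switch is already planar when it funnels to S0
stats = hop_geometry_stats(ens, [PROXY_COORDS["alpha"], PROXY_COORDS["gamma"]], (1, 0))
for name, entry in stats["coordinates"].items():
    print(f"hop-frame {name}: circular mean {entry['mean']:.1f}° ± {entry['std']:.1f}° over {stats['n_hops']} hops")
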