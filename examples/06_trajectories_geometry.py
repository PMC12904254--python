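"""Adaptive walks, well accessibility and well depth.

Greedy stochastic walks (one improving substitution at a time) terminate at
local optima; the fraction of walks ending at a sequence is its
accessibility (well width), and the minimal cumulative uphill barrier to any
other top well (Dijkstra on the mutation graph) is its depth.
"""

from coevoscape import (
    LibraryScheme,
    find_wells,
    sample_landscape,
    simulate_trajectories,
    well_depth,
)

scheme = LibraryScheme(chain_a_positions=(8, 11, 14), chain_b_positions=(29, 30, 33))
landscape = sample_landscape(scheme, pairwise_scale=1.0, seed=21)

ensemble = simulate_trajectories(landscape, scheme, 200_000, seed=22, track_visits=False)
print(f"{len(ensemble.terminal_counts)} distinct wells found")

geometry = well_depth(
    find_wells(ensemble, landscape, k=5), landscape, scheme
)
print(geometry.to_frame().round(4).to_string(index=False))
# Accessibility is the well's basin share of all 200k walks; depth is the
# energy a trajectory must climb to escape into another top well.  Many
# comparably accessible, shallow wells = a rugged, sawtooth landscape.
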