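"""Seed sequences: weak binders that funnel trajectories into specific wells.

A seed candidate for a target well is a weak-binding sequence (fitness inside
a band; on selection data the band is the mean inferred fitness of sequences
whose final-round read count is 5 and 20 respectively) whose through-traffic
is highly *exclusive* to the well (fraction of walks through the sequence
that end there) and which *contributes* a non-negligible share of the well's
inflow (fraction of walks ending there that pass through it), at a minimum
edit distance from the target.  Paths from a seed to its target are extracted
by re-simulating a dedicated walk ensemble started at the seed, which is
exact for the seed's downstream behaviour and avoids storing the global
ensemble's paths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .enrichment import hamming
from .library import LibraryScheme
from .walks import TrajectoryEnsemble, simulate_trajectories

__all__ = [
    "SeedCandidate",
    "PathSet",
    "exclusivity",
    "contribution",
    "fitness_band",
    "find_seeds",
    "extract_paths",
]


@dataclass
class SeedCandidate:
    sequence: str
    fitness: float
    target_well: str
    exclusivity: float
    contribution: float
    edit_distance_to_target: int
    modal_well: str  # well receiving the largest share of the sequence's traffic
    modal_differs: bool  # True when the modal well over *all* terminals differs


@dataclass
class PathSet:
    """Distinct monotone single-substitution paths seed -> target."""

    seed: str
    target: str
    paths: list  # [(tuple of sequences, multiplicity)], major paths, sorted desc
    n_to_target: int
    n_simulated: int
    minor_fraction: float  # aggregate weight of paths folded below the threshold

    @property
    def n_paths(self) -> int:
        return len(self.paths)


def exclusivity(ensemble: TrajectoryEnsemble, sequence: str, well: str):
    """Fraction of trajectories through ``sequence`` that end at ``well``.

    None (undefined) when the sequence was never visited.
    """
    visits = ensemble.visit_counts.get(sequence, 0)
    if visits == 0:
        return None
    return ensemble.through.get(sequence, {}).get(well, 0) / visits


def contribution(ensemble: TrajectoryEnsemble, sequence: str, well: str):
    """Fraction of trajectories ending at ``well`` that pass through
    ``sequence``; None (undefined) when the well received no trajectories."""
    arrived = ensemble.terminal_counts.get(well, 0)
    if arrived == 0:
        return None
    return ensemble.through.get(sequence, {}).get(well, 0) / arrived


def fitness_band(
    dataset,
    fitness_fn: Callable,
    counts: tuple = (5, 20),
    round_label: Optional[str] = None,
) -> tuple:
    """Weak-binder fitness band from final-round read counts.

    Band edges are the mean fitness of sequences observed exactly ``counts[0]``
    and ``counts[1]`` times in the final round; when no sequence has exactly
    that count, the nearest observed count is used.
    """
    r = round_label or dataset.final_round
    items = [(a + b, c) for (a, b), c in dataset.counts[r].items()]
    if not items:
        raise ValueError(f"round {r!r} has no counts")
    values = np.array([c for _, c in items])
    edges = []
    for target_count in counts:
        nearest = values[np.argmin(np.abs(values - target_count))]
        seqs = [s for s, c in items if c == nearest]
        edges.append(float(np.mean(np.atleast_1d(fitness_fn(seqs)))))
    lo, hi = sorted(edges)
    if lo == hi:
        raise ValueError("degenerate fitness band (lo == hi)")
    return lo, hi


def find_seeds(
    ensemble: TrajectoryEnsemble,
    fitness_fn: Callable,
    band: tuple,
    target_wells: Optional[Sequence[str]] = None,
    min_exclusivity: float = 0.9,
    min_contribution: float = 0.01,
    min_distance: int = 3,
) -> list:
    """Seed candidates satisfying the band, exclusivity, contribution and
    distance criteria against their most-likely target well.

    ``target_wells`` restricts attention to specific wells (e.g. those with
    experimentally validated strong binders); by default all terminals are
    eligible.  The most-likely well among the targets is the one receiving
    the largest share of the sequence's through-traffic; when the modal well
    over all terminals differs from it, the candidate is flagged.
    """
    lo, hi = band
    if not lo < hi:
        raise ValueError("empty fitness band")
    targets = set(target_wells) if target_wells is not None else set(ensemble.terminal_counts)
    visited = sorted(ensemble.visit_counts)
    fits = np.atleast_1d(fitness_fn(visited)) if visited else np.empty(0)
    out = []
    for s, f in zip(visited, fits):
        if not lo <= f <= hi:
            continue
        traffic = ensemble.through.get(s, {})
        if not traffic:
            continue
        in_targets = {w: c for w, c in traffic.items() if w in targets}
        if not in_targets:
            continue
        well = max(in_targets, key=lambda w: (in_targets[w], w))
        modal_all = max(traffic, key=lambda w: (traffic[w], w))
        excl = exclusivity(ensemble, s, well)
        contr = contribution(ensemble, s, well)
        dist = hamming(s, well)
        if excl is None or contr is None:
            continue
        if excl >= min_exclusivity and contr >= min_contribution and dist >= min_distance:
            out.append(
                SeedCandidate(
                    sequence=s,
                    fitness=float(f),
                    target_well=well,
                    exclusivity=excl,
                    contribution=contr,
                    edit_distance_to_target=dist,
                    modal_well=modal_all,
                    modal_differs=modal_all != well,
                )
            )
    out.sort(key=lambda c: (-c.exclusivity, -c.contribution, c.sequence))
    return out


def seeds_to_frame(candidates) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sequence": [c.sequence for c in candidates],
            "fitness": [c.fitness for c in candidates],
            "target_well": [c.target_well for c in candidates],
            "exclusivity": [c.exclusivity for c in candidates],
            "contribution": [c.contribution for c in candidates],
            "distance": [c.edit_distance_to_target for c in candidates],
            "modal_well_differs": [c.modal_differs for c in candidates],
        }
    )


def extract_paths(
    fitness_fn: Callable,
    scheme: LibraryScheme,
    seed_sequence: str,
    target: str,
    n_trajectories: int = 10_000,
    seed: int = 0,
    minor_threshold: float = 0.15,
) -> PathSet:
    """Enumerate realized monotone paths from a seed to a target well.

    Simulates ``n_trajectories`` walks started at the seed, keeps those
    terminating at the target, and tallies distinct step sequences.  Paths
    are reported in decreasing multiplicity; the maximal low-weight tail
    whose collective share of seed->target trajectories stays below
    ``minor_threshold`` is folded into ``minor_fraction``.
    """
    ens = simulate_trajectories(
        fitness_fn,
        scheme,
        n_trajectories,
        seed=seed,
        starts=[seed_sequence],
        track_visits=False,
        store_paths=True,
    )
    tally = {}
    n_hit = 0
    for path in ens.paths:
        if path[-1] == target:
            n_hit += 1
            tally[path] = tally.get(path, 0) + 1
    if n_hit == 0:
        return PathSet(seed_sequence, target, [], 0, n_trajectories, 0.0)
    ordered = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    # fold the largest suffix (smallest-weight paths) collectively under threshold
    minor_weight = 0
    cut = len(ordered)
    for i in range(len(ordered) - 1, -1, -1):
        w = ordered[i][1]
        if (minor_weight + w) / n_hit < minor_threshold:
            minor_weight += w
            cut = i
        else:
            break
    major = ordered[:cut]
    return PathSet(
        seed=seed_sequence,
        target=target,
        paths=major,
        n_to_target=n_hit,
        n_simulated=n_trajectories,
        minor_fraction=minor_weight / n_hit,
    )
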