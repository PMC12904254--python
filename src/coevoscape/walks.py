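"""Greedy stochastic adaptive walks on a fitness landscape.

A coevolutionary trajectory starts at a sequence and repeatedly applies a
uniformly chosen single-position substitution among those that *strictly*
increase fitness, terminating at a local optimum.  The fraction of an
ensemble of such walks terminating at a sequence is that sequence's
accessibility — the width of its energy well.  Fitness ties never count as
improving moves (exact float comparison; ties are measure-zero for learned
landscapes but possible with quantized scorers).

For enumerable spaces the simulator precomputes the improving-neighbor table
once and advances all walks in lockstep with vectorized numpy steps; above
``exhaustive_limit`` it falls back to a lazy, memoized walker with identical
semantics.  All randomness flows from one integer seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .library import LibraryScheme

__all__ = ["TrajectoryEnsemble", "simulate_trajectories", "accessibility"]


def _space_size(scheme: LibraryScheme) -> int:
    return scheme.n_letters ** scheme.total_positions


def _index_to_seq(idx: int, scheme: LibraryScheme) -> str:
    A, L = scheme.n_letters, scheme.total_positions
    letters = []
    for _ in range(L):
        idx, rem = divmod(idx, A)
        letters.append(scheme.alphabet[rem])
    return "".join(reversed(letters))


def _seq_to_index(seq: str, scheme: LibraryScheme) -> int:
    pos = {aa: i for i, aa in enumerate(scheme.alphabet)}
    idx = 0
    for c in seq:
        idx = idx * scheme.n_letters + pos[c]
    return idx


def _all_sequences(scheme: LibraryScheme) -> list:
    return [
        "".join(t)
        for t in itertools.product(scheme.alphabet, repeat=scheme.total_positions)
    ]


def _neighbor_table(scheme: LibraryScheme) -> np.ndarray:
    """(M, L*(A-1)) neighbor indices for every sequence of the space."""
    A, L = scheme.n_letters, scheme.total_positions
    M = A**L
    ids = np.arange(M, dtype=np.int64)
    cols = []
    for i in range(L):
        stride = A ** (L - 1 - i)
        digit = (ids // stride) % A
        for delta in range(1, A):
            new_digit = (digit + delta) % A
            cols.append(ids + (new_digit - digit) * stride)
    return np.stack(cols, axis=1)


@dataclass
class TrajectoryEnsemble:
    """Outcome of an adaptive-walk ensemble.

    ``terminal_counts[s]`` counts walks ending at s; ``visit_counts[s]``
    counts walks passing through s (each walk visits a sequence at most once
    because fitness strictly increases along a path); ``through[s][t]``
    counts walks through s that terminated at t — the basis of the seed
    exclusivity/contribution metrics.  ``paths`` holds full paths when
    requested.
    """

    scheme: LibraryScheme
    n_trajectories: int
    terminal_counts: dict
    visit_counts: dict
    through: dict
    seed: int
    paths: Optional[list] = None

    def accessibility(self, sequence: Optional[str] = None):
        if sequence is not None:
            return self.terminal_counts.get(sequence, 0) / self.n_trajectories
        return {
            s: c / self.n_trajectories for s, c in sorted(self.terminal_counts.items())
        }

    def to_frame(self) -> pd.DataFrame:
        seqs = sorted(set(self.visit_counts) | set(self.terminal_counts))
        return pd.DataFrame(
            {
                "sequence": seqs,
                "terminal_count": [self.terminal_counts.get(s, 0) for s in seqs],
                "visit_count": [self.visit_counts.get(s, 0) for s in seqs],
                "accessibility": [
                    self.terminal_counts.get(s, 0) / self.n_trajectories for s in seqs
                ],
            }
        )


def accessibility(ensemble: TrajectoryEnsemble, sequence: Optional[str] = None):
    """Terminal fraction of a sequence (0 for non-terminals) or all of them."""
    return ensemble.accessibility(sequence)


def simulate_trajectories(
    fitness_fn: Callable,
    scheme: LibraryScheme,
    n_trajectories: int,
    seed: int = 0,
    starts: Optional[Sequence[str]] = None,
    track_visits: bool = True,
    store_paths: bool = False,
    exhaustive_limit: int = 2_000_000,
) -> TrajectoryEnsemble:
    """Simulate greedy stochastic adaptive walks.

    Walks start uniformly at random over the full space unless ``starts``
    gives explicit start sequences (cycled to n_trajectories).  Results are
    bit-reproducible for a fixed seed.
    """
    if n_trajectories < 1:
        raise ValueError("n_trajectories must be >= 1")
    M = _space_size(scheme)
    if M <= exhaustive_limit:
        return _simulate_vectorized(
            fitness_fn, scheme, n_trajectories, seed, starts, track_visits, store_paths
        )
    return _simulate_lazy(
        fitness_fn, scheme, n_trajectories, seed, starts, track_visits, store_paths
    )


def _simulate_vectorized(fitness_fn, scheme, n_traj, seed, starts, track_visits, store_paths):
    rng = np.random.default_rng(seed)
    A, L = scheme.n_letters, scheme.total_positions
    M = A**L
    seqs = _all_sequences(scheme)
    F = np.asarray(fitness_fn(seqs), dtype=float)
    if F.shape != (M,):
        F = np.array([float(fitness_fn(s)) for s in seqs])
    nbr = _neighbor_table(scheme)
    better = F[nbr] > F[:, None]
    deg = better.sum(axis=1).astype(np.int64)
    packed = np.where(better, nbr, M)
    packed.sort(axis=1)  # improving neighbors first (sentinel M sorts last)

    if starts is not None:
        start_ids = np.array([_seq_to_index(s, scheme) for s in starts], dtype=np.int64)
        cur = start_ids[np.arange(n_traj) % len(start_ids)]
    else:
        cur = rng.integers(0, M, size=n_traj)

    max_steps = L * (A - 1) * 2 + 2  # generous bound; each step strictly improves
    record = track_visits or store_paths
    path_matrix = [cur.copy()] if record else None
    alive = deg[cur] > 0
    steps = 0
    while alive.any():
        idx = np.flatnonzero(alive)
        nodes = cur[idx]
        choice = (rng.random(len(idx)) * deg[nodes]).astype(np.int64)
        cur[idx] = packed[nodes, choice]
        if record:
            snapshot = np.full(n_traj, -1, dtype=np.int64)
            snapshot[idx] = cur[idx]
            path_matrix.append(snapshot)
        alive[idx] = deg[cur[idx]] > 0
        steps += 1
        if steps > max_steps * 10:
            raise RuntimeError("adaptive walk failed to terminate (fitness cycle?)")

    term_counts = np.bincount(cur, minlength=M)
    terminals = np.flatnonzero(term_counts)
    terminal_counts = {seqs[t]: int(term_counts[t]) for t in terminals}

    visit_counts, through, paths = {}, {}, None
    if record:
        P = np.stack(path_matrix, axis=1)  # (n_traj, steps+1)
        if track_visits:
            tmap = {t: k for k, t in enumerate(terminals)}
            tcol = np.array([tmap[t] for t in cur])
            counts2d = np.zeros((M, len(terminals)), dtype=np.int64)
            for s in range(P.shape[1]):
                col = P[:, s]
                mask = col >= 0
                np.add.at(counts2d, (col[mask], tcol[mask]), 1)
            visited = np.flatnonzero(counts2d.sum(axis=1))
            for v in visited:
                row = counts2d[v]
                nz = np.flatnonzero(row)
                through[seqs[v]] = {seqs[terminals[k]]: int(row[k]) for k in nz}
                visit_counts[seqs[v]] = int(row.sum())
        if store_paths:
            paths = []
            for w in range(n_traj):
                row = P[w]
                paths.append(tuple(seqs[i] for i in row if i >= 0))
    return TrajectoryEnsemble(
        scheme=scheme,
        n_trajectories=n_traj,
        terminal_counts=terminal_counts,
        visit_counts=visit_counts,
        through=through,
        seed=seed,
        paths=paths,
    )


def _simulate_lazy(fitness_fn, scheme, n_traj, seed, starts, track_visits, store_paths):
    """Dict-memoized walker for spaces too large to enumerate (slow path)."""
    rng = np.random.default_rng(seed)
    A, L = scheme.n_letters, scheme.total_positions
    alphabet = scheme.alphabet
    memo = {}

    def fit(s):
        if s not in memo:
            memo[s] = float(fitness_fn(s))
        return memo[s]

    def improving(s):
        f0 = fit(s)
        out = []
        for i in range(L):
            for aa in alphabet:
                if aa != s[i]:
                    t = s[:i] + aa + s[i + 1 :]
                    if fit(t) > f0:
                        out.append(t)
        return out

    terminal_counts, visit_counts, through = {}, {}, {}
    paths = [] if store_paths else None
    for w in range(n_traj):
        if starts is not None:
            s = starts[w % len(starts)]
        else:
            s = "".join(alphabet[i] for i in rng.integers(0, A, size=L))
        path = [s]
        while True:
            ups = improving(s)
            if not ups:
                break
            s = ups[rng.integers(0, len(ups))]
            path.append(s)
        terminal_counts[s] = terminal_counts.get(s, 0) + 1
        if track_visits:
            for node in path:
                visit_counts[node] = visit_counts.get(node, 0) + 1
                through.setdefault(node, {})
                through[node][s] = through[node].get(s, 0) + 1
        if store_paths:
            paths.append(tuple(path))
    return TrajectoryEnsemble(
        scheme=scheme,
        n_trajectories=n_traj,
        terminal_counts=terminal_counts,
        visit_counts=visit_counts,
        through=through,
        seed=seed,
        paths=paths,
    )
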