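"""Ground-truth landscapes and forward simulation of multi-round selection.

The generator draws a sequence->fitness function with additive (single-site)
and pairwise epistatic terms whose intra-/inter-chain composition is
configurable, then forward-simulates rounds of selection: each round rescales
the sequence distribution by a logistic selection factor in true fitness and
draws multinomial read counts at a fixed depth.  This is exactly the
generative family the selection probabilistic model inverts, so fitting the
model on simulated data is a well-posed parameter-recovery experiment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .library import LibraryScheme, SelectionDataset

__all__ = [
    "TrueLandscape",
    "SelectionConfig",
    "sample_landscape",
    "simulate_selection",
    "enumerate_sequences",
]


def enumerate_sequences(scheme: LibraryScheme) -> list:
    """All concatenated sequences of the scheme, in lexicographic order."""
    return [
        "".join(letters)
        for letters in itertools.product(scheme.alphabet, repeat=scheme.total_positions)
    ]


def encode(sequences: Sequence[str], scheme: LibraryScheme) -> np.ndarray:
    """Integer-encode sequences as an (n, L) array of alphabet indices."""
    lut = np.full(128, -1, dtype=np.int64)
    for i, aa in enumerate(scheme.alphabet):
        lut[ord(aa)] = i
    arr = np.frombuffer("".join(sequences).encode(), dtype=np.uint8)
    idx = lut[arr].reshape(len(sequences), scheme.total_positions)
    if (idx < 0).any():
        raise ValueError("sequence contains letters outside the scheme alphabet")
    return idx


@dataclass
class TrueLandscape:
    """Additive + pairwise ground-truth fitness over the library space.

    ``additive`` has shape (L, A); ``pairwise`` maps 0-based position-index
    pairs (i, j), i < j, to (A, A) effect tables.  Fitness of a sequence is
    constant + sum of its additive terms + sum of its pairwise terms.
    """

    scheme: LibraryScheme
    constant: float
    additive: np.ndarray
    pairwise: dict
    seed: Optional[int] = None

    def fitness_many(self, sequences: Sequence[str]) -> np.ndarray:
        idx = encode(sequences, self.scheme)
        f = np.full(len(sequences), self.constant, dtype=float)
        f += self.additive[np.arange(idx.shape[1]), idx].sum(axis=1)
        for (i, j), table in self.pairwise.items():
            f += table[idx[:, i], idx[:, j]]
        return f

    def fitness(self, sequence: str) -> float:
        return float(self.fitness_many([sequence])[0])

    def __call__(self, sequences):
        if isinstance(sequences, str):
            return self.fitness(sequences)
        return self.fitness_many(list(sequences))

    def to_frame(self) -> pd.DataFrame:
        """Long-format term table (term, positions, letters, value)."""
        rows = [("constant", "", "", self.constant)]
        pos = self.scheme.positions
        for i in range(self.additive.shape[0]):
            for a, aa in enumerate(self.scheme.alphabet):
                rows.append(("additive", str(pos[i]), aa, self.additive[i, a]))
        for (i, j), table in sorted(self.pairwise.items()):
            for a, aa in enumerate(self.scheme.alphabet):
                for b, bb in enumerate(self.scheme.alphabet):
                    rows.append(
                        ("pairwise", f"{pos[i]},{pos[j]}", aa + bb, table[a, b])
                    )
        return pd.DataFrame(rows, columns=["term", "positions", "letters", "value"])


def sample_landscape(
    scheme: LibraryScheme,
    additive_scale: float = 1.0,
    pairwise_scale: float = 0.5,
    pairwise_density: float = 0.3,
    inter_fraction: float = 0.5,
    constant: float = 0.0,
    seed: int = 0,
) -> TrueLandscape:
    """Draw a reproducible random landscape.

    Additive effects are N(0, additive_scale^2) per position x letter.  A
    fraction ``pairwise_density`` of all position pairs receives a pairwise
    table of N(0, pairwise_scale^2) entries, with ``inter_fraction`` of the
    selected pairs spanning the two chains (rounded to the nearest feasible
    count given the draw).
    """
    if additive_scale < 0 or pairwise_scale < 0:
        raise ValueError("effect scales must be non-negative")
    if not scheme.alphabet:
        raise ValueError("scheme alphabet is empty")
    rng = np.random.default_rng(seed)
    L, A = scheme.total_positions, scheme.n_letters
    additive = rng.normal(0.0, additive_scale, size=(L, A)) if additive_scale else np.zeros((L, A))

    all_pairs = list(itertools.combinations(range(L), 2))
    inter = [p for p in all_pairs if scheme.chain_of_index(p[0]) != scheme.chain_of_index(p[1])]
    intra = [p for p in all_pairs if scheme.chain_of_index(p[0]) == scheme.chain_of_index(p[1])]
    n_pairs = int(round(pairwise_density * len(all_pairs)))
    pairwise = {}
    if pairwise_scale > 0 and n_pairs > 0:
        n_inter = min(len(inter), int(round(inter_fraction * n_pairs)))
        n_intra = min(len(intra), n_pairs - n_inter)
        chosen = []
        if n_inter:
            chosen += [inter[i] for i in rng.choice(len(inter), n_inter, replace=False)]
        if n_intra:
            chosen += [intra[i] for i in rng.choice(len(intra), n_intra, replace=False)]
        for p in sorted(chosen):
            pairwise[p] = rng.normal(0.0, pairwise_scale, size=(A, A))
    return TrueLandscape(scheme, constant, additive, pairwise, seed=seed)


@dataclass
class SelectionConfig:
    """Conditions of the simulated selection.

    Five positive-selection rounds after the unselected round 0 mirror the
    four magnetic sorts plus one FACS sort of the experimental campaign;
    ``depth`` reads are drawn per round.  The per-round selection factor is
    logistic(stringency * (f - offset)); offset defaults to the mean true
    fitness of the universe so selection is informative from round 1.
    """

    n_rounds: int = 5
    depth: int = 100_000
    stringency: float | Sequence[float] = 1.0
    offset: Optional[float | Sequence[float]] = None
    initial: str = "uniform"
    dirichlet_alpha: float = 1.0
    universe: Optional[Sequence[str]] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


def _per_round(value, n_rounds, default):
    if value is None:
        value = default
    if np.isscalar(value):
        return np.full(n_rounds, float(value))
    arr = np.asarray(value, dtype=float)
    if arr.shape != (n_rounds,):
        raise ValueError(f"per-round parameter must have length {n_rounds}")
    return arr


def simulate_selection(landscape: TrueLandscape, config: SelectionConfig) -> SelectionDataset:
    """Forward-simulate multi-round selection read counts.

    Round-0 counts are multinomial draws from the initial distribution; for
    each subsequent round r, q_r(x) proportional to q_{r-1}(x) * s_r(x) with
    s_r(x) = logistic(stringency_r * (f(x) - offset_r)), and counts_r ~
    Multinomial(depth, q_r).  Deterministic given ``config.seed``.
    """
    scheme = landscape.scheme
    universe = list(config.universe) if config.universe is not None else enumerate_sequences(scheme)
    if not universe:
        raise ValueError("sequence universe is empty")
    rng = np.random.default_rng(config.seed)
    f = landscape.fitness_many(universe)
    slope = _per_round(config.stringency, config.n_rounds, 1.0)
    offset = _per_round(config.offset, config.n_rounds, float(f.mean()))

    if config.initial == "uniform":
        q = np.full(len(universe), 1.0 / len(universe))
    elif config.initial == "dirichlet":
        q = rng.dirichlet(np.full(len(universe), config.dirichlet_alpha))
    else:
        raise ValueError(f"unknown initial distribution {config.initial!r}")

    rounds = [f"R{r}" for r in range(config.n_rounds + 1)]
    counts = {}
    pairs = [scheme.split(s) for s in universe]
    for r in range(config.n_rounds + 1):
        if r > 0:
            s = expit(slope[r - 1] * (f - offset[r - 1]))
            mass = q * s
            z = mass.sum()
            if z <= 0:
                raise ValueError("selection drove every sequence to probability zero")
            q = mass / z
        draw = rng.multinomial(config.depth, q)
        nz = np.nonzero(draw)[0]
        counts[rounds[r]] = {pairs[i]: int(draw[i]) for i in nz}
    return SelectionDataset(scheme=scheme, rounds=rounds, counts=counts)
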