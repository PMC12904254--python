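"""Functional-ANOVA decomposition of fitness landscapes into epistatic terms.

Any sequence->fitness function over the library space decomposes uniquely
(under the uniform reference distribution over the alphabet, the orthogonal
basis underlying the Walsh-Hadamard view of a landscape) into a grand mean
plus zero-mean single-site, pairwise and higher-order contrasts:

    beta_0        = E[f]
    beta_i(a)     = E[f | x_i = a] - beta_0
    beta_ij(a,b)  = E[f | x_i = a, x_j = b] - beta_i(a) - beta_j(b) - beta_0

and analogous Moebius subtraction for higher orders.  The *importance* of a
term is the max-minus-min of its effect sizes over letter configurations —
the maximal amount that choosing amino acids at those positions can move the
fitness.  Terms are classified intra-chain or inter-chain by whether their
positions span both library chains; the ratio of average inter-chain to
average intra-chain importance per term (REI) summarizes, per interaction
order, whether epistasis acts across the interface or within each partner.

Conditional means are exhaustive whenever the enumerated space fits under
``exhaustive_limit`` and Monte Carlo (uniform sequence sampling, fixed seed)
otherwise.  The decomposition applies equally to external scorers (e.g.
structure-conditioned sequence scores supplied as a table).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .library import LibraryScheme

__all__ = [
    "EpistasisTerm",
    "EpistasisReport",
    "decompose",
    "effect_size_at",
    "rei",
    "external_scorer_epistasis",
]


@dataclass
class EpistasisTerm:
    positions: tuple  # scheme residue labels
    indices: tuple  # 0-based indices into the concatenated sequence
    order: int
    chain_class: str  # intra_A | intra_B | inter
    letters: tuple
    effect_sizes: np.ndarray  # shape (A,) * order

    @property
    def importance(self) -> float:
        return float(np.ptp(self.effect_sizes))

    def effect_at(self, letters: str) -> float:
        idx = tuple(self.letters.index(c) for c in letters)
        return float(self.effect_sizes[idx])


@dataclass
class EpistasisReport:
    scheme: LibraryScheme
    beta0: float
    terms: list
    max_order: int
    estimator: str  # "exhaustive" or "monte_carlo"

    def term(self, positions) -> EpistasisTerm:
        key = tuple(positions)
        for t in self.terms:
            if t.positions == key or t.indices == key:
                return t
        raise KeyError(f"no epistasis term for positions {positions}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "positions": ",".join(map(str, t.positions)),
                "order": t.order,
                "chain_class": t.chain_class,
                "importance": t.importance,
            }
            for t in self.terms
        ]
        return pd.DataFrame(rows)

    def effects_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.terms:
            for cfg in itertools.product(range(len(t.letters)), repeat=t.order):
                rows.append(
                    {
                        "positions": ",".join(map(str, t.positions)),
                        "order": t.order,
                        "chain_class": t.chain_class,
                        "letters": "".join(t.letters[i] for i in cfg),
                        "effect_size": float(t.effect_sizes[cfg]),
                    }
                )
        return pd.DataFrame(rows)


def _chain_class(scheme: LibraryScheme, indices) -> str:
    chains = {scheme.chain_of_index(i) for i in indices}
    if chains == {"A"}:
        return "intra_A"
    if chains == {"B"}:
        return "intra_B"
    return "inter"


def _fitness_vector(fitness_fn, sequences) -> np.ndarray:
    try:
        vals = fitness_fn(sequences)
        arr = np.asarray(vals, dtype=float)
        if arr.shape == (len(sequences),):
            return arr
    except Exception:
        pass
    return np.array([float(fitness_fn(s)) for s in sequences])


def _marginal_tensors(fitness_fn, scheme, max_order, exhaustive_limit, mc_samples, seed, batch=200_000):
    """Grand mean and E[f | x_S = cfg] tensors for every subset S, |S| <= max_order."""
    L, A = scheme.total_positions, scheme.n_letters
    alphabet = scheme.alphabet
    exhaustive = A**L <= exhaustive_limit
    subsets = [
        S for k in range(1, max_order + 1) for S in itertools.combinations(range(L), k)
    ]
    if exhaustive:
        F = np.empty((A,) * L)
        flat = F.reshape(-1)
        seqs_iter = itertools.product(alphabet, repeat=L)
        pos = 0
        while True:
            chunk = ["".join(s) for s in itertools.islice(seqs_iter, batch)]
            if not chunk:
                break
            flat[pos : pos + len(chunk)] = _fitness_vector(fitness_fn, chunk)
            pos += len(chunk)
        beta0 = float(F.mean())
        margs = {
            S: F.mean(axis=tuple(i for i in range(L) if i not in S)) for S in subsets
        }
        return beta0, margs, "exhaustive"

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, A, size=(mc_samples, L))
    seqs = ["".join(alphabet[i] for i in row) for row in idx]
    f = _fitness_vector(fitness_fn, seqs)
    beta0 = float(f.mean())
    margs = {}
    for S in subsets:
        k = len(S)
        sums = np.zeros((A,) * k)
        cnts = np.zeros((A,) * k)
        keys = tuple(idx[:, i] for i in S)
        np.add.at(sums, keys, f)
        np.add.at(cnts, keys, 1.0)
        with np.errstate(invalid="ignore"):
            margs[S] = np.where(cnts > 0, sums / np.maximum(cnts, 1.0), beta0)
    return beta0, margs, "monte_carlo"


def _expand(effect: np.ndarray, T, S) -> np.ndarray:
    """Broadcast a T-indexed effect tensor onto the axes of superset S."""
    shape = [1] * len(S)
    for axis, i in enumerate(S):
        if i in T:
            shape[axis] = effect.shape[T.index(i)]
    return effect.reshape(shape)


def decompose(
    fitness_fn: Callable,
    scheme: LibraryScheme,
    max_order: int = 2,
    exhaustive_limit: int = 10**6,
    mc_samples: int = 10**5,
    seed: int = 0,
) -> EpistasisReport:
    """Decompose a fitness function into zero-mean ANOVA contrasts.

    ``fitness_fn`` maps a sequence (or list of sequences) to fitness; the
    reference distribution is uniform over the scheme alphabet.  Exhaustive
    enumeration is used when |alphabet| ** positions <= ``exhaustive_limit``,
    Monte Carlo with ``mc_samples`` uniform draws otherwise.
    """
    L = scheme.total_positions
    if not 1 <= max_order <= L:
        raise ValueError(f"max_order must be in [1, {L}], got {max_order}")
    beta0, margs, estimator = _marginal_tensors(
        fitness_fn, scheme, max_order, exhaustive_limit, mc_samples, seed
    )
    effects = {}
    for S in sorted(margs, key=len):
        eff = margs[S] - beta0
        for k in range(1, len(S)):
            for T in itertools.combinations(S, k):
                eff = eff - _expand(effects[T], T, S)
        effects[S] = eff
    terms = [
        EpistasisTerm(
            positions=tuple(scheme.positions[i] for i in S),
            indices=S,
            order=len(S),
            chain_class=_chain_class(scheme, S),
            letters=scheme.alphabet,
            effect_sizes=effects[S],
        )
        for S in sorted(effects, key=lambda s: (len(s), s))
    ]
    return EpistasisReport(scheme, beta0, terms, max_order, estimator)


def effect_size_at(report_or_term, variant: str, positions=None) -> float:
    """Effect size of one term at the letters a variant carries there."""
    if isinstance(report_or_term, EpistasisTerm):
        term = report_or_term
        scheme_indices = term.indices
    else:
        if positions is None:
            raise ValueError("positions required when passing a report")
        term = report_or_term.term(tuple(positions))
        scheme_indices = term.indices
    letters = "".join(variant[i] for i in scheme_indices)
    return term.effect_at(letters)


def reconstruct(report: EpistasisReport, sequence: str) -> float:
    """beta0 + sum of all term effects at the sequence (exact when
    max_order equals the number of positions and estimation was exhaustive)."""
    return report.beta0 + sum(effect_size_at(t, sequence) for t in report.terms)


def rei(report: EpistasisReport, order: int = 2, eps: float = 1e-9):
    """Ratio of average inter-chain to average intra-chain importance per term.

    Returns None (undefined) when either side has no terms of that order or
    the intra-chain average importance is numerically zero (below ``eps``,
    which absorbs float round-off on exactly additive landscapes).
    """
    inter = [t.importance for t in report.terms if t.order == order and t.chain_class == "inter"]
    intra = [t.importance for t in report.terms if t.order == order and t.chain_class.startswith("intra")]
    if not inter or not intra:
        return None
    denom = float(np.mean(intra))
    if denom <= eps:
        return None
    return float(np.mean(inter)) / denom


def external_scorer_epistasis(
    scores: Mapping[str, float],
    scheme: LibraryScheme,
    max_order: int = 2,
    exhaustive_limit: int = 10**6,
    mc_samples: int = 10**5,
    seed: int = 0,
) -> EpistasisReport:
    """Decompose an externally supplied sequence->score table.

    In exhaustive mode the table must cover the full enumerated space; gaps
    raise an error listing (a sample of) the missing sequences.
    """
    if hasattr(scores, "to_dict") and not isinstance(scores, dict):
        scores = dict(scores)
    L, A = scheme.total_positions, scheme.n_letters
    if A**L <= exhaustive_limit:
        missing = []
        for letters in itertools.product(scheme.alphabet, repeat=L):
            s = "".join(letters)
            if s not in scores:
                missing.append(s)
                if len(missing) >= 10:
                    break
        if missing:
            raise ValueError(
                f"score table does not cover the enumerated space; missing e.g. {missing}"
            )

    def fn(seqs):
        if isinstance(seqs, str):
            return scores[seqs]
        return np.array([scores[s] for s in seqs])

    return decompose(fn, scheme, max_order, exhaustive_limit, mc_samples, seed)
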