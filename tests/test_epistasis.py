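"""Functional-ANOVA epistasis decomposition against enumeration oracles."""

import itertools

import numpy as np
import pytest

from coevoscape import (
    LibraryScheme,
    decompose,
    effect_size_at,
    external_scorer_epistasis,
    rei,
    sample_landscape,
)
from coevoscape.epistasis import reconstruct


def anova_oracle(table, scheme, max_order):
    """Brute-force functional ANOVA by explicit enumeration and subtraction."""
    seqs = ["".join(t) for t in itertools.product(scheme.alphabet, repeat=scheme.total_positions)]
    beta0 = np.mean([table[s] for s in seqs])
    L, A = scheme.total_positions, scheme.n_letters
    effects = {}
    for k in range(1, max_order + 1):
        for S in itertools.combinations(range(L), k):
            eff = np.zeros((A,) * k)
            for cfg in itertools.product(range(A), repeat=k):
                vals = [
                    table[s]
                    for s in seqs
                    if all(s[i] == scheme.alphabet[c] for i, c in zip(S, cfg))
                ]
                e = np.mean(vals) - beta0
                for m in range(1, k):
                    for T in itertools.combinations(range(k), m):
                        sub_S = tuple(S[t] for t in T)
                        sub_cfg = tuple(cfg[t] for t in T)
                        e -= effects[sub_S][sub_cfg]
                eff[cfg] = e
            effects[S] = eff
    return beta0, effects


def xor_table(scheme):
    # f = 1 iff the two letters agree (the 2x2 XOR toy)
    return {a + b: float(a == b) for a in scheme.alphabet for b in scheme.alphabet}


def test_xor_toy_exact_decomposition(scheme_2x2, make_table_fitness):
    table = xor_table(scheme_2x2)
    rep = decompose(make_table_fitness(table), scheme_2x2, max_order=2)
    mains = [t for t in rep.terms if t.order == 1]
    pair = [t for t in rep.terms if t.order == 2][0]
    for t in mains:
        assert np.allclose(t.effect_sizes, 0.0, atol=1e-12)
    assert np.allclose(np.sort(pair.effect_sizes.ravel()), [-0.5, -0.5, 0.5, 0.5])
    assert pair.importance == pytest.approx(1.0)
    assert pair.chain_class == "inter"
    assert effect_size_at(pair, "FF") == pytest.approx(0.5)


def test_additive_landscape_has_zero_pairwise_importance(scheme_4x2):
    land = sample_landscape(scheme_4x2, pairwise_scale=0.0, seed=3)
    rep = decompose(land, scheme_4x2, max_order=2)
    for t in rep.terms:
        if t.order == 2:
            assert t.importance <= 1e-9


def test_single_position_indicator_effects():
    """5-letter alphabet, f = 1 iff position 3 carries M: main effect at that
    position is +0.8 for M and -0.2 elsewhere, importance exactly 1."""
    scheme = LibraryScheme(chain_a_positions=(1, 2, 3), chain_b_positions=(4,))
    table_fn = lambda seqs: (
        np.array([1.0 if s[2] == "M" else 0.0 for s in seqs])
        if not isinstance(seqs, str)
        else float(seqs[2] == "M")
    )
    rep = decompose(table_fn, scheme, max_order=2)
    m_idx = scheme.alphabet.index("M")
    for t in rep.terms:
        if t.order == 1 and t.indices == (2,):
            assert t.effect_sizes[m_idx] == pytest.approx(0.8)
            others = np.delete(t.effect_sizes, m_idx)
            assert np.allclose(others, -0.2)
            assert t.importance == pytest.approx(1.0)
        else:
            assert t.importance <= 1e-12


def test_matches_bruteforce_oracle_on_random_table(scheme_4x2, make_table_fitness):
    rng = np.random.default_rng(12)
    seqs = ["".join(t) for t in itertools.product("FV", repeat=4)]
    table = {s: float(rng.normal()) for s in seqs}
    rep = decompose(make_table_fitness(table), scheme_4x2, max_order=3)
    beta0, oracle = anova_oracle(table, scheme_4x2, max_order=3)
    assert rep.beta0 == pytest.approx(beta0, abs=1e-12)
    for t in rep.terms:
        assert np.allclose(t.effect_sizes, oracle[t.indices], atol=1e-9)


def test_reconstruction_identity(scheme_4x2, make_table_fitness):
    rng = np.random.default_rng(4)
    seqs = ["".join(t) for t in itertools.product("FV", repeat=4)]
    table = {s: float(rng.normal()) for s in seqs}
    rep = decompose(make_table_fitness(table), scheme_4x2, max_order=4)
    for s in seqs:
        assert reconstruct(rep, s) == pytest.approx(table[s], abs=1e-9)


def test_zero_mean_contrasts(scheme_4x2, make_table_fitness):
    """Every term's effect sizes sum to zero along any single coordinate."""
    rng = np.random.default_rng(8)
    seqs = ["".join(t) for t in itertools.product("FV", repeat=4)]
    table = {s: float(rng.normal()) for s in seqs}
    rep = decompose(make_table_fitness(table), scheme_4x2, max_order=3)
    for t in rep.terms:
        for axis in range(t.order):
            assert np.allclose(t.effect_sizes.sum(axis=axis), 0.0, atol=1e-9)


@pytest.mark.parametrize("c,d", [(2.0, 0.0), (1.0, 5.0), (-3.0, 1.0)])
def test_shift_scale_equivariance(scheme_2x2, make_table_fitness, c, d):
    table = xor_table(scheme_2x2)
    scaled = {k: c * v + d for k, v in table.items()}
    rep = decompose(make_table_fitness(table), scheme_2x2, max_order=2)
    rep2 = decompose(make_table_fitness(scaled), scheme_2x2, max_order=2)
    for t1, t2 in zip(rep.terms, rep2.terms):
        assert t2.importance == pytest.approx(abs(c) * t1.importance, abs=1e-12)


def test_monte_carlo_agrees_with_exhaustive(scheme_4x2, make_table_fitness):
    rng = np.random.default_rng(5)
    seqs = ["".join(t) for t in itertools.product("FV", repeat=4)]
    table = {s: float(rng.normal()) for s in seqs}
    fn = make_table_fitness(table)
    exact = decompose(fn, scheme_4x2, max_order=2)
    coarse = decompose(fn, scheme_4x2, max_order=2, exhaustive_limit=1, mc_samples=2000, seed=0)
    fine = decompose(fn, scheme_4x2, max_order=2, exhaustive_limit=1, mc_samples=100_000, seed=0)
    assert fine.estimator == "monte_carlo"

    def err(rep):
        return max(
            abs(t.importance - e.importance) for t, e in zip(rep.terms, exact.terms)
        )

    assert err(fine) < 0.06
    assert err(fine) < err(coarse)


def test_rei_ratio_and_undefined_cases():
    scheme = LibraryScheme(chain_a_positions=(1, 2), chain_b_positions=(3,), alphabet=("F", "V"))

    def contrast(s, i, j):  # +-0.25 XOR-style zero-mean pairwise contrast
        return 0.25 if s[i] == s[j] else -0.25

    # both inter pairs (0,2),(1,2) with weight 2, intra pair (0,1) weight 1:
    # inter importances 1.0 each, intra importance 0.5 -> REI 2
    fn = lambda seqs: np.array(
        [2 * contrast(s, 0, 2) + 2 * contrast(s, 1, 2) + contrast(s, 0, 1) for s in seqs]
    )
    rep = decompose(fn, scheme, max_order=2)
    assert rei(rep, 2) == pytest.approx(2.0)

    # identical inter and intra weights -> REI 1
    sym = lambda seqs: np.array(
        [contrast(s, 0, 2) + contrast(s, 1, 2) + contrast(s, 0, 1) for s in seqs]
    )
    assert rei(decompose(sym, scheme, max_order=2), 2) == pytest.approx(1.0)

    land = sample_landscape(scheme, pairwise_scale=0.0, seed=0)
    assert rei(decompose(land, scheme, max_order=2), 2) is None  # 0/0 flagged


def test_external_scorer_matches_and_shifts(scheme_2x2):
    table = xor_table(scheme_2x2)
    rep1 = external_scorer_epistasis(table, scheme_2x2, max_order=2)
    rep2 = external_scorer_epistasis({k: v + 7.0 for k, v in table.items()}, scheme_2x2, max_order=2)
    for t1, t2 in zip(rep1.terms, rep2.terms):
        assert t1.importance == pytest.approx(t2.importance, abs=1e-12)
    incomplete = dict(table)
    incomplete.pop("FV")
    with pytest.raises(ValueError, match="missing"):
        external_scorer_epistasis(incomplete, scheme_2x2, max_order=2)


def test_external_pairwise_construction_is_recovered(scheme_4x2):
    """A score table built from known pairwise contrasts decomposes back to
    exactly those terms."""
    rng = np.random.default_rng(9)
    pair = (0, 2)
    contrast_tbl = rng.normal(size=(2, 2))
    contrast_tbl -= contrast_tbl.mean(axis=0, keepdims=True)
    contrast_tbl -= contrast_tbl.mean(axis=1, keepdims=True)
    letters = {c: i for i, c in enumerate(scheme_4x2.alphabet)}
    scores = {
        "".join(t): float(contrast_tbl[letters[t[pair[0]]], letters[t[pair[1]]]])
        for t in itertools.product(scheme_4x2.alphabet, repeat=4)
    }
    rep = external_scorer_epistasis(scores, scheme_4x2, max_order=2)
    for t in rep.terms:
        if t.indices == pair:
            assert np.allclose(t.effect_sizes, contrast_tbl, atol=1e-9)
        else:
            assert t.importance <= 1e-9


def test_max_order_bounds(scheme_2x2, make_table_fitness):
    with pytest.raises(ValueError):
        decompose(make_table_fitness(xor_table(scheme_2x2)), scheme_2x2, max_order=3)
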