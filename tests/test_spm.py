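"""Selection probabilistic model: fitting, scoring, CV, bootstrap."""

import numpy as np
import pytest

from coevoscape import (
    LibraryScheme,
    SelectionConfig,
    SelectionDataset,
    SPMFitConfig,
    bootstrap_datasets,
    crossvalidate,
    fit_spm,
    sample_landscape,
    score_sequences,
    simulate_selection,
)
from coevoscape.spm import predict_counts


def two_seq_dataset(scheme, c0=(500, 500), c1=(900, 100)):
    return SelectionDataset(
        scheme=scheme,
        rounds=["R0", "R1"],
        counts={
            "R0": {("F", "F"): c0[0], ("V", "V"): c0[1]},
            "R1": {("F", "F"): c1[0], ("V", "V"): c1[1]},
        },
    )


TOY_CFG = SPMFitConfig(
    max_epochs=3000, val_fraction=0.0, dropout=0.0, learning_rate=0.01,
    patience=10**9, hidden_dim=20, n_layers=2, seed=0,
)


def test_two_sequence_mle_recovers_log_odds_ratio(scheme_2x2):
    """Round 0 (500,500) -> round 1 (900,100): the binomial MLE for the
    round-1 fitness difference is ln 9."""
    model = fit_spm(two_seq_dataset(scheme_2x2), TOY_CFG)
    s = model.score(["FF", "VV"], round="R1")
    assert s[0] - s[1] == pytest.approx(np.log(9), abs=0.05)
    g = model.score(["FF", "VV"])
    assert np.sign(g[0] - g[1]) == 1.0  # global agrees in sign


def test_single_round_is_unidentifiable(scheme_2x2):
    ds = SelectionDataset(
        scheme=scheme_2x2, rounds=["R0"], counts={"R0": {("F", "F"): 10}}
    )
    with pytest.raises(ValueError):
        fit_spm(ds)


def test_proportional_counts_give_flat_fitness(scheme_4x2):
    """Counts proportional across rounds (no enrichment) are explained by a
    flat landscape: pairwise fitness differences stay small."""
    import itertools

    seqs = ["".join(t) for t in itertools.product("FV", repeat=4)]
    base = {scheme_4x2.split(s): 100 + 10 * i for i, s in enumerate(seqs)}
    ds = SelectionDataset(
        scheme=scheme_4x2,
        rounds=["R0", "R1", "R2"],
        counts={"R0": dict(base), "R1": dict(base), "R2": dict(base)},
    )
    cfg = SPMFitConfig(
        max_epochs=800, val_fraction=0.0, dropout=0.0, learning_rate=0.01,
        patience=10**9, hidden_dim=20, n_layers=2, seed=1,
    )
    with pytest.warns(UserWarning):
        model = fit_spm(ds, cfg)
        f = model.score(seqs, round="R1")
        assert np.ptp(f) <= 0.1


def test_fit_is_deterministic_given_seed(scheme_2x2):
    m1 = fit_spm(two_seq_dataset(scheme_2x2), TOY_CFG)
    m2 = fit_spm(two_seq_dataset(scheme_2x2), TOY_CFG)
    assert np.array_equal(m1.score(["FF", "FV", "VV"]), m2.score(["FF", "FV", "VV"]))


def test_scoring_extrapolates_and_validates(scheme_2x2):
    model = fit_spm(two_seq_dataset(scheme_2x2), TOY_CFG)
    # 'FV' and 'VF' never appeared in training
    vals = model.score(["FV", "VF"])
    assert np.all(np.isfinite(vals))
    with pytest.raises(ValueError):
        model.score(["AA"])  # letters outside the alphabet
    with pytest.raises(KeyError):
        model.score(["FF"], round="R9")


def test_round_strengths_are_nonnegative(scheme_2x2):
    model = fit_spm(two_seq_dataset(scheme_2x2), TOY_CFG)
    assert np.all(model.round_strengths >= 0)


def test_gauge_invariance_of_predicted_counts(scheme_2x2):
    """Adding a constant to all fitnesses leaves the per-round distribution
    unchanged: predictions do not depend on the zero-mean gauge choice."""
    ds = two_seq_dataset(scheme_2x2)
    model = fit_spm(ds, TOY_CFG)
    before = predict_counts(model, ds)
    model.mean_g += 123.4  # shift the reported gauge
    after = predict_counts(model, ds)
    for k in before:
        assert before[k] == pytest.approx(after[k], rel=1e-9)


def test_full_batch_likelihood_decreases(scheme_2x2):
    cfg = SPMFitConfig(
        max_epochs=300, val_fraction=0.0, dropout=0.0, learning_rate=0.005,
        patience=10**9, hidden_dim=10, n_layers=1, seed=2,
    )
    model = fit_spm(two_seq_dataset(scheme_2x2), cfg)
    nll = np.array(model.history["nll"])
    assert nll[-1] < nll[0]
    # Adam can wiggle, but the running best must improve steadily
    running_best = np.minimum.accumulate(nll)
    assert running_best[-1] <= running_best[len(nll) // 2] + 1e-12


def test_predicted_counts_sum_to_round_total(scheme_4x2):
    land = sample_landscape(scheme_4x2, seed=0)
    ds = simulate_selection(land, SelectionConfig(n_rounds=2, depth=4000, seed=1))
    cfg = SPMFitConfig(max_epochs=50, val_fraction=0.0, hidden_dim=20, n_layers=2, seed=0)
    model = fit_spm(ds, cfg)
    pred = predict_counts(model, ds)
    assert sum(pred.values()) == pytest.approx(ds.totals[ds.final_round], rel=1e-6)


def test_crossvalidate_single_config(scheme_4x2):
    land = sample_landscape(scheme_4x2, seed=2)
    ds = simulate_selection(land, SelectionConfig(n_rounds=2, depth=4000, seed=3))
    cfg = SPMFitConfig(max_epochs=40, hidden_dim=10, n_layers=1, val_fraction=0.0, seed=0)
    best, scores = crossvalidate(ds, [cfg], n_folds=5, seed=0)
    assert best is cfg
    assert len(scores[0]) == 5
    with pytest.raises(ValueError):
        crossvalidate(ds, [], n_folds=5)


def test_capacity_ordering_on_epistatic_landscape():
    """When the true landscape has pairwise terms, a hidden-layer model beats
    a purely linear one on held-out final-round counts (seed majority)."""
    scheme = LibraryScheme(chain_a_positions=(1, 2), chain_b_positions=(3,), alphabet=("F", "V", "L"))
    wins = 0
    n_seeds = 5
    for seed in range(n_seeds):
        land = sample_landscape(
            scheme, additive_scale=0.3, pairwise_scale=1.5, pairwise_density=1.0, seed=seed
        )
        ds = simulate_selection(
            land, SelectionConfig(n_rounds=3, depth=30_000, stringency=2.0, seed=100 + seed)
        )
        common = dict(max_epochs=150, learning_rate=0.01, val_fraction=0.0, dropout=0.0, seed=seed)
        linear = SPMFitConfig(n_layers=0, hidden_dim=1, **common)
        deep = SPMFitConfig(n_layers=2, hidden_dim=20, **common)
        _, scores = crossvalidate(ds, [linear, deep], n_folds=3, seed=seed)
        if np.mean(scores[1]) < np.mean(scores[0]):
            wins += 1
    assert wins > n_seeds // 2


def test_bootstrap_preserves_totals_and_means(scheme_4x2):
    land = sample_landscape(scheme_4x2, seed=5)
    ds = simulate_selection(land, SelectionConfig(n_rounds=2, depth=2000, seed=6))
    reps = list(bootstrap_datasets(ds, 1000, seed=7))
    assert len(reps) == 1000
    totals = ds.totals
    for b in reps[:50]:
        assert b.totals == totals
    # expected bootstrap count of a sequence equals its observed count
    target = max(ds.counts[ds.final_round], key=ds.counts[ds.final_round].get)
    obs = ds.counts[ds.final_round][target]
    draws = np.array([b.counts[b.final_round].get(target, 0) for b in reps])
    se = draws.std(ddof=1) / np.sqrt(len(draws))
    assert abs(draws.mean() - obs) < 3 * se + 1e-9


def test_model_serialization_roundtrip(tmp_path, scheme_2x2):
    model = fit_spm(two_seq_dataset(scheme_2x2), TOY_CFG)
    path = tmp_path / "model.npz"
    model.save(path)
    from coevoscape import FitnessModel

    back = FitnessModel.load(path)
    seqs = ["FF", "FV", "VF", "VV"]
    assert np.allclose(model.score(seqs), back.score(seqs))
    assert np.allclose(
        score_sequences(model, seqs, round="R1"), score_sequences(back, seqs, round="R1")
    )
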