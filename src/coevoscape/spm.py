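"""Selection probabilistic model (SPM): fitness inference from read counts.

The SPM is a generative model of a multi-round selection experiment.  Writing
q_r for the sequence distribution entering round r+1, each round applies a
selection factor exp(f_r(x)) and renormalizes,

    q_r(x) = q_{r-1}(x) * exp(f_r(x)) / Z_r,

and the observed read counts of round r are a Multinomial(total_r, q_r)
draw.  The per-round fitness is parametrized through a shared neural trunk
g_theta (one-hot input, fully connected ReLU layers) with non-negative
per-round couplings, f_r(x) = a_r * g_theta(x) + b_r, so the trunk g_theta is
the global fitness landscape.  Because the per-round additive offsets b_r
cancel in the normalized distribution, the likelihood only identifies
fitness up to a per-round constant (gauge freedom); reported scores fix the
gauge by zero mean over the training universe.

With model-propagated q_r the chain telescopes: q_r(x) is proportional to
q_0(x) * exp(A_r g(x)) with A_r = a_1 + ... + a_r, which the trainer exploits
for an exact full-likelihood gradient.  q_0 is the additively smoothed
round-0 empirical distribution.  A plug-in variant (q_{r-1} replaced by the
previous round's smoothed empirical frequencies) is available for debugging.

No GPU framework is used: the trunk, backprop, dropout and the Adam update
are implemented directly on numpy arrays; the reference scale is CPU minutes
on reduced schemes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .library import LibraryScheme, SelectionDataset

__all__ = [
    "SPMFitConfig",
    "FitnessModel",
    "fit_spm",
    "score_sequences",
    "crossvalidate",
    "bootstrap_datasets",
    "one_hot",
]


def one_hot(sequences: Sequence[str], scheme: LibraryScheme) -> np.ndarray:
    """One-hot encode concatenated sequences: (n, L * A) float32."""
    from .simulate import encode

    idx = encode(list(sequences), scheme)
    n, L = idx.shape
    A = scheme.n_letters
    X = np.zeros((n, L * A), dtype=np.float32)
    X[np.arange(n)[:, None], np.arange(L) * A + idx] = 1.0
    return X


@dataclass
class SPMFitConfig:
    """Training hyperparameters (defaults follow the published protocol)."""

    learning_rate: float = 1e-3
    batch_size: int = 10_000
    weight_decay: float = 1e-5
    dropout: float = 0.1
    hidden_dim: int = 100
    n_layers: int = 4
    max_epochs: int = 500
    patience: int = 25
    val_fraction: float = 0.1
    smoothing: float = 0.5
    propagation: str = "chain"  # "chain" (generative) or "plugin" (empirical)
    seed: int = 0

    def __post_init__(self):
        for name in ("learning_rate", "batch_size", "hidden_dim", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.propagation not in ("chain", "plugin"):
            raise ValueError("propagation must be 'chain' or 'plugin'")


class _MLP:
    """Minimal fully connected ReLU network with scalar output."""

    def __init__(self, in_dim: int, hidden: int, n_layers: int, rng: np.random.Generator):
        dims = [in_dim] + [hidden] * n_layers + [1]
        self.weights = [
            rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1])).astype(np.float64)
            for i in range(len(dims) - 1)
        ]
        self.biases = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]

    @property
    def params(self):
        return self.weights + self.biases

    def forward(self, X, dropout: float = 0.0, rng: Optional[np.random.Generator] = None):
        h = X.astype(np.float64)
        cache = []
        n_hidden = len(self.weights) - 1
        for layer in range(n_hidden):
            z = h @ self.weights[layer] + self.biases[layer]
            mask = z > 0
            a = np.where(mask, z, 0.0)
            drop = None
            if dropout > 0.0 and rng is not None:
                drop = (rng.random(a.shape) >= dropout) / (1.0 - dropout)
                a = a * drop
            cache.append((h, mask, drop))
            h = a
        g = (h @ self.weights[-1] + self.biases[-1])[:, 0]
        cache.append((h, None, None))
        return g, cache

    def backward(self, cache, dg):
        """Gradients of sum(dg * g) w.r.t. weights and biases."""
        gw = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        h_last = cache[-1][0]
        delta = dg[:, None]  # (n, 1)
        gw[-1] = h_last.T @ delta
        gb[-1] = delta.sum(axis=0)
        grad_h = delta @ self.weights[-1].T
        for layer in range(len(self.weights) - 2, -1, -1):
            h_in, mask, drop = cache[layer]
            if drop is not None:
                grad_h = grad_h * drop
            grad_z = grad_h * mask
            gw[layer] = h_in.T @ grad_z
            gb[layer] = grad_z.sum(axis=0)
            if layer > 0:
                grad_h = grad_z @ self.weights[layer].T
        return gw + gb


class _Adam:
    def __init__(self, params, lr, weight_decay=0.0, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.wd, self.b1, self.b2, self.eps = lr, weight_decay, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            g = g + self.wd * p
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _softplus(x):
    return np.logaddexp(0.0, x)


def _softplus_inv(y):
    return y + np.log(-np.expm1(-y))


@dataclass
class FitnessModel:
    """Fitted SPM: a trunk network plus per-round couplings.

    ``score``/``score_sequences`` evaluate the gauge-fixed global fitness
    g(x) - mean(g) or a per-round fitness a_r * (g(x) - mean(g)).  Inference
    is deterministic (dropout disabled).
    """

    scheme: LibraryScheme
    mlp: _MLP
    rho: np.ndarray  # softplus(rho) = per-round selection strengths a_r
    selection_rounds: list  # round labels R1..RR (round 0 is the input pool)
    mean_g: float
    config: SPMFitConfig
    history: dict = field(default_factory=dict)

    @property
    def round_strengths(self) -> np.ndarray:
        return _softplus(self.rho)

    def score(self, sequences: Sequence[str], round: str = "global") -> np.ndarray:
        seqs = list(sequences)
        chunk = max(1, int(self.config.batch_size))
        parts = []
        for start in range(0, len(seqs), chunk):
            X = one_hot(seqs[start : start + chunk], self.scheme)
            gi, _ = self.mlp.forward(X)
            parts.append(gi)
        g = np.concatenate(parts) if parts else np.empty(0)
        g = g - self.mean_g
        if round == "global":
            return g
        if round not in self.selection_rounds:
            raise KeyError(
                f"unknown round {round!r}; selection rounds are {self.selection_rounds}"
            )
        r = self.selection_rounds.index(round)
        return float(self.round_strengths[r]) * g

    def save(self, path) -> None:
        arch = {
            "chain_a_positions": list(self.scheme.chain_a_positions),
            "chain_b_positions": list(self.scheme.chain_b_positions),
            "degenerate_codon": self.scheme.degenerate_codon,
            "alphabet": "".join(self.scheme.alphabet),
            "hidden_dim": self.config.hidden_dim,
            "n_layers": self.config.n_layers,
            "selection_rounds": self.selection_rounds,
            "mean_g": self.mean_g,
            "rho": self.rho.tolist(),
            "shapes": [list(p.shape) for p in self.mlp.params],
        }
        flat = np.concatenate([p.ravel() for p in self.mlp.params])
        np.savez(path, arch=json.dumps(arch), params=flat)

    @classmethod
    def load(cls, path) -> "FitnessModel":
        data = np.load(path, allow_pickle=False)
        arch = json.loads(str(data["arch"]))
        scheme = LibraryScheme(
            chain_a_positions=tuple(arch["chain_a_positions"]),
            chain_b_positions=tuple(arch["chain_b_positions"]),
            degenerate_codon=arch["degenerate_codon"],
            alphabet=tuple(arch["alphabet"]),
        )
        cfg = SPMFitConfig(hidden_dim=arch["hidden_dim"], n_layers=arch["n_layers"])
        mlp = _MLP(
            scheme.total_positions * scheme.n_letters,
            arch["hidden_dim"],
            arch["n_layers"],
            np.random.default_rng(0),
        )
        flat = data["params"]
        offset = 0
        for i, shape in enumerate(arch["shapes"]):
            size = int(np.prod(shape))
            mlp.params[i][...] = flat[offset : offset + size].reshape(shape)
            offset += size
        return cls(
            scheme=scheme,
            mlp=mlp,
            rho=np.asarray(arch["rho"], dtype=float),
            selection_rounds=list(arch["selection_rounds"]),
            mean_g=float(arch["mean_g"]),
            config=cfg,
        )


def _prepare(dataset: SelectionDataset, smoothing: float):
    """Universe, one-hot matrix, per-round count matrix, smoothed q0."""
    universe = ["".join(pair) for pair in dataset.sequences()]
    index = {s: i for i, s in enumerate(universe)}
    n_rounds = len(dataset.rounds)
    C = np.zeros((n_rounds, len(universe)))
    for r, label in enumerate(dataset.rounds):
        for (a, b), c in dataset.counts[label].items():
            C[r, index[a + b]] = c
    q0 = (C[0] + smoothing) / (C[0].sum() + smoothing * len(universe))
    return universe, C, q0


def fit_spm(dataset: SelectionDataset, config: Optional[SPMFitConfig] = None) -> FitnessModel:
    """Maximize the multinomial selection likelihood over trunk + couplings.

    Requires at least two rounds (round 0 plus one selection round); a single
    round leaves selection unidentifiable.  Training is full-likelihood: the
    normalizing constants couple all universe sequences, so every epoch
    evaluates the trunk on the whole observed universe (scoring chunks its
    forward passes by ``batch_size`` to bound memory).  Early stopping monitors the
    count MSE on a held-out fraction of final-round sequences.
    """
    config = config or SPMFitConfig()
    if len(dataset.rounds) < 2:
        raise ValueError("need at least two rounds; selection is unidentifiable from one")
    for r in dataset.rounds:
        if not dataset.counts[r]:
            raise ValueError(f"round {r!r} is empty")

    universe, C, q0 = _prepare(dataset, config.smoothing)
    scheme = dataset.scheme
    X = one_hot(universe, scheme)
    R = len(dataset.rounds) - 1  # selection rounds
    Csel = C[1:]
    n_r = Csel.sum(axis=1)
    total = Csel.sum()
    log_q0 = np.log(q0)

    if config.propagation == "plugin":
        # base log-weights per round: previous round's smoothed empirical freqs
        bases = np.empty((R, len(universe)))
        for r in range(R):
            prev = C[r]
            bases[r] = np.log((prev + config.smoothing) / (prev.sum() + config.smoothing * len(universe)))
    else:
        bases = np.tile(log_q0, (R, 1))

    rng = np.random.default_rng(config.seed)
    mlp = _MLP(X.shape[1], config.hidden_dim, config.n_layers, rng)
    rho = np.full(R, _softplus_inv(1.0))

    # held-out split over final-round support for early stopping
    val_idx = np.array([], dtype=int)
    if config.val_fraction > 0:
        support = np.flatnonzero(Csel[-1] > 0)
        n_val = int(round(config.val_fraction * len(support)))
        if n_val >= 1 and len(support) - n_val >= 2:
            val_idx = rng.choice(support, n_val, replace=False)
    train_mask = np.ones_like(Csel)
    train_mask[-1, val_idx] = 0.0
    Ctrain = Csel * train_mask
    train_total = max(Ctrain.sum(), 1.0)

    opt = _Adam(mlp.params + [rho], config.learning_rate, config.weight_decay)
    best = None
    best_metric = np.inf
    since_best = 0
    history = {"nll": [], "val_mse": []}

    for epoch in range(config.max_epochs):
        g, cache = mlp.forward(X, dropout=config.dropout, rng=rng)
        a = _softplus(rho)
        K = np.cumsum(a) if config.propagation == "chain" else a
        logits = bases + K[:, None] * g[None, :]
        logits -= logits.max(axis=1, keepdims=True)
        q = np.exp(logits)
        q /= q.sum(axis=1, keepdims=True)
        logq = np.log(q + 1e-300)

        nll = -(Ctrain * logq).sum() / train_total
        # d(-sum C log q)/d logit_r(y) = n_train_r * q_r(y) - Ctrain_r(y)
        n_train = Ctrain.sum(axis=1)
        resid = n_train[:, None] * q - Ctrain
        dg = (K[:, None] * resid).sum(axis=0) / train_total
        grads = mlp.backward(cache, dg)
        dK = (resid * g[None, :]).sum(axis=1)
        if config.propagation == "chain":
            # dL/da_t = sum_{r >= t} dL/dK_r
            da = np.cumsum(dK[::-1])[::-1]
        else:
            da = dK
        drho = da * _sigmoid(rho) / train_total
        opt.step(mlp.params + [rho], grads + [drho])

        history["nll"].append(float(nll))
        if len(val_idx):
            g_eval, _ = mlp.forward(X)
            K_eval = np.cumsum(_softplus(rho)) if config.propagation == "chain" else _softplus(rho)
            lf = bases[-1] + K_eval[-1] * g_eval
            lf -= lf.max()
            qf = np.exp(lf)
            qf /= qf.sum()
            pred = n_r[-1] * qf[val_idx]
            val_mse = float(np.mean((pred - Csel[-1, val_idx]) ** 2))
            history["val_mse"].append(val_mse)
            metric = val_mse
        else:
            metric = float(nll)
        if metric < best_metric - 1e-9:
            best_metric = metric
            best = ([p.copy() for p in mlp.params], rho.copy())
            since_best = 0
        else:
            since_best += 1
            if since_best > config.patience:
                break

    if best is not None:
        for p, bp in zip(mlp.params, best[0]):
            p[...] = bp
        rho = best[1]

    g_final, _ = mlp.forward(X)
    model = FitnessModel(
        scheme=scheme,
        mlp=mlp,
        rho=rho,
        selection_rounds=list(dataset.rounds[1:]),
        mean_g=float(g_final.mean()),
        config=config,
        history=history,
    )
    flat_span = float(_softplus(rho).max() * np.ptp(g_final))
    if flat_span < 1e-2:
        import warnings

        warnings.warn(
            "fitted selection is (near-)flat: no round separates sequences by "
            f"more than {flat_span:.2g} fitness units",
            stacklevel=2,
        )
    return model


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def score_sequences(model: FitnessModel, sequences: Sequence[str], round: str = "global") -> np.ndarray:
    """Score sequences with a fitted model ('global' or a round label).

    Extrapolates to sequences never observed in training (the walk simulator
    relies on this to cover the full combinatorial space).
    """
    return model.score(sequences, round=round)


def predict_counts(model: FitnessModel, dataset: SelectionDataset, round_label: Optional[str] = None) -> dict:
    """Expected read counts total_r * q_r(x) over the dataset universe."""
    config = model.config
    universe, C, q0 = _prepare(dataset, config.smoothing)
    g = model.score(universe)  # gauge shift cancels in the softmax below
    r_lab = round_label or dataset.final_round
    r = dataset.rounds.index(r_lab)
    if r == 0:
        raise ValueError("round 0 is the input pool; no selection to predict")
    a = model.round_strengths
    if config.propagation == "chain":
        K = float(np.cumsum(a)[r - 1])
        base = np.log(q0)
    else:
        K = float(a[r - 1])
        prev = C[r - 1]
        base = np.log((prev + config.smoothing) / (prev.sum() + config.smoothing * len(universe)))
    logits = base + K * g
    logits -= logits.max()
    q = np.exp(logits)
    q /= q.sum()
    n_r = C[r].sum()
    return dict(zip(universe, n_r * q))


def crossvalidate(
    dataset: SelectionDataset,
    grid: Sequence[SPMFitConfig],
    n_folds: int = 5,
    seed: int = 0,
):
    """Select hyperparameters by k-fold CV on the final selection round.

    Folds partition the final-round sequences; each fit uses all previous
    rounds plus the remaining final-round counts, and is scored by the MSE
    between predicted counts total_R * q_R(x) and held-out observations.
    Returns (best config, {config index: fold MSE list}).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    rng = np.random.default_rng(seed)
    final = dataset.final_round
    support = sorted(dataset.counts[final])
    order = rng.permutation(len(support))
    folds = [sorted(order[i::n_folds]) for i in range(n_folds)]

    scores = {}
    for ci, cfg in enumerate(grid):
        fold_mse = []
        for fold in folds:
            held = {support[i] for i in fold}
            train_counts = {
                r: (
                    {k: v for k, v in dataset.counts[r].items() if k not in held}
                    if r == final
                    else dict(dataset.counts[r])
                )
                for r in dataset.rounds
            }
            if not train_counts[final]:
                continue
            sub = SelectionDataset(dataset.scheme, list(dataset.rounds), train_counts)
            cfg_fold = replace(cfg, val_fraction=0.0)
            model = fit_spm(sub, cfg_fold)
            # predict on the full dataset so held-out sequences get expected counts
            pred = predict_counts(model, dataset, final)
            obs = dataset.counts[final]
            mse = float(
                np.mean([(pred["".join(k)] - obs.get(k, 0)) ** 2 for k in held])
            )
            fold_mse.append(mse)
        scores[ci] = fold_mse
    best_ci = min(scores, key=lambda ci: float(np.mean(scores[ci])))
    return grid[best_ci], scores


def bootstrap_datasets(dataset: SelectionDataset, B: int = 1000, seed: int = 0):
    """Yield B multinomial resamples of the read counts, totals preserved.

    Each replicate redraws every round's counts from Multinomial(total_r,
    empirical frequencies of round r).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    per_round = []
    for r in dataset.rounds:
        items = sorted(dataset.counts[r].items())
        seqs = [k for k, _ in items]
        c = np.array([v for _, v in items], dtype=float)
        per_round.append((r, seqs, c / c.sum(), int(c.sum())))
    for _ in range(B):
        counts = {}
        for r, seqs, freqs, total in per_round:
            draw = rng.multinomial(total, freqs)
            counts[r] = {seqs[i]: int(draw[i]) for i in np.flatnonzero(draw)}
        yield SelectionDataset(dataset.scheme, list(dataset.rounds), counts)
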