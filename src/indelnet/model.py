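"""The RoseNet-style regressor and its training loop.

The network maps the four categorical inputs of a double-insertion mutant —
two insertion slots and two inserted amino acids — through embedding tables
(dimension 200 each) to a concatenated 4x200 representation, passes it
through one block of fully connected layers with batch normalization and
ReLU, adds the block input back via an identity skip connection, and applies
a final linear layer (no output non-linearity) to predict the 18 retained
z-scored energy terms.  Training uses the NAdam optimizer with Huber loss,
batch size 64 and learning rate 1e-5, with early stopping on validation
loss.

Everything here is plain NumPy: forward, backward and the optimizer are
implemented explicitly so that inference is a pure deterministic function of
(parameters, key) and training is reproducible from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import AMINO_ACIDS, KEY_COLUMNS, RETAINED_SCORES, MutantDataset, MutantKey
from .preprocess import NormalizationStats
from .splits import SplitResult

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``hidden_width`` defaults to the concatenation width (4 x embedding_dim)
    so the skip connection is a plain addition without a projection.
    Embedding tables are shared across the two position slots and across the
    two residue slots by default; slot identity is carried by concatenation
    order."""

    position_vocab: int
    embedding_dim: int = 200
    aa_vocab: int = 20
    n_block_layers: int = 2
    hidden_width: int | None = None
    n_outputs: int = 18
    share_position_table: bool = True
    share_aa_table: bool = True

    def __post_init__(self) -> None:
        if self.hidden_width is None:
            self.hidden_width = 4 * self.embedding_dim
        if self.hidden_width != 4 * self.embedding_dim:
            raise ValueError(
                "hidden_width must equal the concatenation width "
                f"(4 x embedding_dim = {4 * self.embedding_dim}) for the "
                "identity skip connection"
            )
        if self.position_vocab < 2 or self.aa_vocab < 2:
            raise ValueError("vocabulary sizes must be >= 2")
        if self.n_block_layers < 1:
            raise ValueError("need at least one block layer")


@dataclass
class TrainConfig:
    """Optimization hyperparameters: NAdam, lr 1e-5, batch 64, Huber loss."""

    learning_rate: float = 1e-5
    batch_size: int = 64
    huber_delta: float = 1.0
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.huber_delta <= 0:
            raise ValueError("huber_delta must be positive")


def huber(residual, delta: float = 1.0):
    """Elementwise Huber loss: r^2/2 for |r| <= delta, else
    delta * (|r| - delta/2)."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    r = np.abs(np.asarray(residual, dtype=float))
    out = np.where(r <= delta, 0.5 * r * r, delta * (r - 0.5 * delta))
    return out if out.ndim else float(out)


def _init_params(cfg: ModelConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """He-style initialization; batch-norm scale 1 / shift 0."""
    d, w = cfg.embedding_dim, cfg.hidden_width
    p: dict[str, np.ndarray] = {}

    def table(name: str, vocab: int) -> None:
        p[name] = rng.normal(0.0, 1.0, size=(vocab, d)).astype(np.float32)

    if cfg.share_position_table:
        table("emb_pos", cfg.position_vocab)
    else:
        table("emb_pos1", cfg.position_vocab)
        table("emb_pos2", cfg.position_vocab)
    if cfg.share_aa_table:
        table("emb_aa", cfg.aa_vocab)
    else:
        table("emb_aa1", cfg.aa_vocab)
        table("emb_aa2", cfg.aa_vocab)

    for i in range(cfg.n_block_layers):
        p[f"W{i}"] = rng.normal(0.0, np.sqrt(2.0 / w), size=(w, w)).astype(np.float32)
        p[f"b{i}"] = np.zeros(w, dtype=np.float32)
        p[f"gamma{i}"] = np.ones(w, dtype=np.float32)
        p[f"beta{i}"] = np.zeros(w, dtype=np.float32)
    # the output head starts at zero so initial predictions equal the target
    # mean (z-scored targets: 0) and early training fits a linear readout of
    # the initial features before reshaping the trunk
    p["Wo"] = np.zeros((w, cfg.n_outputs), dtype=np.float32)
    p["bo"] = np.zeros(cfg.n_outputs, dtype=np.float32)
    return p


def _init_running(cfg: ModelConfig) -> dict[str, np.ndarray]:
    r = {}
    for i in range(cfg.n_block_layers):
        r[f"rmean{i}"] = np.zeros(cfg.hidden_width, dtype=np.float32)
        r[f"rvar{i}"] = np.ones(cfg.hidden_width, dtype=np.float32)
    return r


@dataclass
class ModelState:
    """Learned tensors plus the configuration and the normalization
    statistics used at fit time, sufficient to reproduce forward outputs
    bit-exactly in inference mode."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    running: dict[str, np.ndarray]
    score_names: tuple[str, ...] = tuple(RETAINED_SCORES)
    norm_stats: NormalizationStats | None = None

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.npz`` (tensors) and ``<prefix>.json`` (config,
        score-name order, normalization stats)."""
        prefix = Path(prefix)
        arrays = {f"p__{k}": v for k, v in self.params.items()}
        arrays.update({f"r__{k}": v for k, v in self.running.items()})
        np.savez(prefix.with_suffix(".npz"), **arrays)
        side = {
            "config": {
                "position_vocab": self.config.position_vocab,
                "embedding_dim": self.config.embedding_dim,
                "aa_vocab": self.config.aa_vocab,
                "n_block_layers": self.config.n_block_layers,
                "hidden_width": self.config.hidden_width,
                "n_outputs": self.config.n_outputs,
                "share_position_table": self.config.share_position_table,
                "share_aa_table": self.config.share_aa_table,
            },
            "score_names": list(self.score_names),
            "norm_stats": None
            if self.norm_stats is None
            else {
                "mean": {k: float(v) for k, v in self.norm_stats.mean.items()},
                "sd": {k: float(v) for k, v in self.norm_stats.sd.items()},
            },
        }
        prefix.with_suffix(".json").write_text(json.dumps(side, indent=2))

    @classmethod
    def load(cls, prefix: str | Path) -> "ModelState":
        prefix = Path(prefix)
        side = json.loads(prefix.with_suffix(".json").read_text())
        cfg = ModelConfig(**side["config"])
        data = np.load(prefix.with_suffix(".npz"))
        params = {k[3:]: data[k] for k in data.files if k.startswith("p__")}
        running = {k[3:]: data[k] for k in data.files if k.startswith("r__")}
        stats = None
        if side["norm_stats"] is not None:
            stats = NormalizationStats(
                mean=pd.Series(side["norm_stats"]["mean"]),
                sd=pd.Series(side["norm_stats"]["sd"]),
            )
        return cls(
            config=cfg,
            params=params,
            running=running,
            score_names=tuple(side["score_names"]),
            norm_stats=stats,
        )


def count_parameters(state: ModelState) -> int:
    """Total learned scalar count (batch-norm running statistics excluded)."""
    return int(sum(v.size for v in state.params.values()))


def initialize(cfg: ModelConfig, seed: int = 0,
               norm_stats: NormalizationStats | None = None,
               score_names: tuple[str, ...] = tuple(RETAINED_SCORES)) -> ModelState:
    rng = np.random.default_rng(seed)
    return ModelState(
        config=cfg,
        params=_init_params(cfg, rng),
        running=_init_running(cfg),
        score_names=score_names,
        norm_stats=norm_stats,
    )


# --------------------------------------------------------------------------
# forward / backward


def _embed(state: ModelState, p1, p2, a1, a2) -> np.ndarray:
    p = state.params
    ep1 = p["emb_pos" if state.config.share_position_table else "emb_pos1"]
    ep2 = p["emb_pos" if state.config.share_position_table else "emb_pos2"]
    ea1 = p["emb_aa" if state.config.share_aa_table else "emb_aa1"]
    ea2 = p["emb_aa" if state.config.share_aa_table else "emb_aa2"]
    return np.concatenate([ep1[p1], ep2[p2], ea1[a1], ea2[a2]], axis=1)


def _forward(
    state: ModelState, x: np.ndarray, training: bool
) -> tuple[np.ndarray, list[dict]]:
    """Block forward; returns predictions and per-layer caches for backprop."""
    p, cfg = state.params, state.config
    h = x
    caches: list[dict] = []
    for i in range(cfg.n_block_layers):
        z = h @ p[f"W{i}"] + p[f"b{i}"]
        if training:
            mu = z.mean(axis=0)
            var = z.var(axis=0)
            state.running[f"rmean{i}"] = (
                (1 - _BN_MOMENTUM) * state.running[f"rmean{i}"] + _BN_MOMENTUM * mu
            ).astype(np.float32)
            state.running[f"rvar{i}"] = (
                (1 - _BN_MOMENTUM) * state.running[f"rvar{i}"] + _BN_MOMENTUM * var
            ).astype(np.float32)
        else:
            mu = state.running[f"rmean{i}"]
            var = state.running[f"rvar{i}"]
        inv_sd = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (z - mu) * inv_sd
        bn = p[f"gamma{i}"] * xhat + p[f"beta{i}"]
        relu_mask = bn > 0
        h_next = bn * relu_mask
        caches.append(
            {"h_in": h, "xhat": xhat, "inv_sd": inv_sd, "relu_mask": relu_mask,
             "training": training}
        )
        h = h_next
    block_out = h + x  # identity skip over the whole block
    y = block_out @ p["Wo"] + p["bo"]
    caches.append({"block_out": block_out})
    return y, caches


def _backward(
    state: ModelState, x: np.ndarray, caches: list[dict], dy: np.ndarray
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Gradients of the loss w.r.t. all parameters and the embedding input."""
    p, cfg = state.params, state.config
    grads: dict[str, np.ndarray] = {}
    block_out = caches[-1]["block_out"]
    grads["Wo"] = block_out.T @ dy
    grads["bo"] = dy.sum(axis=0)
    dblock = dy @ p["Wo"].T
    dh = dblock
    dx = dblock.copy()  # skip branch
    m = x.shape[0]
    for i in reversed(range(cfg.n_block_layers)):
        c = caches[i]
        dbn = dh * c["relu_mask"]
        grads[f"gamma{i}"] = (dbn * c["xhat"]).sum(axis=0)
        grads[f"beta{i}"] = dbn.sum(axis=0)
        dxhat = dbn * p[f"gamma{i}"]
        if c["training"] and m > 1:
            dz = (c["inv_sd"] / m) * (
                m * dxhat
                - dxhat.sum(axis=0)
                - c["xhat"] * (dxhat * c["xhat"]).sum(axis=0)
            )
        else:
            dz = dxhat * c["inv_sd"]
        grads[f"W{i}"] = c["h_in"].T @ dz
        grads[f"b{i}"] = dz.sum(axis=0)
        dh = dz @ p[f"W{i}"].T
        if i == 0:
            dx += dh
        # dh now flows into the previous layer's output (or x when i == 0)
    return grads, dx


def _accumulate_embedding_grads(
    state: ModelState, grads: dict[str, np.ndarray], dx: np.ndarray,
    p1, p2, a1, a2,
) -> None:
    cfg = state.config
    d = cfg.embedding_dim
    chunks = [dx[:, :d], dx[:, d : 2 * d], dx[:, 2 * d : 3 * d], dx[:, 3 * d :]]

    def scatter(name: str, idx: np.ndarray, g: np.ndarray) -> None:
        if name not in grads:
            grads[name] = np.zeros_like(state.params[name])
        np.add.at(grads[name], idx, g)

    if cfg.share_position_table:
        scatter("emb_pos", p1, chunks[0])
        scatter("emb_pos", p2, chunks[1])
    else:
        scatter("emb_pos1", p1, chunks[0])
        scatter("emb_pos2", p2, chunks[1])
    if cfg.share_aa_table:
        scatter("emb_aa", a1, chunks[2])
        scatter("emb_aa", a2, chunks[3])
    else:
        scatter("emb_aa1", a1, chunks[2])
        scatter("emb_aa2", a2, chunks[3])


def forward(state: ModelState, key: MutantKey) -> pd.Series:
    """Inference-mode prediction for one mutant, on the normalized scale."""
    df = pd.DataFrame(
        [{"p1": key.p1, "p2": key.p2, "a1": key.a1, "a2": key.a2}]
    )
    return pd.Series(predict(state, df)[0], index=list(state.score_names))


def _encode_keys(state: ModelState, keys: pd.DataFrame):
    cfg = state.config
    p1 = keys["p1"].to_numpy(dtype=np.int64) - 1
    p2 = keys["p2"].to_numpy(dtype=np.int64) - 1
    if (p1 < 0).any() or (p2 >= cfg.position_vocab).any():
        bad = int(keys["p2"].max())
        raise ValueError(
            f"insertion slot {bad} outside position vocabulary 1..{cfg.position_vocab}"
        )
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    a1 = np.array([aa_index[a] for a in keys["a1"]], dtype=np.int64)
    a2 = np.array([aa_index[a] for a in keys["a2"]], dtype=np.int64)
    return p1, p2, a1, a2


def predict(state: ModelState, keys: pd.DataFrame, batch_size: int = 4096) -> np.ndarray:
    """Inference-mode predictions (normalized scale) for a key frame."""
    p1, p2, a1, a2 = _encode_keys(state, keys)
    outs = []
    for start in range(0, len(keys), batch_size):
        sl = slice(start, start + batch_size)
        x = _embed(state, p1[sl], p2[sl], a1[sl], a2[sl])
        y, _ = _forward(state, x, training=False)
        outs.append(y)
    return np.concatenate(outs, axis=0)


# --------------------------------------------------------------------------
# optimizer


class NAdam:
    """Nesterov-accelerated Adam (Dozat's formulation, bias-corrected
    lookahead momentum)."""

    def __init__(self, params: dict[str, np.ndarray], cfg: TrainConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        c = self.cfg
        self.t += 1
        t = self.t
        bc1 = 1.0 - c.beta1**t
        bc1_next = 1.0 - c.beta1 ** (t + 1)
        bc2 = 1.0 - c.beta2**t
        for k, g in grads.items():
            m = self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            v = self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            m_hat = c.beta1 * m / bc1_next + (1 - c.beta1) * g / bc1
            v_hat = v / bc2
            params[k] -= (c.learning_rate * m_hat / (np.sqrt(v_hat) + c.eps)).astype(
                params[k].dtype
            )


# --------------------------------------------------------------------------
# training


def _split_arrays(
    dataset: MutantDataset, keys: pd.DataFrame, score_names: tuple[str, ...]
):
    merged = keys.merge(dataset.scores, on=list(KEY_COLUMNS), how="left", sort=False)
    if merged[list(score_names)].isna().any().any():
        raise ValueError("split contains keys absent from the dataset")
    return merged[list(KEY_COLUMNS)], merged[list(score_names)].to_numpy(np.float32)


def _mean_loss(state: ModelState, keys_enc, targets, delta: float,
               batch_size: int = 4096) -> float:
    p1, p2, a1, a2 = keys_enc
    total, n = 0.0, 0
    for start in range(0, len(targets), batch_size):
        sl = slice(start, start + batch_size)
        x = _embed(state, p1[sl], p2[sl], a1[sl], a2[sl])
        y, _ = _forward(state, x, training=False)
        total += huber(y - targets[sl], delta).sum()
        n += targets[sl].size
    return total / n


def train(
    dataset: MutantDataset,
    splits: SplitResult,
    mcfg: ModelConfig,
    tcfg: TrainConfig,
    norm_stats: NormalizationStats | None = None,
    verbose: bool = False,
) -> tuple[ModelState, list[dict]]:
    """Fit the regressor on the train split, early-stopping on validation
    Huber loss (patience ``tcfg.patience``); returns the best-validation
    state and a per-epoch log of train/val losses."""
    if not dataset.normalized:
        raise ValueError("dataset must be z-score normalized before training")
    if len(splits.train) == 0 or len(splits.val) == 0:
        raise ValueError("train and val splits must be non-empty")

    score_names = tuple(c for c in dataset.score_columns)
    if len(score_names) != mcfg.n_outputs:
        raise ValueError(
            f"model predicts {mcfg.n_outputs} outputs but dataset has "
            f"{len(score_names)} score columns"
        )
    state = initialize(mcfg, seed=tcfg.seed, norm_stats=norm_stats,
                       score_names=score_names)
    train_keys, train_y = _split_arrays(dataset, splits.train, score_names)
    val_keys, val_y = _split_arrays(dataset, splits.val, score_names)
    tr_enc = _encode_keys(state, train_keys)
    va_enc = _encode_keys(state, val_keys)

    opt = NAdam(state.params, tcfg)
    rng = np.random.default_rng(tcfg.seed + 1)
    n = len(train_y)
    log: list[dict] = []
    best_val = np.inf
    best_params = None
    best_running = None
    bad_epochs = 0

    for epoch in range(tcfg.max_epochs):
        perm = rng.permutation(n)
        epoch_loss, n_seen = 0.0, 0
        for start in range(0, n, tcfg.batch_size):
            idx = perm[start : start + tcfg.batch_size]
            if len(idx) < 2:
                continue  # batch-norm needs at least 2 samples
            p1, p2, a1, a2 = (a[idx] for a in tr_enc)
            t = train_y[idx]
            x = _embed(state, p1, p2, a1, a2)
            y, caches = _forward(state, x, training=True)
            r = y - t
            epoch_loss += huber(r, tcfg.huber_delta).sum()
            n_seen += r.size
            dy = (np.clip(r, -tcfg.huber_delta, tcfg.huber_delta) / r.size).astype(
                np.float32
            )
            grads, dx = _backward(state, x, caches, dy)
            _accumulate_embedding_grads(state, grads, dx, p1, p2, a1, a2)
            opt.step(state.params, grads)
        val_loss = _mean_loss(state, va_enc, val_y, tcfg.huber_delta)
        entry = {
            "epoch": epoch,
            "train_loss": epoch_loss / max(n_seen, 1),
            "val_loss": float(val_loss),
        }
        log.append(entry)
        if verbose:
            print(f"epoch {epoch:3d}  train {entry['train_loss']:.5f}  "
                  f"val {entry['val_loss']:.5f}")
        if val_loss < best_val:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in state.params.items()}
            best_running = {k: v.copy() for k, v in state.running.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= tcfg.patience:
                break
    if best_params is not None:
        state.params = best_params
        state.running = best_running
    return state, log
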