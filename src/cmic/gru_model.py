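"""Bidirectional GRU classifier over variable-length k-mer sentences.

The network is: embedding layer (frozen, ``C``, or trainable, ``V``) →
forward and backward GRU recurrences → concatenation of the two final hidden
states → dropout → fully connected layer → sigmoid.  The output is read as
the probability of the input sequence being *unmethylated* (class 1).

One GRU step computes, with sigmoid σ and Hadamard product ⊙::

    r_t = σ(W_r x_t + U_r h_{t-1} + b_r)          reset gate
    z_t = σ(W_z x_t + U_z h_{t-1} + b_z)          update gate
    h~_t = tanh(W x_t + U (r_t ⊙ h_{t-1}) + b_h)  candidate activation
    h_t = z_t ⊙ h_{t-1} + (1 - z_t) ⊙ h~_t        affine combination

Training minimises ``L(w) = E(ŷ, y) + α·‖w‖₂`` with Adam, where E is the
(summed) binary cross-entropy and the penalty is, as written, the *unsquared*
global L2 norm of the non-bias weights; the conventional squared form is
available behind ``TrainConfig.decay_squared``.

Everything runs in float64 numpy; forward, backward (hand-derived gradients)
and Adam are implemented here so the model has no deep-learning framework
dependency and can be checked against finite differences exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .embedding import EmbeddingTable
from .sequence_ops import (
    METHYLATED,
    UNMETHYLATED,
    DnaSequence,
    SegmentationConfig,
    augment,
)

__all__ = [
    "GruCellWeights",
    "GruModel",
    "TrainConfig",
    "PredictionResult",
    "gru_step",
    "bigru_forward",
    "predict_sentence",
    "predict_cgi",
    "loss",
    "train",
]

EPS_CLIP = 1e-7  # probability clipping before log

_CELL_KEYS = ("W_r", "U_r", "b_r", "W_z", "U_z", "b_z", "W", "U", "b_h")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class GruCellWeights:
    """Weights of one GRU direction: gates, candidate, biases."""

    W_r: np.ndarray
    U_r: np.ndarray
    b_r: np.ndarray
    W_z: np.ndarray
    U_z: np.ndarray
    b_z: np.ndarray
    W: np.ndarray
    U: np.ndarray
    b_h: np.ndarray

    def __post_init__(self):
        H, D = self.W_r.shape
        expect = {
            "W_r": (H, D), "U_r": (H, H), "b_r": (H,),
            "W_z": (H, D), "U_z": (H, H), "b_z": (H,),
            "W": (H, D), "U": (H, H), "b_h": (H,),
        }
        for k, shape in expect.items():
            arr = getattr(self, k)
            if arr.shape != shape:
                raise ValueError(f"{k} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{k} contains non-finite values")

    @classmethod
    def initialize(cls, dim: int, hidden: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(hidden)
        def u(*shape):
            return rng.uniform(-s, s, size=shape)
        return cls(
            W_r=u(hidden, dim), U_r=u(hidden, hidden), b_r=u(hidden),
            W_z=u(hidden, dim), U_z=u(hidden, hidden), b_z=u(hidden),
            W=u(hidden, dim), U=u(hidden, hidden), b_h=u(hidden),
        )


@dataclass
class TrainConfig:
    """Training hyper-parameters (published defaults)."""

    epochs: int = 2
    learning_rate: float = 0.0001
    batch_size: int = 32
    dropout: float = 0.5
    weight_decay: float = 0.01
    hidden_dim: int = 256
    seed: int = 0
    decay_squared: bool = False  # use conventional alpha*||w||^2 instead


@dataclass
class PredictionResult:
    """Per-sentence probabilities and the aggregated per-CGI call."""

    cgi_id: str
    sentence_probs: np.ndarray
    probability: float
    label: int  # 1 = unmethylated iff probability > 0.5, else 0

    def __post_init__(self):
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"probability {self.probability} outside [0,1]")


class GruModel:
    """All weights of the BiGRU classifier plus the embedding layer.

    Parameters are held in a flat name → array dict (prefix ``f_``/``b_``
    for the two directions, ``head_w``/``head_b`` for the output layer and
    ``emb`` for the embedding matrix, whose last row is the shared zero
    vector for padding / out-of-vocabulary tokens).
    """

    def __init__(
        self,
        params: dict[str, np.ndarray],
        vocab: list[str],
        dim: int,
        hidden: int,
        embedding_trainable: str = "C",
        embedding_metadata: dict | None = None,
    ):
        if embedding_trainable not in ("C", "V"):
            raise ValueError("embedding_trainable must be 'C' or 'V'")
        if params["head_w"].shape != (2 * hidden,):
            raise ValueError("head input dimension must equal 2H")
        self.params = params
        self.vocab = list(vocab)
        self.index = {t: i for i, t in enumerate(self.vocab)}
        self.dim = dim
        self.hidden = hidden
        self.embedding_trainable = embedding_trainable
        self.embedding_metadata = embedding_metadata or {}

    # -- construction -------------------------------------------------

    @classmethod
    def from_embedding(
        cls,
        table: EmbeddingTable,
        hidden: int = 256,
        embedding_trainable: str = "C",
        seed: int = 0,
    ) -> "GruModel":
        rng = np.random.default_rng(seed)
        vocab, mat = table.matrix()
        emb = np.vstack([mat, np.zeros((1, table.dim))])  # last row: pad/OOV
        params: dict[str, np.ndarray] = {"emb": emb.astype(float)}
        for prefix in ("f", "b"):
            cell = GruCellWeights.initialize(table.dim, hidden, rng)
            for k in _CELL_KEYS:
                params[f"{prefix}_{k}"] = getattr(cell, k)
        s = 1.0 / np.sqrt(hidden)
        params["head_w"] = rng.uniform(-s, s, size=2 * hidden)
        params["head_b"] = rng.uniform(-s, s, size=1)
        return cls(params, vocab, table.dim, hidden, embedding_trainable,
                   dict(table.metadata))

    def cell(self, direction: str) -> GruCellWeights:
        prefix = {"forward": "f", "backward": "b"}[direction]
        return GruCellWeights(**{k: self.params[f"{prefix}_{k}"] for k in _CELL_KEYS})

    @property
    def forward_cell(self) -> GruCellWeights:
        return self.cell("forward")

    @property
    def backward_cell(self) -> GruCellWeights:
        return self.cell("backward")

    @property
    def embedding_table(self) -> EmbeddingTable:
        """Current embedding layer as a table (reflects V-mode updates)."""
        emb = self.params["emb"]
        return EmbeddingTable(
            {t: emb[i].copy() for i, t in enumerate(self.vocab)},
            self.dim,
            dict(self.embedding_metadata),
        )

    def token_ids(self, tokens) -> np.ndarray:
        oov = len(self.vocab)
        return np.array([self.index.get(t, oov) for t in tokens], dtype=np.int64)

    def decayed_keys(self) -> list[str]:
        """Parameters subject to weight decay.

        All recurrent and head weight matrices; biases are exempt, as is the
        embedding layer (its scale is set by the pre-trained vectors, and in
        V mode its rows are updated sparsely).
        """
        return sorted(
            k for k in self.params
            if not (k.endswith(("b_r", "b_z", "b_h")) or k in ("head_b", "emb"))
        )

    def trainable_keys(self) -> list[str]:
        keys = sorted(self.params)
        if self.embedding_trainable != "V":
            keys.remove("emb")
        return keys

    # -- persistence ---------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "dim": self.dim,
            "hidden": self.hidden,
            "embedding_trainable": self.embedding_trainable,
            "embedding_metadata": self.embedding_metadata,
        }
        with open(path, "wb") as fh:  # keep the exact filename (no .npz suffix)
            np.savez(
                fh,
                _vocab=np.array(self.vocab),
                _meta=np.array(json.dumps(meta)),
                **self.params,
            )

    @classmethod
    def load(cls, path) -> "GruModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["_meta"]))
            vocab = [str(t) for t in z["_vocab"]]
            params = {k: z[k].copy() for k in z.files if not k.startswith("_")}
        return cls(params, vocab, meta["dim"], meta["hidden"],
                   meta["embedding_trainable"], meta["embedding_metadata"])


# ---------------------------------------------------------------------------
# forward pass


def gru_step(x_t: np.ndarray, h_prev: np.ndarray, cell: GruCellWeights) -> np.ndarray:
    """One GRU time step; accepts a single vector or a batch (rows)."""
    r, z, hc, h_new = _cell_forward(np.atleast_2d(x_t), np.atleast_2d(h_prev), cell)
    return h_new[0] if x_t.ndim == 1 else h_new


def _cell_forward(x, h, cell):
    r = _sigmoid(x @ cell.W_r.T + h @ cell.U_r.T + cell.b_r)
    z = _sigmoid(x @ cell.W_z.T + h @ cell.U_z.T + cell.b_z)
    hc = np.tanh(x @ cell.W.T + (r * h) @ cell.U.T + cell.b_h)
    h_new = z * h + (1.0 - z) * hc
    return r, z, hc, h_new


def bigru_forward(vectors: np.ndarray, model: GruModel) -> np.ndarray:
    """Run both directions over a (T, D) vector sequence.

    Initial hidden states are zero; returns the concatenation
    ``[h_fwd_T ; h_bwd_T]`` of the two final hidden states.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] < 1:
        raise ValueError("input must be a non-empty (T, D) array")
    H = model.hidden
    out = np.empty(2 * H)
    for sl, cell, xs in (
        (slice(0, H), model.forward_cell, vectors),
        (slice(H, 2 * H), model.backward_cell, vectors[::-1]),
    ):
        h = np.zeros(H)
        for t in range(xs.shape[0]):
            h = gru_step(xs[t], h, cell)
        out[sl] = h
    return out


def _direction_pass(X, active, cell, want_cache):
    """Masked batched recurrence; frozen hidden state past each row's end."""
    B, T, _ = X.shape
    H = cell.b_r.shape[0]
    h = np.zeros((B, H))
    cache = [] if want_cache else None
    for t in range(T):
        r, z, hc, h_new = _cell_forward(X[:, t, :], h, cell)
        if want_cache:
            cache.append((h, r, z, hc))
        a = active[:, t][:, None]
        h = np.where(a, h_new, h)
    return h, cache


def _direction_backward(dh, X, active, cell, cache, grads, prefix):
    """Backprop through one direction; returns dL/dX."""
    B, T, _ = X.shape
    dX = np.zeros_like(X)
    for t in reversed(range(T)):
        h_prev, r, z, hc = cache[t]
        a = active[:, t][:, None]
        dh_act = dh * a
        x = X[:, t, :]

        dz = dh_act * (h_prev - hc)
        dhc = dh_act * (1.0 - z)
        dh_prev = dh_act * z

        da_h = dhc * (1.0 - hc * hc)
        grads[f"{prefix}_W"] += da_h.T @ x
        grads[f"{prefix}_U"] += da_h.T @ (r * h_prev)
        grads[f"{prefix}_b_h"] += da_h.sum(axis=0)
        dX[:, t, :] += da_h @ cell.W
        drh = da_h @ cell.U
        dr = drh * h_prev
        dh_prev = dh_prev + drh * r

        da_z = dz * z * (1.0 - z)
        grads[f"{prefix}_W_z"] += da_z.T @ x
        grads[f"{prefix}_U_z"] += da_z.T @ h_prev
        grads[f"{prefix}_b_z"] += da_z.sum(axis=0)
        dX[:, t, :] += da_z @ cell.W_z
        dh_prev = dh_prev + da_z @ cell.U_z

        da_r = dr * r * (1.0 - r)
        grads[f"{prefix}_W_r"] += da_r.T @ x
        grads[f"{prefix}_U_r"] += da_r.T @ h_prev
        grads[f"{prefix}_b_r"] += da_r.sum(axis=0)
        dX[:, t, :] += da_r @ cell.W_r
        dh_prev = dh_prev + da_r @ cell.U_r

        dh = dh_prev + dh * (1.0 - a)
    return dX


def _pad_batch(id_arrays, pad):
    lengths = np.array([len(a) for a in id_arrays])
    T = int(lengths.max())
    ids = np.full((len(id_arrays), T), pad, dtype=np.int64)
    for i, a in enumerate(id_arrays):
        ids[i, : len(a)] = a
    return ids, lengths


def _reverse_ids(ids, lengths, pad):
    B, T = ids.shape
    j = np.arange(T)[None, :]
    src = lengths[:, None] - 1 - j
    rev = np.take_along_axis(ids, np.clip(src, 0, T - 1), axis=1)
    return np.where(src >= 0, rev, pad)


def _batch_forward(model, ids, lengths, dropout_mask=None, want_cache=False):
    """Probabilities (and cache) for one padded batch of token-id rows."""
    pad = len(model.vocab)
    emb = model.params["emb"]
    active = np.arange(ids.shape[1])[None, :] < lengths[:, None]
    ids_rev = _reverse_ids(ids, lengths, pad)
    Xf, Xb = emb[ids], emb[ids_rev]
    hf, cf = _direction_pass(Xf, active, model.forward_cell, want_cache)
    hb, cb = _direction_pass(Xb, active, model.backward_cell, want_cache)
    concat = np.concatenate([hf, hb], axis=1)
    dropped = concat if dropout_mask is None else concat * dropout_mask
    logit = dropped @ model.params["head_w"] + model.params["head_b"][0]
    p = _sigmoid(logit)
    if not want_cache:
        return p, None
    cache = dict(ids=ids, ids_rev=ids_rev, active=active, Xf=Xf, Xb=Xb,
                 cf=cf, cb=cb, concat=concat, dropped=dropped,
                 dropout_mask=dropout_mask)
    return p, cache


def batch_loss_and_grads(model, id_arrays, labels, cfg, dropout_mask=None):
    """Loss L(w) on one batch and its analytic gradients.

    Returns ``(loss_value, grads)`` with one gradient array per trainable
    parameter.  The data term is the summed cross-entropy over the batch;
    the decay term and its (sub)gradient follow ``cfg.decay_squared``.
    """
    pad = len(model.vocab)
    ids, lengths = _pad_batch(id_arrays, pad)
    y = np.asarray(labels, dtype=float)
    p, cache = _batch_forward(model, ids, lengths, dropout_mask, want_cache=True)

    p_clip = np.clip(p, EPS_CLIP, 1.0 - EPS_CLIP)
    data = -np.sum(y * np.log(p_clip) + (1.0 - y) * np.log(1.0 - p_clip))

    grads = {k: np.zeros_like(v) for k, v in model.params.items()}
    dlogit = p - y  # sigmoid + cross-entropy shortcut
    grads["head_w"] += cache["dropped"].T @ dlogit
    grads["head_b"] += np.array([dlogit.sum()])
    dconcat = dlogit[:, None] * model.params["head_w"][None, :]
    if cache["dropout_mask"] is not None:
        dconcat = dconcat * cache["dropout_mask"]
    H = model.hidden
    dXf = _direction_backward(dconcat[:, :H], cache["Xf"], cache["active"],
                              model.forward_cell, cache["cf"], grads, "f")
    dXb = _direction_backward(dconcat[:, H:], cache["Xb"], cache["active"],
                              model.backward_cell, cache["cb"], grads, "b")
    if model.embedding_trainable == "V":
        demb = grads["emb"]
        np.add.at(demb, cache["ids"], dXf)
        np.add.at(demb, cache["ids_rev"], dXb)
        demb[pad] = 0.0  # padding/OOV row stays the zero vector

    alpha = cfg.weight_decay
    decay = 0.0
    if alpha > 0:
        keys = model.decayed_keys()
        sq = sum(float(np.sum(model.params[k] ** 2)) for k in keys)
        if cfg.decay_squared:
            decay = alpha * sq
            for k in keys:
                grads[k] += 2.0 * alpha * model.params[k]
        else:
            norm = np.sqrt(sq)
            decay = alpha * norm
            if norm > 0:
                for k in keys:
                    grads[k] += alpha * model.params[k] / norm
    return data + decay, grads


# ---------------------------------------------------------------------------
# loss, training, prediction


def loss(y_hat, y, weights=None, alpha: float = 0.0, squared: bool = False) -> float:
    """Cross-entropy E plus the weight-decay term α·‖w‖₂.

    ``weights`` is any collection of parameter arrays entering the penalty;
    ``squared=True`` switches to the conventional α·‖w‖₂² form.  Predicted
    probabilities are clipped to [1e-7, 1 - 1e-7] before the logs.
    """
    y_hat = np.asarray(y_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_hat.shape != y.shape:
        raise ValueError(f"length mismatch: {y_hat.shape} vs {y.shape}")
    p = np.clip(y_hat, EPS_CLIP, 1.0 - EPS_CLIP)
    e = -np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    if weights is not None and alpha > 0:
        sq = sum(float(np.sum(np.asarray(w) ** 2)) for w in weights)
        e += alpha * (sq if squared else np.sqrt(sq))
    return float(e)


def train(dataset, model: GruModel, cfg: TrainConfig):
    """Adam training loop over (sentence, label) pairs.

    ``dataset`` holds :class:`KmerSentence` (or plain token lists) with binary
    labels; dropout acts on the concatenated BiGRU output.  The embedding
    matrix receives updates only in ``V`` mode.  Returns ``(model, trace)``
    where ``trace`` is the mean per-sentence training loss per epoch.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    labels_arr = np.array([lab for _, lab in dataset], dtype=float)
    if len(np.unique(labels_arr)) < 2:
        warnings.warn("training dataset contains a single class", stacklevel=2)

    id_arrays = [model.token_ids(list(sent)) for sent, _ in dataset]
    n = len(id_arrays)
    rng = np.random.default_rng(cfg.seed)
    keys = model.trainable_keys()
    m = {k: np.zeros_like(model.params[k]) for k in keys}
    v = {k: np.zeros_like(model.params[k]) for k in keys}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    keep = 1.0 - cfg.dropout
    trace = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            batch_ids = [id_arrays[i] for i in sel]
            mask = None
            if cfg.dropout > 0:
                mask = (rng.random((len(sel), 2 * model.hidden)) < keep) / keep
            loss_val, grads = batch_loss_and_grads(
                model, batch_ids, labels_arr[sel], cfg, dropout_mask=mask
            )
            epoch_loss += loss_val
            step += 1
            for k in keys:
                g = grads[k]
                if k == "emb":
                    # lazy sparse Adam: only rows touched by this batch move
                    rows = np.unique(np.concatenate([a for a in batch_ids]))
                    g = g[rows]
                    m[k][rows] = beta1 * m[k][rows] + (1 - beta1) * g
                    v[k][rows] = beta2 * v[k][rows] + (1 - beta2) * g * g
                    mhat = m[k][rows] / (1 - beta1**step)
                    vhat = v[k][rows] / (1 - beta2**step)
                    model.params[k][rows] -= (
                        cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
                    )
                    continue
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1**step)
                vhat = v[k] / (1 - beta2**step)
                model.params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        trace.append(epoch_loss / n)
    return model, trace


def predict_sentences(sentences, model: GruModel, batch_size: int = 256) -> np.ndarray:
    """Probabilities for many sentences (dropout off)."""
    id_arrays = [model.token_ids(list(s)) for s in sentences]
    probs = np.empty(len(id_arrays))
    pad = len(model.vocab)
    for start in range(0, len(id_arrays), batch_size):
        chunk = id_arrays[start : start + batch_size]
        ids, lengths = _pad_batch(chunk, pad)
        p, _ = _batch_forward(model, ids, lengths)
        probs[start : start + len(chunk)] = p
    return probs


def predict_sentence(sentence, model: GruModel) -> float:
    """Probability of one sentence being unmethylated."""
    return float(predict_sentences([sentence], model)[0])


def predict_cgi(
    seq: DnaSequence, model: GruModel, cfg: SegmentationConfig
) -> PredictionResult:
    """Score one CGI: mean probability over its 2N cognate sentences.

    The per-CGI label is unmethylated only if the aggregated probability is
    strictly greater than 0.5 (a tie counts as methylated).
    """
    sentences = augment(seq, cfg)
    probs = predict_sentences(sentences, model)
    p = float(probs.mean())
    label = UNMETHYLATED if p > 0.5 else METHYLATED
    return PredictionResult(seq.id, probs, p, label)
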