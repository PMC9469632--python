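"""k-mer embedding tables trained with the splitDNA2vec procedure.

splitDNA2vec generates, for every available CGI sequence, 2N non-overlapping
variable-length k-mer sentences (forward + reverse complement) and feeds them
to word2vec in continuous bag-of-words (CBOW) mode with a context window of
10, minimum count c_min = 1 and embedding dimension D = 20.  The assignment is
unsupervised — class labels play no role — and, following the original
transductive design, the corpus may span training and test sequences alike.

Two control schemes are provided: a *shuffled* table in which the learned
k-mer → vector mapping is permuted uniformly at random, and the overlapping,
stride-1 *dna2vec-style* corpus (optionally with N replicates per sequence).

The CBOW trainer here is a self-contained numpy implementation using negative
sampling: for each center token the context vectors within the window are
averaged, and the center plus a handful of noise tokens (drawn from the
unigram distribution raised to 3/4) are scored against that average.  Updates
are applied in small mini-batches; with a fixed seed training is exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence_ops import DnaSequence, SegmentationConfig, augment

__all__ = [
    "EmbeddingConfig",
    "EmbeddingTable",
    "build_corpus",
    "train_embeddings",
    "shuffle_embedding",
    "lookup",
]


class LookupError_(KeyError):
    """Out-of-vocabulary token under strict lookup."""


@dataclass
class EmbeddingConfig:
    """word2vec/CBOW hyper-parameters.

    ``dim``, ``window`` and ``min_count`` follow the published defaults
    (D=20, window=10, c_min=1); ``epochs``, ``negatives`` and the learning
    rates are conventional word2vec settings.
    """

    dim: int = 20
    window: int = 10
    min_count: int = 1
    seed: int = 0
    corpus_replicates: int = 1000  # N used when building the embedding corpus
    epochs: int = 5
    negatives: int = 5
    alpha: float = 0.025  # initial learning rate, linearly decayed
    min_alpha: float = 0.0001
    batch_size: int = 512


@dataclass
class EmbeddingTable:
    """Mapping from k-mer token to a D-dimensional real vector."""

    vectors: dict[str, np.ndarray]
    dim: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tok, v in self.vectors.items():
            if v.shape != (self.dim,):
                raise ValueError(
                    f"vector for {tok!r} has shape {v.shape}, expected ({self.dim},)"
                )

    def __len__(self) -> int:
        return len(self.vectors)

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def matrix(self) -> tuple[list[str], np.ndarray]:
        """Stable (sorted) vocabulary list and the stacked vector matrix."""
        vocab = sorted(self.vectors)
        return vocab, np.stack([self.vectors[t] for t in vocab])

    def save(self, path) -> None:
        """Write in word2vec text format: header ``V D`` then token + floats."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.vectors)} {self.dim}\n")
            for tok in sorted(self.vectors):
                vals = " ".join(repr(float(x)) for x in self.vectors[tok])
                fh.write(f"{tok} {vals}\n")

    @classmethod
    def load(cls, path) -> "EmbeddingTable":
        with open(path) as fh:
            n, dim = map(int, fh.readline().split())
            vectors = {}
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
        if len(vectors) != n:
            raise ValueError(f"header declared {n} vectors, found {len(vectors)}")
        return cls(vectors, dim)


def build_corpus(
    seqs: list[DnaSequence],
    seg_cfg: SegmentationConfig,
    mode: str = "nonoverlap",
) -> list[list[str]]:
    """Tokenized embedding-training corpus: 2N sentences per sequence.

    Class labels are not consulted — embedding training is unsupervised.
    ``mode='nonoverlap'`` is splitDNA2vec; ``mode='overlap'`` the
    dna2vec-style control (use ``n_replicates=1`` for original dna2vec).
    """
    if not seqs:
        raise ValueError("empty sequence set")
    corpus: list[list[str]] = []
    for s in seqs:
        corpus.extend(sent.tokens for sent in augment(s, seg_cfg, mode=mode))
    return corpus


def _scatter_add(target: np.ndarray, rows: np.ndarray, updates: np.ndarray) -> None:
    """``target[rows] += updates`` with repeated rows accumulated.

    Row-compressed bincount accumulation; much faster than ``np.add.at`` for
    the wide, collision-heavy scatters of CBOW training.
    """
    uniq, inv = np.unique(rows, return_inverse=True)
    acc = np.empty((uniq.size, target.shape[1]), dtype=target.dtype)
    for d in range(target.shape[1]):
        acc[:, d] = np.bincount(inv, weights=updates[:, d], minlength=uniq.size)
    target[uniq] += acc


def _corpus_arrays(corpus, cfg):
    """Flatten the corpus into center/context index arrays for CBOW."""
    counts: dict[str, int] = {}
    for sent in corpus:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted(t for t, c in counts.items() if c >= cfg.min_count)
    if not vocab:
        raise ValueError("corpus has no tokens above min_count")
    index = {t: i for i, t in enumerate(vocab)}

    centers, ctx_rows = [], []
    width = 2 * cfg.window
    for sent in corpus:
        ids = [index[t] for t in sent if t in index]
        L = len(ids)
        for i in range(L):
            lo, hi = max(0, i - cfg.window), min(L, i + cfg.window + 1)
            ctx = ids[lo:i] + ids[i + 1 : hi]
            if not ctx:
                continue
            centers.append(ids[i])
            ctx_rows.append(ctx + [-1] * (width - len(ctx)))
    if not centers:
        raise ValueError("corpus yields no (center, context) pairs")
    freq = np.array([counts[t] for t in vocab], dtype=float)
    return vocab, np.asarray(centers), np.asarray(ctx_rows), freq


def train_embeddings(corpus: list[list[str]], cfg: EmbeddingConfig) -> EmbeddingTable:
    """Train CBOW word2vec embeddings with negative sampling.

    Every token occurring at least ``min_count`` times receives a vector;
    with the default c_min = 1 that is the full corpus vocabulary.
    """
    if not corpus:
        raise ValueError("empty corpus")
    vocab, centers, ctx, freq = _corpus_arrays(corpus, cfg)
    V, D = len(vocab), cfg.dim
    rng = np.random.default_rng(cfg.seed)

    # float32 internals: training is memory-bandwidth bound
    w_in = ((rng.random((V, D)) - 0.5) / D).astype(np.float32)
    w_out = np.zeros((V, D), dtype=np.float32)  # target (output) vectors
    noise = freq**0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    n_pairs = centers.shape[0]
    ctx_mask = ctx >= 0
    ctx_counts = ctx_mask.sum(axis=1)
    ctx_safe = np.where(ctx_mask, ctx, 0)

    total_batches = max(1, cfg.epochs * -(-n_pairs // cfg.batch_size))
    batch_no = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            B = sel.shape[0]
            lr = cfg.alpha + (cfg.min_alpha - cfg.alpha) * (batch_no / total_batches)
            batch_no += 1

            c_ids = ctx_safe[sel]  # (B, 2w)
            c_mask = ctx_mask[sel]
            h = (w_in[c_ids] * c_mask[..., None]).sum(axis=1)
            h /= ctx_counts[sel][:, None]  # (B, D) mean context vector

            tgt = centers[sel]
            neg = np.searchsorted(noise_cdf, rng.random((B, cfg.negatives)))
            neg = np.minimum(neg, V - 1)
            samples = np.concatenate([tgt[:, None], neg], axis=1)  # (B, 1+K)
            labels = np.zeros((B, 1 + cfg.negatives))
            labels[:, 0] = 1.0
            # a sampled negative equal to the true center is skipped
            valid = np.ones_like(labels)
            valid[:, 1:] = neg != tgt[:, None]

            out = w_out[samples]  # (B, 1+K, D)
            score = 1.0 / (1.0 + np.exp(-np.einsum("bkd,bd->bk", out, h)))
            g = (score - labels) * valid  # (B, 1+K)

            grad_h = np.einsum("bk,bkd->bd", g, out)
            _scatter_add(w_out, samples.ravel(),
                         (-lr * g[..., None] * h[:, None, :]).reshape(-1, D))
            gc = grad_h / ctx_counts[sel][:, None]  # mean shared across context
            upd = (-lr * gc[:, None, :] * c_mask[..., None]).reshape(-1, D)
            _scatter_add(w_in, c_ids.ravel(), upd)

    vectors = {t: w_in[i].astype(float) for i, t in enumerate(vocab)}
    meta = {
        "algorithm": "cbow-negative-sampling",
        "dim": D,
        "window": cfg.window,
        "min_count": cfg.min_count,
        "epochs": cfg.epochs,
        "negatives": cfg.negatives,
        "alpha": cfg.alpha,
        "min_alpha": cfg.min_alpha,
        "seed": cfg.seed,
    }
    return EmbeddingTable(vectors, D, meta)


def shuffle_embedding(table: EmbeddingTable, rng: np.random.Generator) -> EmbeddingTable:
    """Permute the token → vector mapping uniformly at random.

    The vocabulary and the multiset of vectors are preserved exactly; only
    the assignment changes (the shuffled-embedding control scheme).
    """
    vocab, mat = table.matrix()
    perm = rng.permutation(len(vocab))
    vectors = {tok: mat[perm[i]].copy() for i, tok in enumerate(vocab)}
    meta = dict(table.metadata, shuffled=True)
    return EmbeddingTable(vectors, table.dim, meta)


def lookup(table: EmbeddingTable, sentence, oov_policy: str = "zero") -> np.ndarray:
    """Embed a sentence: one D-vector per token, in order.

    ``oov_policy='zero'`` maps unknown tokens to the zero vector;
    ``'strict'`` raises, naming the token.
    """
    tokens = list(sentence)
    if not tokens:
        raise ValueError("empty sentence")
    out = np.zeros((len(tokens), table.dim))
    for i, tok in enumerate(tokens):
        v = table.vectors.get(tok)
        if v is None:
            if oov_policy == "strict":
                raise LookupError_(f"token {tok!r} not in vocabulary")
            if oov_policy != "zero":
                raise ValueError(f"unknown oov_policy {oov_policy!r}")
        else:
            out[i] = v
    return out
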