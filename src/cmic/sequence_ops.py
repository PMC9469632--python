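"""Segmentation of DNA sequences into variable-length k-mer sentences.

A CpG-island (CGI) sequence is converted into *sentences* of k-mer tokens in
one of three ways:

* **non-overlapping random splits** — the sequence is consumed left to right,
  each token length drawn i.i.d. uniform on ``{k_min, ..., k_max}``.  Repeating
  the split N times for the sequence and N times for its reverse complement
  yields the 2N *cognate* sentences used as network input (data augmentation).
* **overlapping, stride-1 random windows** — one token per start position with
  a random length; the control scheme for embedding-vector comparison.
* **fixed k / fixed stride** — the classic tokenization used by fixed-k
  recurrent classifiers; provided as a variant operation.

All randomness flows through :func:`numpy.random.default_rng` streams; the
per-(sequence, origin, replicate) substream derivation makes augmentation
reproducible regardless of iteration order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "DnaSequence",
    "KmerSentence",
    "SegmentationConfig",
    "normalize_sequence",
    "reverse_complement",
    "split_variable_kmers",
    "split_overlapping_kmers",
    "split_fixed_kmers",
    "augment",
    "read_fasta",
    "write_fasta",
    "read_labels",
    "write_labels",
    "write_corpus",
    "read_corpus",
    "sequence_rng",
]

ALPHABET = frozenset("ACGTN")

#: class-label convention: 0 = methylated, 1 = unmethylated
METHYLATED, UNMETHYLATED = 0, 1


class SequenceError(ValueError):
    """Invalid nucleotide input."""


@dataclass
class DnaSequence:
    """An identified nucleotide string with an optional binary class label.

    ``label`` follows the convention 0 = methylated, 1 = unmethylated.
    """

    id: str
    seq: str
    label: int | None = None

    def __post_init__(self) -> None:
        self.seq = normalize_sequence(self.seq)
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class KmerSentence:
    """One tokenization pass over a sequence (or its reverse complement)."""

    source_id: str
    tokens: list[str]
    origin: str = "forward"  # or "reverse_complement"
    replicate_index: int = 0
    label: int | None = None

    def __post_init__(self) -> None:
        if self.origin not in ("forward", "reverse_complement"):
            raise ValueError(f"unknown origin {self.origin!r}")

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


@dataclass
class SegmentationConfig:
    """Bounds of the random token length and the augmentation factor N."""

    k_min: int = 4
    k_max: int = 12
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1")
        if self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def normalize_sequence(raw: str) -> str:
    """Uppercase ``raw`` and reject characters outside {A,C,G,T,N}.

    Raises :class:`SequenceError` naming the 1-based position of the first
    offending character, or on empty input.
    """
    if not raw:
        raise SequenceError("empty sequence")
    seq = raw.upper()
    for i, ch in enumerate(seq):
        if ch not in ALPHABET:
            raise SequenceError(
                f"illegal character {ch!r} at position {i + 1} "
                f"(alphabet is A,C,G,T,N)"
            )
    return seq


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def sequence_rng(
    seed: int, source_id: str, origin: str = "forward", replicate_index: int = 0
) -> np.random.Generator:
    """Deterministic substream for one (sequence, origin, replicate) triple.

    Derivation uses a CRC32 of the sequence id inside a
    :class:`numpy.random.SeedSequence`, so streams are independent of the
    order in which sequences are processed.
    """
    sid = zlib.crc32(source_id.encode())
    oid = 0 if origin == "forward" else 1
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(sid, oid, replicate_index))
    )


def split_variable_kmers(
    seq: str,
    cfg: SegmentationConfig,
    rng: np.random.Generator,
    *,
    source_id: str = "",
    origin: str = "forward",
    replicate_index: int = 0,
    label: int | None = None,
) -> KmerSentence:
    """Non-overlapping left-to-right split with i.i.d. uniform token lengths.

    Each token length is drawn uniform on ``{k_min, ..., k_max}``.  When the
    remaining suffix is shorter than the drawn length the whole suffix is
    emitted as the final token (possibly shorter than ``k_min``), so that the
    concatenation of tokens always reconstructs ``seq`` exactly.
    """
    tokens: list[str] = []
    pos, n = 0, len(seq)
    while pos < n:
        k = int(rng.integers(cfg.k_min, cfg.k_max + 1))
        tokens.append(seq[pos : pos + k])
        pos += k
    return KmerSentence(source_id, tokens, origin, replicate_index, label)


def split_overlapping_kmers(
    seq: str,
    cfg: SegmentationConfig,
    rng: np.random.Generator,
    *,
    source_id: str = "",
    origin: str = "forward",
    replicate_index: int = 0,
    label: int | None = None,
) -> KmerSentence:
    """Overlapping stride-1 windows with random lengths (dna2vec-style).

    One token per start position ``0 .. len-k_min``; each token's length is
    drawn uniform on ``{k_min, ..., k_max}`` and truncated at the sequence
    end.  Start positions whose full ``k_min``-mer does not fit are dropped.
    """
    n = len(seq)
    if n < cfg.k_min:
        raise SequenceError(
            f"sequence of length {n} is shorter than k_min={cfg.k_min}"
        )
    n_tokens = n - cfg.k_min + 1
    lengths = rng.integers(cfg.k_min, cfg.k_max + 1, size=n_tokens)
    tokens = [seq[i : i + int(k)] for i, k in enumerate(lengths)]
    return KmerSentence(source_id, tokens, origin, replicate_index, label)


def split_fixed_kmers(
    seq: str,
    k: int,
    stride: int,
    *,
    source_id: str = "",
    label: int | None = None,
) -> KmerSentence:
    """Fixed-k, fixed-stride tokenization (KEGRU-style)."""
    if k < 1 or stride < 1:
        raise ValueError("k and stride must be >= 1")
    if len(seq) < k:
        raise SequenceError(f"sequence of length {len(seq)} is shorter than k={k}")
    tokens = [seq[i : i + k] for i in range(0, len(seq) - k + 1, stride)]
    return KmerSentence(source_id, tokens, label=label)


def augment(
    seq: DnaSequence,
    cfg: SegmentationConfig,
    *,
    mode: str = "nonoverlap",
) -> list[KmerSentence]:
    """Generate the 2N cognate sentences of ``seq``.

    N independent splits of the forward sequence and N of its reverse
    complement, all carrying the sequence's id and label.  ``mode`` selects
    non-overlapping random splits (the default augmentation) or the
    overlapping dna2vec-style variant.
    """
    split = {"nonoverlap": split_variable_kmers, "overlap": split_overlapping_kmers}[
        mode
    ]
    out: list[KmerSentence] = []
    for origin, s in (
        ("forward", seq.seq),
        ("reverse_complement", reverse_complement(seq.seq)),
    ):
        for rep in range(cfg.n_replicates):
            rng = sequence_rng(cfg.seed, seq.id, origin, rep)
            out.append(
                split(
                    s,
                    cfg,
                    rng,
                    source_id=seq.id,
                    origin=origin,
                    replicate_index=rep,
                    label=seq.label,
                )
            )
    return out


# ---------------------------------------------------------------------------
# I/O helpers


def read_fasta(path, labels: dict[str, int] | None = None) -> list[DnaSequence]:
    """Read sequences from FASTA; labels, if given, are joined by id."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        lab = labels.get(rec.id) if labels else None
        out.append(DnaSequence(rec.id, str(rec.seq), lab))
    return out


def write_fasta(seqs: Iterable[DnaSequence], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.seq}\n")


def read_labels(path) -> dict[str, int]:
    """Sidecar label TSV: ``id <tab> label`` (0=methylated, 1=unmethylated)."""
    labels: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, lab = line.split("\t")[:2]
            labels[sid] = int(lab)
    return labels


def write_labels(labels: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for sid, lab in labels.items():
            fh.write(f"{sid}\t{lab}\n")


def write_corpus(sentences: Iterable[Sequence[str]], path) -> None:
    """One sentence per line, tokens space-separated (word2vec corpus text)."""
    with open(path, "w") as fh:
        for sent in sentences:
            fh.write(" ".join(sent) + "\n")


def read_corpus(path) -> list[list[str]]:
    with open(path) as fh:
        return [line.split() for line in fh if line.strip()]
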