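"""Synthetic CGI-like data with known ground truth.

Real CGIs are GC-rich, CpG-dense and (in the inheritance dataset emulated
here) come as 150 methylation-inheriting vs 60 methylation-losing sequences
of 200-500 bp.  The generator reproduces that shape: GC-biased background
with boosted CpG dinucleotides, class-specific 10-mer motifs planted on a
random strand, and toy WGBS read-count tables whose intended M2M / M2U /
excluded outcome is guaranteed by construction.

What it does *not* emulate: real CGI sequence structure beyond composition
(no repeats, no transcription-factor grammar), bisulfite conversion noise,
or any coupling between sequence and the read counts.  Classification
difficulty is controlled purely by the planted motifs (``motif_copies=0``
makes the classes exchangeable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .methylation_labeling import (
    BLASTOCYST_PRESET,
    FGO_PRESET,
    CgiMethylationRecord,
    ThresholdConfig,
)
from .sequence_ops import METHYLATED, UNMETHYLATED, DnaSequence, reverse_complement

__all__ = ["SyntheticSpec", "generate_background", "generate_dataset",
           "generate_count_table"]

_BASES = np.array(list("ACGT"))

#: default planted motifs; disjoint as strings and not reverse complements
DEFAULT_MOTIFS = ("ACGTACGTAA", "GATCGGATCC")


@dataclass
class SyntheticSpec:
    """Recipe for a labeled CGI-like dataset.

    Class 0 (methylated / inheriting) gets ``n_per_class[0]`` sequences and
    ``motifs_per_class[0]``; class 1 likewise.  Defaults mirror the real
    dataset's 150/60 imbalance and 200-500 bp length regime.
    """

    n_per_class: tuple[int, int] = (150, 60)
    length_range: tuple[int, int] = (200, 500)
    gc_content: float = 0.65
    cpg_boost: float = 5.0
    motifs_per_class: tuple[str, str] = DEFAULT_MOTIFS
    motif_copies: int = 3
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be in (0,1)")
        if self.cpg_boost < 1.0:
            raise ValueError("cpg_boost must be >= 1")
        for m in self.motifs_per_class:
            if not set(m) <= set("ACGT"):
                raise ValueError(f"motif {m!r} not over A,C,G,T")
            if len(m) > self.length_range[0]:
                raise ValueError("motif longer than the minimum sequence length")
        m0, m1 = self.motifs_per_class
        if m0 == m1 or m0 in m1 or m1 in m0:
            raise ValueError("class motifs must be disjoint strings")


def _transition_rows(gc: float, boost: float) -> np.ndarray:
    """First-order transition matrix (rows A,C,G,T) with boosted CpG.

    Every row keeps total G+C probability equal to ``gc``, so the marginal
    GC law holds exactly; from C, probability mass moves from C to G by
    factor ``boost``, capped so the row stays a distribution (with high
    boost and high GC the effective boost saturates at ``gc / (gc/2)`` = 2).
    """
    at, gcq = (1.0 - gc) / 2.0, gc / 2.0
    base = np.array([at, gcq, gcq, at])
    rows = np.tile(base, (4, 1))
    p_g = min(boost * gcq, gc)  # cap: C-row keeps G+C mass == gc
    rows[1] = [at, gc - p_g, p_g, at]
    return rows


def generate_background(
    length: int, gc_content: float, cpg_boost: float, rng: np.random.Generator
) -> str:
    """GC-biased background sequence with CpG-enriched dinucleotides."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rows = _transition_rows(gc_content, cpg_boost)
    cum = rows.cumsum(axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int64)
    prev = int(np.searchsorted(cum[0], u[0]))  # row A == base composition
    out[0] = prev
    for i in range(1, length):
        prev = int(np.searchsorted(cum[prev], u[i]))
        out[i] = prev
    return "".join(_BASES[out])


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[DnaSequence], pd.DataFrame]:
    """Labeled sequences with planted class motifs, plus a truth manifest.

    Each sequence receives ``motif_copies`` non-overlapping insertions of
    its class motif at random positions, each on a random strand (the motif
    or its reverse complement overwrites the background in place).  The
    manifest records every insertion: id, motif, position, strand.
    """
    rng = np.random.default_rng(spec.seed)
    seqs: list[DnaSequence] = []
    manifest_rows = []
    lo, hi = spec.length_range
    for label, n, motif in (
        (METHYLATED, spec.n_per_class[0], spec.motifs_per_class[0]),
        (UNMETHYLATED, spec.n_per_class[1], spec.motifs_per_class[1]),
    ):
        for i in range(n):
            sid = f"cgi_c{label}_{i:04d}"
            length = int(rng.integers(lo, hi + 1))
            if spec.motif_copies * len(motif) > length:
                raise ValueError(
                    f"{spec.motif_copies} copies of a {len(motif)}-mer "
                    f"cannot fit in {length} bp"
                )
            seq = list(generate_background(length, spec.gc_content,
                                           spec.cpg_boost, rng))
            placed: list[tuple[int, int]] = []
            while len(placed) < spec.motif_copies:
                pos = int(rng.integers(0, length - len(motif) + 1))
                span = (pos, pos + len(motif))
                if any(span[0] < e and s < span[1] for s, e in placed):
                    continue
                placed.append(span)
                strand = "+" if rng.random() < 0.5 else "-"
                ins = motif if strand == "+" else reverse_complement(motif)
                seq[span[0] : span[1]] = list(ins)
                manifest_rows.append(
                    {"cgi_id": sid, "motif": motif, "position": pos,
                     "strand": strand}
                )
            seqs.append(DnaSequence(sid, "".join(seq), label))
    manifest = pd.DataFrame(
        manifest_rows, columns=["cgi_id", "motif", "position", "strand"]
    )
    return seqs, manifest


#: intended outcomes the count-table generator can realise
_INTENTS = ("M2M", "M2U", "excluded_by_T", "excluded_intermediate")


def _counts_for(label: str, thr: ThresholdConfig, rng) -> tuple[int, int]:
    """Read counts guaranteed to produce ``label`` under ``thr``."""
    if label == "below_T":
        total = int(rng.integers(0, max(thr.T, 1)))
        meth = int(rng.integers(0, total + 1))
        return total, meth
    total = int(rng.integers(thr.T, thr.T + 100)) if thr.T > 0 else int(
        rng.integers(1, 101)
    )
    if label == "M":
        meth = int(rng.integers(int(np.ceil(thr.beta_M * total)), total + 1))
    elif label == "U":
        hi = int(np.ceil(thr.beta_U * total)) - 1  # ratio strictly < beta_U
        meth = int(rng.integers(0, max(hi, 0) + 1))
        while meth / total >= thr.beta_U:
            meth -= 1
    else:  # intermediate: beta_U <= ratio < beta_M
        lo = int(np.ceil(thr.beta_U * total))
        hi = int(np.ceil(thr.beta_M * total)) - 1
        meth = int(rng.integers(lo, hi + 1))
    return total, meth


def generate_count_table(
    intended: list[str],
    fgo_thr: ThresholdConfig = FGO_PRESET,
    blast_thr: ThresholdConfig = BLASTOCYST_PRESET,
    rng: np.random.Generator | None = None,
) -> tuple[list[CgiMethylationRecord], list[CgiMethylationRecord], pd.DataFrame]:
    """Toy read-count tables realising the intended class of every CGI.

    ``intended`` lists, per CGI, one of ``M2M``, ``M2U``, ``excluded_by_T``
    (too few FGO reads) or ``excluded_intermediate`` (FGO ratio between the
    thresholds).  Counts are sampled inside the region that analytically
    guarantees the intent.  Returns the FGO records, the blastocyst
    maternal-genome records and the expected-label table.
    """
    rng = rng or np.random.default_rng(0)
    fgo, blast, rows = [], [], []
    for i, intent in enumerate(intended):
        if intent not in _INTENTS:
            raise ValueError(f"unknown intent {intent!r}")
        cid = f"cgi_{i:04d}"
        if intent == "M2M":
            f, b = _counts_for("M", fgo_thr, rng), _counts_for("M", blast_thr, rng)
        elif intent == "M2U":
            f, b = _counts_for("M", fgo_thr, rng), _counts_for("U", blast_thr, rng)
        elif intent == "excluded_by_T":
            f = _counts_for("below_T", fgo_thr, rng)
            b = _counts_for("M", blast_thr, rng)
        else:
            f = _counts_for("intermediate", fgo_thr, rng)
            b = _counts_for("M", blast_thr, rng)
        fgo.append(CgiMethylationRecord(cid, *f))
        blast.append(CgiMethylationRecord(cid, *b))
        expected = intent if intent in ("M2M", "M2U") else "excluded"
        rows.append({"cgi_id": cid, "intent": intent, "expected_class": expected})
    return fgo, blast, pd.DataFrame(rows)
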