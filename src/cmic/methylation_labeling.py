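"""WGBS read-count thresholding and methylation-inheritance classes.

For each CGI and cell type, the methylation ratio is the count of methylated
read observations over the whole read count.  A CGI with fewer than ``T``
covering reads is excluded; otherwise it is labeled M (methylated) when the
ratio is at least ``beta_M`` and U (unmethylated) when the ratio is below
``beta_U``.  Intermediate ratios belong to neither class and are excluded.

The inheritance target is defined on CGIs methylated in fully grown oocytes
(FGOs): those still M in the maternal genome of blastocysts are M2M
(methylation inheritance, class label 0) and those turned U are M2U
(methylation loss, class label 1).  Published threshold presets: FGO
T=100, beta_M=0.8, beta_U=0.1; blastocyst maternal genome T=20, beta_M=0.4,
beta_U=0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .sequence_ops import METHYLATED, UNMETHYLATED, DnaSequence

__all__ = [
    "CgiMethylationRecord",
    "ThresholdConfig",
    "InheritanceLabel",
    "FGO_PRESET",
    "BLASTOCYST_PRESET",
    "label_cgi",
    "inheritance_class",
    "build_dataset",
    "read_count_table",
    "write_count_table",
    "write_inheritance_labels",
]


@dataclass
class CgiMethylationRecord:
    cgi_id: str
    total_reads: int
    methylated_reads: int

    def __post_init__(self):
        if self.total_reads < 0 or self.methylated_reads < 0:
            raise ValueError(f"{self.cgi_id}: negative read count")
        if self.methylated_reads > self.total_reads:
            raise ValueError(
                f"{self.cgi_id}: methylated reads ({self.methylated_reads}) "
                f"exceed total reads ({self.total_reads})"
            )

    @property
    def ratio(self) -> float | None:
        if self.total_reads == 0:
            return None
        return self.methylated_reads / self.total_reads


@dataclass
class ThresholdConfig:
    """Read-count floor T and the two ratio thresholds."""

    T: int
    beta_M: float
    beta_U: float

    def __post_init__(self):
        if not (0.0 <= self.beta_U < self.beta_M <= 1.0):
            raise ValueError("thresholds must satisfy 0 <= beta_U < beta_M <= 1")
        if self.T < 0:
            raise ValueError("T must be non-negative")


FGO_PRESET = ThresholdConfig(T=100, beta_M=0.8, beta_U=0.1)
BLASTOCYST_PRESET = ThresholdConfig(T=20, beta_M=0.4, beta_U=0.1)


@dataclass
class InheritanceLabel:
    cgi_id: str
    klass: str  # M2M | M2U | excluded


def label_cgi(rec: CgiMethylationRecord, thr: ThresholdConfig) -> str:
    """Label one CGI M, U or excluded under the given thresholds."""
    if rec.total_reads < thr.T:
        return "excluded"
    ratio = rec.ratio
    if ratio is None:  # only reachable with T == 0
        return "excluded"
    if ratio >= thr.beta_M:
        return "M"
    if ratio < thr.beta_U:
        return "U"
    return "excluded"


def inheritance_class(fgo: str, blast_maternal: str) -> str:
    """M2M if methylation persists, M2U if lost; anything else is excluded.

    Defined only for CGIs methylated in FGOs — all other combinations fall
    outside the target set.
    """
    if fgo == "M" and blast_maternal == "M":
        return "M2M"
    if fgo == "M" and blast_maternal == "U":
        return "M2U"
    return "excluded"


def classify_records(
    fgo_records: list[CgiMethylationRecord],
    blast_records: list[CgiMethylationRecord],
    fgo_thr: ThresholdConfig = FGO_PRESET,
    blast_thr: ThresholdConfig = BLASTOCYST_PRESET,
) -> pd.DataFrame:
    """Per-CGI M/U labels for both cell types and the inheritance class."""
    blast = {r.cgi_id: r for r in blast_records}
    rows = []
    for rec in fgo_records:
        fgo_label = label_cgi(rec, fgo_thr)
        b = blast.get(rec.cgi_id)
        blast_label = label_cgi(b, blast_thr) if b is not None else "excluded"
        rows.append(
            {
                "cgi_id": rec.cgi_id,
                "fgo_label": fgo_label,
                "blast_label": blast_label,
                "class": inheritance_class(fgo_label, blast_label),
            }
        )
    return pd.DataFrame(rows)


def build_dataset(
    fgo_records: list[CgiMethylationRecord],
    blast_records: list[CgiMethylationRecord],
    cgi_seqs: dict[str, str],
    max_len: int = 500,
    fgo_thr: ThresholdConfig = FGO_PRESET,
    blast_thr: ThresholdConfig = BLASTOCYST_PRESET,
) -> tuple[list[DnaSequence], list[DnaSequence]]:
    """Labeled sequences for classification, split at ``max_len``.

    M2M CGIs get class label 0 (methylated), M2U label 1 (unmethylated).
    Sequences longer than ``max_len`` (inclusive boundary: length == max_len
    stays in the short set) go to the separate long-CGI generalization set.
    Returns ``(short, long)``.
    """
    if not fgo_records:
        raise ValueError("empty count table")
    table = classify_records(fgo_records, blast_records, fgo_thr, blast_thr)
    table = table[table["class"].isin(["M2M", "M2U"])]
    missing = [cid for cid in table["cgi_id"] if cid not in cgi_seqs]
    if missing:
        raise KeyError(f"CGI ids missing from FASTA: {missing}")
    short, long_ = [], []
    for _, row in table.iterrows():
        label = METHYLATED if row["class"] == "M2M" else UNMETHYLATED
        seq = DnaSequence(row["cgi_id"], cgi_seqs[row["cgi_id"]], label)
        (short if len(seq) <= max_len else long_).append(seq)
    return short, long_


# ---------------------------------------------------------------------------
# I/O


def read_count_table(path) -> list[CgiMethylationRecord]:
    """TSV with columns cgi_id, total_reads, methylated_reads."""
    df = pd.read_csv(path, sep="\t")
    need = {"cgi_id", "total_reads", "methylated_reads"}
    if not need.issubset(df.columns):
        raise ValueError(f"count table must have columns {sorted(need)}")
    return [
        CgiMethylationRecord(str(r.cgi_id), int(r.total_reads), int(r.methylated_reads))
        for r in df.itertuples()
    ]


def write_count_table(records: list[CgiMethylationRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "cgi_id": r.cgi_id,
                "total_reads": r.total_reads,
                "methylated_reads": r.methylated_reads,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def write_inheritance_labels(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
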