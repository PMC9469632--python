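"""Stratified cross-validation harness and performance metrics.

Evaluation follows the published protocol: 3-fold stratified cross-validation
at the CGI level (all 2N cognate sentences of one CGI stay in one fold), with
balanced accuracy, F-measure, MCC and AUC reported as fold-wise mean ± the
standard error.  The positive class for precision/recall is *unmethylated*
(label 1), matching the sigmoid head's output.  Metrics are produced at two
levels: per CGI (aggregated probability, the headline numbers) and per
sentence (the network's actual training instance).

The harness takes any *pipeline* object exposing ``fit(train_seqs, seed)`` →
fitted with ``predict(seqs) -> list[PredictionResult]``; the production
pipeline wires segmentation, embedding training and the BiGRU together, and
tests may substitute oracles.  A no-leakage audit (empty intersection of
train and test CGI ids in every fold) is asserted on every run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.exceptions import UndefinedMetricWarning
from sklearn.metrics import (
    balanced_accuracy_score,
    f1_score,
    matthews_corrcoef,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .embedding import (
    EmbeddingConfig,
    EmbeddingTable,
    build_corpus,
    shuffle_embedding,
    train_embeddings,
)
from .gru_model import (
    GruModel,
    PredictionResult,
    TrainConfig,
    predict_cgi,
    train,
)
from .sequence_ops import DnaSequence, SegmentationConfig, augment

__all__ = [
    "MetricReport",
    "CVResult",
    "stratified_folds",
    "compute_metrics",
    "cross_validate",
    "sweep",
    "evaluate_long",
    "CmicPipeline",
    "make_embedding_table",
    "EMBEDDING_SCHEMES",
    "LONG_BIN_EDGES",
]

EMBEDDING_SCHEMES = ("splitDNA2vec", "splitDNA2vec-sh", "dna2vec", "dna2vec-N1000")

#: long-CGI length bins: [501,601), ..., [901,1001), [1001, inf)
LONG_BIN_EDGES = (501, 601, 701, 801, 901, 1001)


@dataclass
class MetricReport:
    balanced_accuracy: float
    f_measure: float
    mcc: float
    auc: float | None
    level: str = "per_cgi"
    balanced_accuracy_se: float | None = None
    f_measure_se: float | None = None
    mcc_se: float | None = None
    auc_se: float | None = None
    n: int = 0

    def as_dict(self) -> dict:
        return {
            "level": self.level,
            "balanced_accuracy": self.balanced_accuracy,
            "f_measure": self.f_measure,
            "mcc": self.mcc,
            "auc": self.auc,
            "n": self.n,
        }


def compute_metrics(y_true, y_pred, probs=None, level: str = "per_cgi") -> MetricReport:
    """Balanced accuracy, F-measure (positive class 1), MCC and AUC.

    Zero-denominator conventions: precision/recall → 0, MCC → 0.  AUC is
    the rank statistic over ``probs`` and is reported as missing (None) when
    ``y_true`` has a single class or no probabilities are given.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be non-empty and aligned")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UndefinedMetricWarning)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        warnings.simplefilter("ignore", category=UserWarning)
        bal = float(balanced_accuracy_score(y_true, y_pred))
        f = float(f1_score(y_true, y_pred, pos_label=1, zero_division=0))
        mcc = float(matthews_corrcoef(y_true, y_pred))
    auc = None
    if probs is not None and len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, np.asarray(probs)))
    return MetricReport(bal, f, mcc, auc, level=level, n=int(y_true.size))


def _aggregate(reports: list[MetricReport], level: str) -> MetricReport:
    """Fold-wise mean with standard error (K-1 denominator)."""
    def mean_se(vals):
        vals = [v for v in vals if v is not None]
        if not vals:
            return None, None
        arr = np.asarray(vals, dtype=float)
        se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
        return float(arr.mean()), se

    bal, bal_se = mean_se([r.balanced_accuracy for r in reports])
    f, f_se = mean_se([r.f_measure for r in reports])
    mcc, mcc_se = mean_se([r.mcc for r in reports])
    auc, auc_se = mean_se([r.auc for r in reports])
    return MetricReport(
        bal, f, mcc, auc, level=level,
        balanced_accuracy_se=bal_se, f_measure_se=f_se, mcc_se=mcc_se,
        auc_se=auc_se, n=sum(r.n for r in reports),
    )


def stratified_folds(
    dataset: list[DnaSequence], k: int, seed: int = 0
) -> dict[str, int]:
    """CGI-level stratified fold assignment, deterministic given the seed."""
    labels = np.array([s.label for s in dataset])
    ids = [s.id for s in dataset]
    for cls in np.unique(labels):
        if (labels == cls).sum() < k:
            raise ValueError(f"class {cls} has fewer than {k} CGIs")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(ids)), labels)):
        for i in test_idx:
            assignment[ids[i]] = fold
    return assignment


# ---------------------------------------------------------------------------
# the production pipeline


def make_embedding_table(
    seqs: list[DnaSequence],
    scheme: str,
    seg_cfg: SegmentationConfig,
    emb_cfg: EmbeddingConfig,
) -> EmbeddingTable:
    """Embedding table for one of the four schemes.

    splitDNA2vec: non-overlapping splits, N replicates; splitDNA2vec-sh:
    same, then the token → vector map is shuffled; dna2vec: overlapping
    stride-1 windows, a single replicate; dna2vec-N1000: overlapping with N
    replicates.  Training is unsupervised — labels are never read.
    """
    if scheme not in EMBEDDING_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {EMBEDDING_SCHEMES}")
    mode = "nonoverlap" if scheme.startswith("splitDNA2vec") else "overlap"
    n = 1 if scheme == "dna2vec" else emb_cfg.corpus_replicates
    corpus_cfg = replace(seg_cfg, n_replicates=n)
    corpus = build_corpus(seqs, corpus_cfg, mode=mode)
    table = train_embeddings(corpus, emb_cfg)
    if scheme == "splitDNA2vec-sh":
        table = shuffle_embedding(table, np.random.default_rng(emb_cfg.seed))
    return table


@dataclass
class FittedCmic:
    """A trained BiGRU plus everything needed to score new CGIs."""

    model: GruModel
    seg_cfg: SegmentationConfig
    train_ids: frozenset
    loss_trace: list = field(default_factory=list)

    def predict(self, seqs: list[DnaSequence]) -> list[PredictionResult]:
        return [predict_cgi(s, self.model, self.seg_cfg) for s in seqs]


@dataclass
class CmicPipeline:
    """Segmentation → embedding lookup → BiGRU training, as one unit.

    ``embedding_table`` is trained once (typically transductively, over all
    available sequences, as the original design does) and shared across
    folds; pass a table trained on the training folds only for a strictly
    inductive run.
    """

    embedding_table: EmbeddingTable
    seg_cfg: SegmentationConfig
    train_cfg: TrainConfig
    embedding_mode: str = "C"

    def fit(self, train_seqs: list[DnaSequence], seed: int = 0) -> FittedCmic:
        if any(s.label is None for s in train_seqs):
            raise ValueError("all training sequences must be labeled")
        seg = replace(self.seg_cfg, seed=self.seg_cfg.seed + seed)
        sentences = []
        for s in train_seqs:
            sentences.extend((sent, s.label) for sent in augment(s, seg))
        model = GruModel.from_embedding(
            self.embedding_table,
            hidden=self.train_cfg.hidden_dim,
            embedding_trainable=self.embedding_mode,
            seed=seed,
        )
        cfg = replace(self.train_cfg, seed=seed)
        model, trace = train(sentences, model, cfg)
        return FittedCmic(model, seg, frozenset(s.id for s in train_seqs), trace)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    fold_table: pd.DataFrame
    summary: dict[str, MetricReport]
    fold_reports: dict[str, list[MetricReport]]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for level, rep in self.summary.items():
            rows.append(
                {
                    "level": level,
                    "balanced_accuracy": rep.balanced_accuracy,
                    "balanced_accuracy_se": rep.balanced_accuracy_se,
                    "f_measure": rep.f_measure,
                    "f_measure_se": rep.f_measure_se,
                    "mcc": rep.mcc,
                    "mcc_se": rep.mcc_se,
                    "auc": rep.auc,
                    "auc_se": rep.auc_se,
                }
            )
        return pd.DataFrame(rows)


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(fold,)).generate_state(1)[0]
               % (2**31))


def cross_validate(
    dataset: list[DnaSequence],
    pipeline,
    k: int = 3,
    seed: int = 0,
) -> CVResult:
    """K-fold CGI-stratified cross-validation of a pipeline.

    Per fold the pipeline is fitted on the K-1 training folds' sequences and
    scored on the held-out fold at both the per-CGI level (aggregated
    probability) and the per-sentence level.  The report is the fold-wise
    mean ± standard error.  Raises if any CGI id leaks across the split.
    """
    assignment = stratified_folds(dataset, k, seed)
    fold_reports: dict[str, list[MetricReport]] = {"per_cgi": [], "per_sentence": []}
    rows = []
    for fold in range(k):
        train_seqs = [s for s in dataset if assignment[s.id] != fold]
        test_seqs = [s for s in dataset if assignment[s.id] == fold]
        train_ids = {s.id for s in train_seqs}
        test_ids = {s.id for s in test_seqs}
        if train_ids & test_ids:
            raise AssertionError(f"fold {fold}: CGI ids leak across the split")

        fitted = pipeline.fit(train_seqs, seed=_fold_seed(seed, fold))
        fit_ids = getattr(fitted, "train_ids", None)
        if fit_ids is not None and set(fit_ids) & test_ids:
            raise AssertionError(f"fold {fold}: fitted pipeline saw test CGIs")
        results = fitted.predict(test_seqs)

        y_true = np.array([s.label for s in test_seqs])
        y_pred = np.array([r.label for r in results])
        probs = np.array([r.probability for r in results])
        rep_cgi = compute_metrics(y_true, y_pred, probs, level="per_cgi")

        sent_true = np.concatenate(
            [np.full(len(r.sentence_probs), s.label)
             for s, r in zip(test_seqs, results)]
        )
        sent_probs = np.concatenate([r.sentence_probs for r in results])
        rep_sent = compute_metrics(
            sent_true, (sent_probs > 0.5).astype(int), sent_probs,
            level="per_sentence",
        )
        fold_reports["per_cgi"].append(rep_cgi)
        fold_reports["per_sentence"].append(rep_sent)
        for rep in (rep_cgi, rep_sent):
            rows.append({"fold": fold, **rep.as_dict()})

    summary = {lv: _aggregate(reps, lv) for lv, reps in fold_reports.items()}
    return CVResult(pd.DataFrame(rows), summary, fold_reports)


def sweep(
    dataset: list[DnaSequence],
    experiment: str,
    grid,
    seg_cfg: SegmentationConfig,
    emb_cfg: EmbeddingConfig,
    train_cfg: TrainConfig,
    embedding_mode: str = "C",
    k: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """One cross-validation run per grid point of a named experiment.

    ``k_range``: grid of (k_min, k_max) pairs with k_max - k_min >= 1;
    ``n_replicates``: grid of N values (used for both the augmentation and
    the embedding corpus); ``embedding_scheme``: grid of (scheme, mode)
    pairs over the four embedding schemes x {C, V}.
    """
    rows = []
    for point in grid:
        sc, ec, mode = seg_cfg, emb_cfg, embedding_mode
        scheme = "splitDNA2vec"
        if experiment == "k_range":
            k_min, k_max = point
            if k_max - k_min < 1:
                raise ValueError(f"invalid pair ({k_min},{k_max}): need k_max-k_min>=1")
            sc = replace(seg_cfg, k_min=k_min, k_max=k_max)
            coords = {"k_min": k_min, "k_max": k_max}
        elif experiment == "n_replicates":
            sc = replace(seg_cfg, n_replicates=int(point))
            ec = replace(emb_cfg, corpus_replicates=int(point))
            coords = {"n": int(point)}
        elif experiment == "embedding_scheme":
            scheme, mode = point
            coords = {"scheme": scheme, "embedding_mode": mode}
        else:
            raise ValueError(f"unknown experiment {experiment!r}")
        table = make_embedding_table(dataset, scheme, sc, ec)
        pipeline = CmicPipeline(table, sc, train_cfg, embedding_mode=mode)
        cv = cross_validate(dataset, pipeline, k=k, seed=seed)
        rep = cv.summary["per_cgi"]
        rows.append(
            {**coords, "balanced_accuracy": rep.balanced_accuracy,
             "f_measure": rep.f_measure, "f_measure_se": rep.f_measure_se,
             "mcc": rep.mcc, "auc": rep.auc}
        )
    return pd.DataFrame(rows)


def evaluate_long(
    fitted,
    long_seqs: list[DnaSequence],
    bin_edges=LONG_BIN_EDGES,
) -> dict[str, MetricReport | None]:
    """Metrics for long CGIs, binned by length: [501,601), ..., [1001, inf).

    A model trained on short (<= 500 bp) sequences is scored per length bin;
    empty bins are reported as missing (None).
    """
    edges = list(bin_edges) + [None]
    bins: dict[str, list[DnaSequence]] = {}
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        lab = f"{lo}-" if hi is None else f"{lo}-{hi - 1}"
        labels.append(lab)
        bins[lab] = [
            s for s in long_seqs if len(s) >= lo and (hi is None or len(s) < hi)
        ]
    out: dict[str, MetricReport | None] = {}
    for lab in labels:
        seqs = bins[lab]
        if not seqs:
            out[lab] = None
            continue
        results = fitted.predict(seqs)
        y_true = np.array([s.label for s in seqs])
        y_pred = np.array([r.label for r in results])
        probs = np.array([r.probability for r in results])
        out[lab] = compute_metrics(y_true, y_pred, probs, level="per_cgi")
    return out
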