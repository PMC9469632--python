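"""Model/Results front end for CGI methylation-inheritance classification.

:class:`CmicModel` binds a labeled sequence dataset to the full pipeline
(variable-length k-mer augmentation → k-mer embeddings → BiGRU); ``fit()``
returns a :class:`CmicResults` holding the trained network, its loss trace
and prediction/summary methods, in the spirit of statsmodels' model/results
split.  ``cross_validate()`` runs the stratified evaluation protocol and
returns fold-wise metrics with standard errors.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .embedding import EmbeddingConfig, EmbeddingTable
from .evaluation import (
    CmicPipeline,
    CVResult,
    cross_validate,
    make_embedding_table,
)
from .gru_model import GruModel, TrainConfig, predict_cgi
from .sequence_ops import DnaSequence, SegmentationConfig, read_fasta, read_labels

__all__ = ["CmicModel", "CmicResults"]


class CmicModel:
    """CGI methylation-inheritance classifier bound to a dataset.

    Parameters
    ----------
    sequences
        Labeled :class:`DnaSequence` objects (label 0 = methylated /
        inheriting, 1 = unmethylated / losing methylation).
    seg_cfg, emb_cfg, train_cfg
        Segmentation, embedding and training hyper-parameters; published
        defaults are used where omitted.
    scheme
        Embedding scheme: ``splitDNA2vec`` (default), ``splitDNA2vec-sh``,
        ``dna2vec`` or ``dna2vec-N1000``.
    embedding_mode
        ``"C"`` keeps embedding vectors frozen during training, ``"V"``
        treats them as trainable weights.
    embedding_table
        Optional pre-trained table; when absent one is trained on this
        model's sequences (the transductive default of the original design).
    """

    def __init__(
        self,
        sequences: list[DnaSequence],
        seg_cfg: SegmentationConfig | None = None,
        emb_cfg: EmbeddingConfig | None = None,
        train_cfg: TrainConfig | None = None,
        scheme: str = "splitDNA2vec",
        embedding_mode: str = "C",
        embedding_table: EmbeddingTable | None = None,
    ):
        if not sequences:
            raise ValueError("empty dataset")
        if any(s.label is None for s in sequences):
            raise ValueError("all sequences must carry a class label")
        self.sequences = list(sequences)
        self.seg_cfg = seg_cfg or SegmentationConfig()
        self.emb_cfg = emb_cfg or EmbeddingConfig()
        self.train_cfg = train_cfg or TrainConfig()
        self.scheme = scheme
        self.embedding_mode = embedding_mode
        self._embedding_table = embedding_table

    @classmethod
    def from_fasta(cls, fasta_path, labels_path, **kwargs) -> "CmicModel":
        """Build from a FASTA file and an ``id <tab> label`` sidecar TSV."""
        seqs = read_fasta(fasta_path, labels=read_labels(labels_path))
        return cls(seqs, **kwargs)

    @property
    def embedding_table(self) -> EmbeddingTable:
        if self._embedding_table is None:
            self._embedding_table = make_embedding_table(
                self.sequences, self.scheme, self.seg_cfg, self.emb_cfg
            )
        return self._embedding_table

    def pipeline(self) -> CmicPipeline:
        return CmicPipeline(
            self.embedding_table,
            self.seg_cfg,
            self.train_cfg,
            embedding_mode=self.embedding_mode,
        )

    def fit(self, seed: int = 0) -> "CmicResults":
        """Train the BiGRU on all of this model's sequences."""
        fitted = self.pipeline().fit(self.sequences, seed=seed)
        return CmicResults(self, fitted.model, fitted.seg_cfg, fitted.loss_trace,
                           seed)

    def cross_validate(self, k: int = 3, seed: int = 0) -> CVResult:
        """Stratified K-fold CV at the CGI level (default 3 folds)."""
        return cross_validate(self.sequences, self.pipeline(), k=k, seed=seed)


class CmicResults:
    """A fitted classifier: trained weights, loss trace, predictions."""

    def __init__(self, model: CmicModel, network: GruModel,
                 seg_cfg: SegmentationConfig, loss_trace, seed: int):
        self.model = model
        self.network = network
        self.seg_cfg = seg_cfg
        self.loss_trace = list(loss_trace)
        self.seed = seed

    def predict(self, sequences: list[DnaSequence] | None = None) -> pd.DataFrame:
        """Per-CGI aggregated probabilities and class calls.

        Defaults to the training sequences; the returned frame has columns
        id, probability (of being unmethylated), label.
        """
        seqs = sequences if sequences is not None else self.model.sequences
        rows = []
        for s in seqs:
            r = predict_cgi(s, self.network, self.seg_cfg)
            rows.append({"id": r.cgi_id, "probability": r.probability,
                         "label": r.label})
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        self.network.save(path)

    def summary(self) -> str:
        m = self.model
        labels = np.array([s.label for s in m.sequences])
        lines = [
            "CGI methylation inheritance classifier (BiGRU)",
            "=" * 48,
            f"sequences:          {len(m.sequences)} "
            f"({int((labels == 0).sum())} methylated / "
            f"{int((labels == 1).sum())} unmethylated)",
            f"embedding scheme:   {m.scheme} ({m.embedding_mode} mode), "
            f"D={m.emb_cfg.dim}",
            f"vocabulary:         {len(self.network.vocab)} k-mers",
            f"segmentation:       k in [{m.seg_cfg.k_min}, {m.seg_cfg.k_max}], "
            f"N={m.seg_cfg.n_replicates} (2N sentences per CGI)",
            f"hidden dim H:       {self.network.hidden}",
            f"training:           {m.train_cfg.epochs} epochs, "
            f"lr={m.train_cfg.learning_rate}, batch={m.train_cfg.batch_size}, "
            f"dropout={m.train_cfg.dropout}, "
            f"weight_decay={m.train_cfg.weight_decay}",
            f"seed:               {self.seed}",
            "per-epoch mean training loss: "
            + ", ".join(f"{x:.4f}" for x in self.loss_trace),
        ]
        return "\n".join(lines)
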