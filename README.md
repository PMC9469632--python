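# cmic

Classification of CpG-island (CGI) methylation inheritance from sequence.

In early mammalian development most oocyte-derived CGI methylation is erased,
but a subset survives reprogramming in the maternal genome of the blastocyst.
`cmic` asks whether the CGI sequence itself predicts that outcome — M2M
(methylation inherited, class 0) versus M2U (methylation lost, class 1) —
and implements the full modelling stack for doing so with only a few hundred
labeled CGIs:

1. **Augmentation** — each sequence `s` is split into non-overlapping
   k-mers with lengths drawn uniform on `{k_min, …, k_max}` (defaults 4–12);
   repeating the random split N times for `s` and N times for its reverse
   complement yields 2N *cognate sentences* sharing the CGI's label.
2. **splitDNA2vec** — CBOW word2vec k-mer embeddings (D = 20, window 10,
   min count 1) trained, without labels, on the same kind of sentences;
   shuffled-map and overlapping (dna2vec-style) control schemes included.
3. **BiGRU** — a bidirectional gated recurrent unit reads each embedded
   sentence; the gate equations

       r_t = σ(W_r x_t + U_r h_{t−1} + b_r)
       z_t = σ(W_z x_t + U_z h_{t−1} + b_z)
       h̃_t = tanh(W x_t + U (r_t ⊙ h_{t−1}) + b_h)
       h_t = z_t ⊙ h_{t−1} + (1 − z_t) ⊙ h̃_t

   feed a concatenation of the two final hidden states into a sigmoid head
   giving P(unmethylated).  Training minimises
   `L(w) = E(ŷ, y) + α·‖w‖₂` (summed cross-entropy plus an unsquared-norm
   penalty) with Adam.  Forward, backward and optimiser are pure numpy —
   no deep-learning framework — and are verified against an independent
   scalar oracle and finite differences.
4. **WGBS labeling** — read-count thresholding (minimum coverage T, ratio
   thresholds β_M / β_U) for oocyte and blastocyst samples, combined into
   M2M / M2U / excluded inheritance classes.
5. **Evaluation** — CGI-level 3-fold stratified cross-validation with
   balanced accuracy, F-measure, MCC and AUC (fold mean ± SE), per CGI and
   per sentence, plus sweep drivers (k-range, N, embedding schemes) and
   long-CGI generalization bins.
6. **Synthetic data** — CGI-like GC-rich sequences (150/60 class imbalance,
   200–500 bp, planted strand-randomised 10-mer motifs) and read-count
   tables with analytically guaranteed labels, so everything above is
   testable without downloads.

See `docs/methods.md` for the model details and design decisions.

## Worked example

```python
from cmic import CmicModel, SyntheticSpec, generate_dataset
from cmic.config import scaled_down_configs

seqs, truth = generate_dataset(SyntheticSpec(seed=0))   # 150 M2M + 60 M2U
seg, emb, tr = scaled_down_configs()                    # N=50, H=32 desk scale
model = CmicModel(seqs, seg_cfg=seg, emb_cfg=emb, train_cfg=tr,
                  embedding_mode="V")
cv = model.cross_validate(k=3, seed=1)
print(cv.summary_frame().to_string(index=False))
```

prints

```
       level  balanced_accuracy  balanced_accuracy_se  f_measure  f_measure_se      mcc   mcc_se      auc   auc_se
     per_cgi           1.000000              0.000000   1.000000      0.000000 1.000000 0.000000 1.000000 0.000000
per_sentence           0.906283              0.002592   0.879433      0.002136 0.836267 0.004783 0.979306 0.002309
```

Per-CGI calls (the mean over a CGI's 2N cognate sentence probabilities,
thresholded at 0.5) recover the planted class of every held-out CGI; the
per-sentence rows show that individual random splits are noisier views of
the same signal, which is exactly why the cognate ensemble helps.  A single
fitted model is available as `results = model.fit(seed=1)` with
`results.predict()`, `results.summary()` and `results.save(path)`.

The same pipeline is scriptable: `cmic simulate`, `cmic augment`,
`cmic embed`, `cmic label`, `cmic train`, `cmic predict`, `cmic evaluate`,
`cmic sweep` (see `cmic --help`).

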