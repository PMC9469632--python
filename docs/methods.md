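# Methods

## Problem and model

The package classifies CpG-island (CGI) sequences by whether oocyte-derived
DNA methylation is inherited in the maternal genome of the blastocyst (M2M,
class 0) or lost (M2U, class 1), from sequence alone.  The central obstacle
is data volume: only a few hundred informative CGIs exist, far too few to
train a recurrent network directly.  The method therefore augments each CGI
into many alternative token-level views and classifies those.

**Variable-length k-mer augmentation.**  A sequence `s` is split left to
right into non-overlapping k-mers whose lengths are drawn i.i.d. from the
discrete uniform distribution on `{k_min, …, k_max}` (defaults 4 and 12).
The split is repeated N times for `s` and N times for its reverse complement,
giving 2N *cognate sentences* that share the CGI's label.  N defaults to
1000.  Two details the procedure must fix itself:

* *Tail fragments.*  When the remaining suffix is shorter than the drawn
  length, the entire suffix becomes the final token, even if shorter than
  `k_min`.  Discarding bases would make reconstruction impossible and leak
  sequence length into the token statistics; because the embedding stage
  counts every token (`c_min = 1`), short tail tokens are legal vocabulary.
* *Ambiguity codes.*  `N` bases are carried verbatim; tokens containing `N`
  are ordinary vocabulary entries.  CGI sequences rarely contain them and
  silent exclusion would be surprising.

Randomness is organised as one master seed with per-(sequence, origin,
replicate) substreams derived through `numpy.random.SeedSequence`, so
augmentation output is independent of iteration order.

**splitDNA2vec embeddings.**  k-mer vectors (dimension D = 20) are trained
with word2vec in CBOW mode, context window 10, minimum count 1, on the 2N
non-overlapping sentences per available sequence.  Training is unsupervised
and, following the original design, transductive (the corpus spans training
and test sequences); an inductive run simply passes a table trained on the
training folds.  Control schemes: a *shuffled* table (token → vector map
permuted uniformly at random) and the *overlapping* stride-1 corpus
(dna2vec-style), with either one replicate or N replicates per sequence.

The CBOW trainer is implemented in numpy inside the package: negative
sampling with 5 noise words drawn from the unigram distribution raised to
3/4, 5 epochs, learning rate decaying linearly from 0.025 to 1e-4, updates
applied in mini-batches of 512 with bincount-based gradient accumulation,
float32 internals.  A fixed seed reproduces training exactly (single
process).  The window is a fixed 10 tokens each side (no random window
shrinking).  One empirical property worth knowing: CBOW input-vector
similarity is driven by *shared contexts*; two tokens that always appear as
each other's context do not end up with similar input vectors.  The unit
tests probe geometry through shared-context constructions for this reason.

**BiGRU classifier.**  Each sentence is embedded token-wise and read by a
bidirectional GRU.  One step computes

    r_t = σ(W_r x_t + U_r h_{t−1} + b_r)
    z_t = σ(W_z x_t + U_z h_{t−1} + b_z)
    h̃_t = tanh(W x_t + U (r_t ⊙ h_{t−1}) + b_h)
    h_t = z_t ⊙ h_{t−1} + (1 − z_t) ⊙ h̃_t

with zero initial hidden states.  The final hidden states of the two
directions are concatenated (2H), passed through dropout, then a fully
connected layer and a sigmoid; the output is the probability of the input
being unmethylated.  Training minimises `L(w) = E(ŷ, y) + α·‖w‖₂`, where E
is the summed binary cross-entropy and the penalty uses, as written, the
*unsquared* global L2 norm of the non-bias weights (the conventional squared
form sits behind `TrainConfig.decay_squared`).  The penalty covers the
recurrent and head weight matrices; biases and the embedding matrix are
exempt — the embedding's scale is set by pre-training, and in trainable
mode its rows are updated with lazy row-sparse Adam (only rows touched by a
batch move), so a dense decay gradient would be both disproportionate and
expensive.  Optimisation is Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8).
Probabilities are clipped to [1e-7, 1 − 1e-7] before logarithms.

Default hyper-parameters: N = 1000, D = 20, H = 256, 2 epochs, learning rate
1e-4, batch size 32, dropout 0.5 (applied to the concatenated BiGRU output),
weight decay α = 0.01.

Forward, backward (hand-derived gradients) and Adam are all numpy; the test
suite checks the vectorised recurrence against an independent scalar
implementation of the printed equations (1e-6) and the analytic gradients
against central finite differences (relative error ≤ 1e-4).  Variable-length
batches are padded with a dedicated zero row of the embedding matrix and
masked so that padded positions freeze the hidden state; a sentence scored
alone and inside a padded batch produces identical output to machine
precision.

**Per-CGI calls.**  The network scores sentences; a CGI call aggregates the
2N cognate probabilities by their mean and thresholds at 0.5, with a tie
counting as methylated (the decision rule is strictly "greater than").
Reverse-complement sentences participate at inference exactly as in
training.  Per-sentence metrics are also reported, since the sentence is the
network's actual training instance.

## Labeling from WGBS counts

Per CGI and cell type, the methylation ratio is methylated read count over
whole read count; CGIs with fewer than T reads are excluded, ratio ≥ β_M
gives M, ratio < β_U gives U, and intermediate ratios are excluded (the two
labeled regions are the only defined ones).  Presets: fully grown oocytes
T = 100, β_M = 0.8, β_U = 0.1; blastocyst maternal genome T = 20, β_M = 0.4,
β_U = 0.1.  The inheritance target is defined on FGO-methylated CGIs:
(M, M) → M2M, (M, U) → M2U, anything else excluded.  Sequences longer than
500 bp (inclusive boundary) are routed to a separate long-CGI set evaluated
in length bins [501, 601), …, [901, 1001), [1001, ∞).  Producing count
tables from alignments is upstream of this package.

## Evaluation protocol

3-fold stratified cross-validation at the CGI level: all cognate sentences
of a CGI stay in one fold, per-fold class proportions are balanced to within
one CGI, and the harness asserts on every run that no CGI id appears on both
sides of a split.  Metrics: balanced accuracy, F-measure (positive class =
unmethylated, matching the sigmoid head), Matthews correlation coefficient
and AUC, reported as fold-wise mean ± standard error (K−1 denominator).
Zero-denominator conventions: precision/recall → 0, MCC → 0; AUC is missing
when a fold's truth is single-class.

## Synthetic data

The generator emulates the shape of the real inheritance dataset: 150 + 60
sequences, lengths uniform on [200, 500] bp, GC content 0.65, CpG-boosted
dinucleotides, with class separability supplied by planted 10-mer motifs
(3 copies per sequence, random positions, random strand) so that
reverse-complement augmentation is genuinely informative.  The background is
a first-order chain in which every row keeps total G+C probability equal to
the target GC (so the marginal GC law holds exactly) and the C-row moves
mass from C to G by the CpG boost factor, capped at feasibility — at
GC = 0.65 a nominal boost of 5 saturates at an effective factor of 2.
Count-table fixtures sample read counts inside the region that analytically
guarantees each CGI's intended label, so labeling can be checked for exact
recovery.

What the generator does *not* emulate: real CGI sequence grammar (repeats,
transcription-factor sites), bisulfite noise, or any coupling between
sequence and read counts.  Passing the recovery experiments therefore shows
that the pipeline can find planted, strand-symmetric, local sequence signal
under the published protocol — not that it reproduces the real-data
F-measures, which require the original WGBS accessions.

## Scaled-down study conditions

The recovery experiments run at desk scale: N = 50 sentences per sequence,
H = 32 hidden units, three CV seeds.  Two deliberate departures from the
full-scale defaults come with it:

* **Trainable embeddings ("V" mode).**  At N = 50 a given long k-mer occurs
  only a handful of times in the embedding corpus (vs hundreds at
  N = 1000), so frozen CBOW vectors are undertrained and carry little
  signal; letting the classifier update them restores capacity.  V mode is
  also the strongest variant at full scale.
* **Learning rate 1e-3.**  The default 1e-4 was calibrated for a schedule
  of roughly 26k Adam steps; the scaled run takes about 15× fewer, and the
  step size is raised in proportion so total optimisation travel is
  comparable.

Both are fixed in `cmic.config.scaled_down_configs()` and used by the test
suite and the acceptance script alike.  Under these conditions the planted
signal is recovered essentially perfectly (per-CGI F ≈ 1.0), the
no-motif control sits at chance, and N = 50 dominates the N = 1 control,
mirroring the qualitative benefit of augmentation.

## Known limitations

* The CBOW trainer applies mini-batched SGD rather than word2vec's
  per-example updates; with the small learning rates involved the
  difference is a smoothing of the update sequence.
* The unsquared-norm weight decay is implemented as printed; at ‖w‖ → 0 its
  subgradient is taken as 0.  The conventional squared form is a switch.
* Lazy sparse Adam for the embedding matrix skips momentum decay on
  untouched rows; this is the standard sparse-Adam approximation.
* Real-data performance claims are out of scope: the package's experiments
  are synthetic by design, and the real WGBS accessions are not fetched.
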