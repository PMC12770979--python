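# motifattn

Inferring cooperative transcription-factor (TF) binding from the
self-attention maps of a DNA sequence classifier.

Gene regulation is orchestrated by TFs binding DNA motifs in close
proximity to one another. Given only sequences and labels (e.g. accessible
vs. inaccessible chromatin), a convolutional network with a multi-head
self-attention layer learns which sequence positions are relevant to each
other — and those attention maps can be mined for *pairs of motifs* that
the model treats as jointly informative, i.e. candidate TF–TF
cooperativity. `motifattn` implements that entire workflow for people who
study regulatory sequence: the model, an entropy penalty that makes the
attention maps sparse enough to read, the statistics that turn attention
values into significant motif pairs, and a simulation benchmark with
implanted ground-truth interactions to measure precision and recall.

## The model and the statistic

One-hot DNA passes through a 1D convolution (motif scanner), ReLU and a
small max-pool; the pooled features `X` enter multi-head scaled dot-product
attention

    Q = XW_q,  K = XW_k,  V = XW_v,
    A = softmax(QKᵀ / √d_k),   Z = A·V,

and `Z` feeds a fully connected classifier (optionally preceded by a
bidirectional LSTM, or followed by residual convolution blocks in the deep
variant). Training minimizes

    Loss = Loss_c + λ · Loss_e,
    Loss_e = − Σ_heads (1/n) Σ_ij A_ij ln A_ij,

binary cross-entropy plus λ times the mean Shannon row entropy of the
attention maps — the entropy term drives `A` toward sparse, near-binary
maps that are easy to threshold and interpret.

To call interactions, attention heads are combined by an elementwise
maximum; position pairs above the per-sequence mean are mapped to the
convolutional filters active at those positions (activation ≥ 0.65 of the
filter maximum, or half the maximal PSSM score for PWM-pre-loaded
filters); per filter pair, foreground scores (correctly predicted
positives) are compared with background scores (negative examples, or
dinucleotide-shuffled sequences for multi-label tasks) with a one-sided
Mann–Whitney U test, Benjamini–Hochberg corrected (q ≤ 0.05). Filters are
translated to motif names by PWM correlation matching; an *attribution*
mode scores interactions by integrated gradients of the output with
respect to the attention values instead of raw attention. Details and all
defaults: [docs/methods.md](docs/methods.md).

## Worked example

`examples/04_infer_interactions.py` simulates a 6-motif / 3-pair benchmark
(6 000 × 200 bp), trains the basic entropy-regularized model, and infers
interactions (a few minutes on one core):

```
classifier test AUC 0.901

interpreted 258 correctly predicted positives against 229 negatives
203 significant filter pairs -> 8 motif pairs (q <= 0.05):

motif_a motif_b  n_support  median_fg_score  q_value
  TF001   TF004        197         0.973307 0.000302
  TF000   TF001        161         0.950835 0.000302
  ...
  TF000   TF002         95         0.627224 0.001437
  TF002   TF005        159         0.847611 0.004123

ground truth: [('TF000', 'TF002'), ('TF001', 'TF003'), ('TF004', 'TF005')]
precision 0.12  recall 0.33  F1 0.18
```

Reading this: the classifier cleanly separates pair-bearing from
isolated-motif sequences (AUC 0.90); 8 motif pairs are significant, each
supported by ~100–200 test sequences whose attention linked the two
motifs' filters (`median_fg_score` is the attention value, near 1 under
the entropy penalty); the implanted pair TF000–TF002 is recovered.
Precision is the method's hard part — motifs that merely co-occur with a
true pair also attract attention — which is exactly what the entropy term
and the benchmark are for. `examples/05_entropy_sparsity.py` shows the
entropy term halving the mean attention row entropy (3.35 → 1.88 nats)
at similar AUC.

The other examples cover motif I/O and matching (01), the simulator and
its file formats (02), plain training (03), and the config-driven pipeline
(06), which is also exposed as a CLI:

```bash
motifattn run --config config.yaml --outdir run/   # simulate→train→interpret→evaluate
motifattn report --outdir run/
```

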