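# plmscreen

Desk-scale protein language-model screening of translated ORFeomes:
train a small character-level causal sequence model to separate target
(e.g. microalgal) from contaminant (e.g. bacterial) protein sequences,
and interrogate *why* it decides the way it does.

Genome assemblies from algal cultures are routinely contaminated with
bacterial sequences, and a large fraction of translated ORFs — the
"dark proteome" — returns no homology hits at all, so alignment-based
screening leaves most sequences unclassified. A generative classifier
sidesteps homology entirely: a decoder-only model is trained with the
next-token objective

    p(x_t | x_<t; θ) = softmax(W h_t + b)

on sequences that end in a class-tag token, and a query is classified
by the next-token distribution at the end of the prompt restricted to
the tag tokens, ŷ = argmax_y p(y | x; θ). Training data comes in two
regimes: full-length tagged sequences (TI-inclusive), or *TI-free
chimeras* — each class's proteome concatenated into one "unisequence"
and cut into fixed 100-residue fragments (f_j = (a_{(j−1)l+1}, …,
a_{jl}), l = 100), destroying terminal information and gene boundaries
so the model must rely on internal sequence signal alone.

The package implements the full loop plus an interpretability suite:

* `synthetic_data` — two-class synthetic proteomes with controlled
  residue composition and planted motifs (no downloads needed);
* `dataprep` — unisequence construction, 100-residue fragmentation,
  1:1-balanced assembly and splits, `"<"+tag` preparation, exact-match
  holdout dedup screening;
* `model` — character-level tokenizer and a NumPy causal transformer
  with hand-written backprop (AdamW, cosine schedule, best-checkpoint
  export) exposing logits, embeddings, per-layer hidden states and
  attention maps;
* `classify` — tag-token prediction, fragment-vote aggregation for
  long proteins, precision/recall/F1 with macro and weighted means;
* `attribution` — gradient×embedding (SHAP-like) scores with an exact
  Shapley oracle, integrated gradients (completeness-checked),
  windowed reference-based attribution (window 32, stride 16), and
  elbow-selected k-means over attribution matrices;
* `motifs` — hidden-state influence profiles, class-separation index
  I(a, i) = ‖μ_{a,i} − μ_{¬a,i}‖₂, flexible (degenerate, "XRXDX"-style)
  and strict (composite 0.4·divergence + 0.3·attention + 0.3·IG)
  motif finders;
* `projections` — layer-wise uncentered SVD of hidden states,
  Z(l) = H(l) V[:, :2], tracking residue features through depth;
* `domains` — regex scanning of motifs against a PFAM-A-like FASTA
  with overlap counting and weighted score = count × mean influence.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

```python
from plmscreen import predict_tag, shap_like
from plmscreen.benchmark import run_tifree_benchmark

bench = run_tifree_benchmark(seed=1)          # ~8 minutes on one CPU
print(f"held-out macro F1: {bench.metrics.macro_f1:.4f}")
print(f"held-out accuracy: {bench.metrics.accuracy:.4f}")

frag, label = bench.datasets["test"].items[0]
pred = predict_tag(bench.model, frag, bench.tag_map)
print(pred.predicted, {k: round(v, 3) for k, v in pred.posterior.items()})
```

prints (seed 1):

```
held-out macro F1: 0.9960
held-out accuracy: 0.9960
algal {'algal': 0.209, 'bacterial': 0.151}
```

The benchmark generates 3,000 100-residue sequences per class from the
default contrasting profiles (class A enriched in Q/A/R, class B in
G/S/L), fragments and balances them 1:1 (~2,000 training and ~500
held-out test fragments per class), trains the default 2-layer,
d = 64 model for 600 steps, and evaluates by tag argmax on the test
split. Macro F1 ≈ 0.996 on held-out chimeric fragments shows the
model recovers the compositional contrast. The posterior line shows
the decision for one test fragment: after only 600 steps the model
still spreads next-token mass over residue tokens, but the correct
class tag carries clearly more mass than the wrong one (0.209 vs
0.151), and the argmax over tags is what classifies. A chance control
(both classes drawn from the same profile) lands at accuracy ≈ 0.49,
confirming no label leakage in the pipeline.

The same surface is scriptable from the shell (`plmscreen generate`,
`prep-tifree`, `train`, `classify`, `evaluate`, `explain`,
`mine-motifs`, `pfam-scan`, `project`); every command is a thin wrapper
over the functions above.

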