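# Methods

## Problem and model

`plmscreen` addresses contamination screening of translated ORFeomes:
deciding, per protein sequence, whether it originates from the target
organism (e.g. a microalga) or a contaminant lineage (e.g. bacteria),
without alignment or homology search. The classifier is a small
character-level decoder-only transformer trained with the plain
next-token objective

    p(x_t | x_<t; θ) = softmax(W h_t + b)
    L(θ) = − mean over non-pad target tokens of log p(x_t | x_<t; θ)

over training strings that end in a single class-tag token. Class
membership is then read out generatively (tag-token classification):
the next-token distribution at the end of a prompt, restricted to the
tag tokens, is the class posterior, and ŷ = argmax_y p(y | x; θ).

Two training regimes are supported:

* **TI-free** — all sequences of a class are concatenated into one
  "unisequence" and cut into fixed 100-residue chimeric fragments
  (f_j = (a_{(j−1)l+1}, …, a_{jl}), l = 100, trailing remainder
  discarded), destroying terminal information (TI): N-/C-terminal
  signals and gene boundaries. The tag is appended directly to each
  fragment.
* **TI-inclusive** — full-length sequences with `"<" + tag` appended;
  the `<` delimiter marks the switch from sequence to label sampling.

Class pools are balanced by downsampling to the smallest pool (1:1 for
two classes), shuffled once, then split 2/3 / 1/6 / 1/6 into
train/eval/test. Holdout splits are screened against the training set
by fixed-string whole-line matching of the bare fragment text, and
exact duplicates are removed.

## Architecture and optimization

The model is implemented directly in NumPy with a hand-written backward
pass (verified against central finite differences in the test suite to
~1e-6 relative error in float64). Blocks are pre-norm: causal
multi-head self-attention and a GELU MLP, each with a residual
connection; learned token and position embeddings; final layer norm;
untied output projection. The desk-scale default is 2 layers,
d_model = 64, 4 heads, context 128 — deliberately small enough to train
in minutes on one CPU while preserving the multi-layer structure the
interpretability tools need; all sizes are configurable upward.

Optimizer: AdamW with weight decay 0.01 (weight matrices only),
initial learning rate 1e-4, cosine decay with linear warmup
(100 steps at the default scale), batch size 64. Loss covers all
non-pad tokens (sequence and tag); a tag-only loss is available as an
ablation. Pad positions are masked out of the loss. Periodic
checkpoints are scored by eval macro-F1 and the best one (ties to the
earlier step) is exported, since over-trained checkpoints degrade.

## Synthetic data: what it emulates, and what it does not

The generator emulates the two signal types that separate real algal
and bacterial proteomes: bulk amino-acid composition and short
recurrent motifs. The default benchmark profiles enrich class A in
Q/A/R (0.12/0.10/0.10) and class B in G/S/L, with the remaining mass
uniform over the other canonical residues, 'X' at 0.1% to exercise
ambiguity handling, one planted 5-mer motif per class (insertion
probability 0.25, written over residues at a uniform position so the
length distribution is untouched), and fixed 100-residue lengths.
Benchmark sizes: ~2,000 training fragments and ~500 held-out test
fragments per class, with an equally sized eval split driving
checkpoint selection; the model is trained for 600 steps.

These are i.i.d.-residue sequences: they carry no phylogenetic
structure, no codon/GC-level signal, no length variation beyond the
configured bounds, no shared homologous domains, and far weaker
long-range structure than natural proteins. Passing tests therefore
demonstrates that the pipeline recovers compositional and motif signal
under controlled conditions — not that the desk-scale model matches
production-scale accuracy on real proteomes.

A chance control reruns the identical pipeline with both classes drawn
from the *same* profile; held-out accuracy must sit at chance, which
guards against label leakage anywhere in the data path.

## Interpretability suite

* **Gradient × embedding (SHAP-like)** — φ_i = Σ_j (∂L/∂e_ij) e_ij
  with L the loss of predicting the target tag. An exact Shapley
  enumerator (≤ 12 features, full 2^n subsets) serves as the test
  oracle; with an additive scalar (the raw tag logit of a linear head)
  the two coincide, and the efficiency/symmetry/additivity axioms are
  asserted to 1e-9.
* **Integrated gradients** — midpoint Riemann approximation of the
  path integral from a reference embedding to the input, target = the
  pre-softmax tag logit at the last position; 50 steps by default.
  The reference is the pad-token embedding (a zero-vector option
  exists). Completeness (Σ IG = F(x) − F(x0)) is asserted within 1%
  at 50 steps and improves monotonically with step count.
* **Windowed reference-based attribution** — sequences are processed
  in sliding windows (window 32, stride 16; a final truncated window
  covers any tail), each window tokenized and attributed
  independently against the reference. The per-window attribution is
  computed by the same straight-line path integral, which realizes the
  reference-comparison contract exactly: per-window scores sum to
  Δy = y(x) − y(x0). A plain gradient×(input−baseline) rule satisfies
  that contract only to first order on a trained nonlinear model, so
  the path-integral form is used. Overlapping windows are combined by
  the arithmetic per-position mean (sum available).
* **Attribution clustering** — k-means (10 restarts, fixed seed) on
  z-scored attribution rows; k = 1..min(10, n); the selected k is the
  first whose percentage inertia decrease vs k−1 falls below 20%
  (if inertia is already ~0 at k−1, that k−1 is selected; if no k
  qualifies, the largest is used).
* **Influence profiles and motif mining** — per layer, influence at
  position i is ‖h_i − mean(h)‖₂, min-max normalized per layer before
  averaging across layers (the per-layer-then-average order follows
  the normalization being defined per layer's score vector). The
  flexible finder takes peaks above the 95th percentile (minimum
  inter-peak distance = window size, the same default the window
  parameter uses), masks below-threshold positions to 'X', requires
  ≥ 2 strictly-above-threshold residues, merges overlapping or
  adjacent hits (length-weighted mean influence) and ranks by mean
  influence. The strict finder min-max normalizes three channels —
  hidden-state divergence, the mean self-attention diagonal, and
  integrated gradients — combines them as 0.4/0.3/0.3, and accepts
  3–9-residue windows whose mean composite exceeds the 95th
  percentile with ≥ 75% of residues individually above it; hits
  strictly contained in a longer accepted hit are dropped (no merging,
  so degenerate single-position acceptance stays exact). All
  percentiles use linear interpolation between closest ranks.
* **Class-separation index** — I(a, i) = ‖μ_{a,i} − μ_{¬a,i}‖₂ over an
  aligned corpus, thresholded at the 95th percentile to form the motif
  seed set M; positions whose complement set is empty are excluded and
  counted.
* **Layer-wise projection** — the hidden-state matrix of each layer
  (layer 0 = embeddings after positional mixing, then each block
  output) is decomposed by *uncentered* SVD, H = UΣVᵀ, and residues
  are projected onto the first two right-singular axes, Z = H V[:, :2];
  centered (conventional PCA) is an option. Sign convention: each
  singular vector is flipped so its largest-magnitude loading is
  positive; near-degenerate top singular values are flagged. A
  separation statistic (mean inter-class centroid distance over mean
  intra-class spread, classes = residue identity) is computed on the
  full-dimensional hidden states — the 2D projection is for display;
  measuring the trend in the shadow would conflate projection loss
  with representation change.
* **Domain mapping** — degenerate motifs ('X' = any residue) are
  compiled to regular expressions and scanned over a PFAM-A-like
  FASTA with overlapping matches counted (lookahead scanning);
  counts aggregate per accession (`PFxxxxx` token, version stripped,
  else the first header token). Each (motif, accession) pair scores
  weighted = count × mean influence; rows sort by weighted score
  descending, ties by count descending then motif ascending, with a
  stable sort so the operation is streaming-friendly.

## Inference conventions and edge cases

Tag posteriors are read from the first generated position; an optional
scan mode instead generates k = 9 tokens greedily and takes the first
tag found ("unknown" if none appears). Ties in the tag posterior break
deterministically to the first class in configured order and are
flagged. Full-length proteins in TI-free mode vote over non-overlapping
100-mers; the trailing remainder is classified as its own padded
fragment so whole proteins are covered (inference must not discard
residues the way training preparation does); tied votes yield
"unknown". In metrics, "unknown" counts as a false negative for its
true class and never as a false positive; macro-F1 is the unweighted
per-class mean and weighted-F1 the support-weighted mean.

Numerical details: layer-norm epsilon 1e-5; causal masking by additive
−1e9; training in float32 (float64 for gradient-check fixtures);
min-max normalization of a constant vector returns zeros; k-means and
all stochastic steps take explicit seeds, and generation is
byte-reproducible for identical inputs.

## Known limitations

The NumPy training loop is single-device and unbatched across
sequences of different lengths (strings are padded to the widest item);
no dropout or data augmentation is implemented; posteriors are not
calibrated; the synthetic benchmark's separability means its accuracy
ceiling is ~1.0 and results do not transfer quantitatively to natural
proteomes; protist-like near-boundary contaminants, four-way taxonomy
at scale, and alignment-tool comparisons are out of scope.
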