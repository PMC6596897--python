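# Methods

## Model

A classifier over fixed-length DNA sequences is a layer composition
`F = F_n ∘ … ∘ F_1` on the one-hot encoding `X ∈ R^{4×N}` (channel order
A, C, G, T; 1-based statements below map to 0-based code by `k ↔ k−1`,
`−k ↔ size−k`). The reverse-complement (RC) group has two elements; its
action on the input — and on every hidden `[C, L]` tensor — is reversal of
both axes, `RC(T)[i, j] = T[−i, −j]`. A layer is *equivariant* when
`F(RC_in(X)) = RC_out(F(X))`; the network is *invariant* when the final
action is the identity.

Layer constructions and the conditions under which they are equivariant:

* **Convolution** (valid padding, stride 1):
  `C(X)[i, j] = f(Σ_{m,n} X[m, j+n−1] W[m, n, i] + b[i])`. Equivariance
  requires the weight tie `W[m,n,i] = W[−m,−n,−i]` and the bias tie
  `b[i] = b[−i]` (the bias tie is a necessary completion: an untied bias
  breaks the symmetry as soon as the tied filters differ). We store only the
  first `n_f/2` filters (`FreeConvParams`) and construct the full bank on
  every forward pass, so the tie holds bitwise at every training step and
  gradients flow through the symmetrization. `n_f` must be even; an odd
  count would need a self-RC-symmetric middle filter, which we do not
  support.
* **Spatial max-pool**, stride = width: equivariant as-is. The standalone
  operation requires the width to divide the length; inside a network stack
  the trailing remainder is cropped instead. Cropping is only reached after
  orbit pooling (where RC already acts as the identity), so exact invariance
  is unaffected.
* **RC orbit pooling**: reduce each orbit `{(i,j), (−i,−j)}` along the
  filter axis by max, sum or mean, halving the channel count. Afterwards RC
  is the identity, so dense layers need no symmetry of their own — the
  network validator therefore requires an orbit-pool layer before the first
  dense layer in equivariant configurations.
* **Dropout**: Hadamard mask `eps ~ Bernoulli(keep_p)`, sampled once per
  training batch and shared across the batch. Equivariant mode draws one
  Bernoulli variable per orbit (`C·L/2` free draws) and copies it to both
  members, giving `eps = RC(eps)` exactly.

Prediction is either **Monte Carlo dropout** — average of `K` stochastic
passes, each with a mask set sampled once and applied to every test example,
so the predictive function is a fixed (and, with equivariant masks, exactly
RC-symmetric) function — or **weight averaging** — a single pass with no
masks.

### Numerical conventions

* *Inverted dropout scaling.* Masked activations are divided by `keep_p`
  during training and during MC passes; weight-averaged prediction applies
  no mask and no scaling. This makes `keep_p = 1` reduce exactly to the
  no-dropout network and keeps expected activations scale-stable. `keep_p`
  is the keep probability throughout the API; the drop rate is `1 − keep_p`.
* *Loss.* Softmax cross-entropy over the two classes, plus an optional L2
  penalty `l2 · Σ w²` on free convolution weights and dense weights (not
  biases).
* *Optimizer.* Adam (default, lr 3e-3, batch 64) or plain mini-batch SGD.
  Adam is the default because the desk-scale fixtures should converge within
  about ten epochs; nothing in the layer algebra depends on the optimizer.
* *Output-layer initialization.* Final dense weights all 1, biases
  `(1, −1)`; hidden weights use scaled (He) normal initialization. A
  consequence worth knowing: an *untrained* model is a constant function of
  its input, because all-ones output weights give both logits the same
  channel sum. Tests that need input-dependent behaviour from random models
  randomize the output head explicitly.
* *Tie-breaks.* Orbit max-pooling routes gradients to the first orbit member
  on exact ties; spatial/global max route to the lowest position index.

## Synthetic data generator

The simulator emulates a regulatory element bound by two proteins: draw a
label `y ~ Bernoulli(0.5)`; draw an i.i.d. background sequence (uniform
composition by default, configurable); independently for each of the two
PWMs, with probability 0.4 (`y = 1`) or 0.2 (`y = 0`), sample a concrete
instance column-wise from the PWM, reverse-complement it with probability
1/2, and write it at a uniform random position. Defaults are 40 000
sequences of length 1000. Overlapping injections are allowed (the second
overwrites; both are logged); labels are drawn first and injections
conditioned on them, so motif presence is the only label signal. Every
injection is logged exactly (id, PWM, position, strand, instance).

Two synthetic PWMs are bundled so the package is self-contained — a sharp
10-mer (dominant base weight 0.97) and a degenerate 8-mer with a
near-uniform core — standing in for database motifs; real JASPAR PFM files
load through `read_jaspar_pfm`. What the generator does *not* emulate:
genomic background composition and repeats, motif clustering/spacing
grammar, GC heterogeneity, and measurement noise in labels beyond the
injection probabilities. Passing tests on this generator therefore
demonstrate the symmetry and estimation machinery, not real-genome
performance.

Because motif presence is Bernoulli in both classes, the generator imposes a
hard information ceiling on classification: with per-motif injection
probabilities `p₁, p₀`, the best possible AUROC is
`P(S₁ > S₀) + ½·P(S₁ = S₀)` where `S_y` counts injected motifs under class
`y` — e.g. 0.855 for two motifs at 0.6/0.1, 0.75 for one. Hold-out AUROCs on
such fixtures must be read against that ceiling, not against 1.0.

## Hotspot segmentation and controls

A two-state HMM with exponential emissions `f(x; μ) = exp(−x/μ)/μ` models
windowed recombination rates (cM/Mb). Parameters are set by **Viterbi
training** (hard EM): decode the most probable path (log-space DP), then
re-estimate each state's mean as the sample mean of its assigned windows and
the transition matrix from path transition counts with add-one smoothing;
stop when the path no longer changes or the largest parameter change is
below `tol`. State 0 is "hot" under the convention `mean_hot > mean_cold`,
enforced by swapping if estimation inverts it. Rates of exactly 0 are
floored at `1e-6` cM/Mb so a state capturing only zeros cannot degenerate
the mean estimate. The initial distribution is held fixed (uniform by
default); with tracks of thousands of windows it is immaterial.

Downstream rules: maximal runs of hot windows merge into intervals;
intervals over `max_len = 4000` bp are discarded as poorly localized; the
centered `out_len = 1000` bp window (center `floor((start+end)/2)`) is
extracted, dropping windows containing N or overrunning the contig. For each
hotspot, a *coldspot* control is the first window, scanning outward in 1 kb
steps alternating right/left within 300 kb, with GC within 0.10 of the
hotspot's GC (absolute difference of fractions; a relative ±10% mode exists
behind `relative_gc=True`), mean overlap-weighted track rate below 0.5
cM/Mb, no N, and no overlap with hot intervals or previously chosen
coldspots. The outward-alternating order is our concretization of "greedy";
coordinates are 0-based half-open (BED).

## Motif statistics

Scanning counts *occurrence positions* (overlaps allowed), by default on
both strands, with a position matching both the pattern and its RC pattern
counted once; both-strand counts are therefore invariant under
reverse-complementing the sequence set. Enrichment between hot and cold sets
is reported as the plain hot/cold occurrence-count ratio (a per-sequence
rate-ratio variant is available via `method="rate_ratio"`), with a two-sided
exact binomial test — null success probability = the hot fraction of
sequences — and Bonferroni correction over the tested motif set. Printed
2-decimal reference ratios are compared at the printed precision (one unit
in the last decimal): published tables round inconsistently (3.625 appears
as 3.63 but 1.645 as 1.64), so exact 2-dp equality against any single
rounding rule is unattainable in principle. Display rounding in this package
uses round-half-up.

Motif harvesting inverts the first layer: per RC-tied filter pair, each
sequence contributes its maximal first-layer activation and position; the
`min(top_k, #above the 0.99 activation quantile)` strongest sequences are
kept; the filter-length subsequence at each position is extracted, RC'd when
the partner filter fired harder, and stacked into base counts with
pseudocount 1, normalized to a PWM. Activations are rounded to 9 decimals
before ranking and exact strand ties resolve to the lexicographically
smaller orientation, making the harvest exactly invariant under RC of the
input set (strand-flipped evaluation otherwise perturbs floating-point sums
at ranking boundaries). Per-column information content is
`2 + Σ_b p_b log₂ p_b` bits (uniform background); the degenerate consensus
letter requires IC ≥ 0.5 bits and dominant-base probability ≥ 0.75, else N.

## Problem sizes used by the test suite

Chosen as the smallest sizes at which the statistical checks are
well-powered: layer equivariance on 100 random draws; exact RC symmetry on
100 random models × 100 sequences; Viterbi decoding vs brute-force path
enumeration for tracks up to length 12; parameter recovery from 10⁴
simulated windows at means 10.5/0.5 cM/Mb; simulator contract at its default
40 000 × 1000; end-to-end training fixtures of 4000 sequences of length 200
with an 80/20 split.

## Known limitations

* Only the two-element RC group; no general finite-group equivariance, no 2-D
  convolutions, dilation, or same-padding.
* A single, first-layer convolution per stack (the reference architecture);
  deeper convolutional stacks would need input-gradient propagation through
  convolution, which the trainer does not implement.
* Exponential emissions and two states only in the HMM; no posterior
  (forward–backward) decoding.
* The binomial enrichment test is a documented convention; published
  corrected p-values for the reference motifs are not reconstructable from
  counts alone and are not asserted.
* CPU-only numpy training: adequate for desk-scale fixtures, not for
  genome-scale hyperparameter searches.
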