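# Methods

## Problem

Intrinsically disordered protein regions (IDPRs) are contiguous stretches of
residues that lack a stable tertiary structure. `idrpred` treats their
identification as per-residue binary classification: each residue of a
protein sequence is labelled disordered (1) or ordered (0) from a 35-row
feature matrix derived from the sequence and an evolutionary profile.

## Feature model

Given a sequence `w = w1…wL` and an odd sliding-window size `N`
(default 33), the feature matrix `F` is `35 × L`; column `j` describes
residue `j`.

**Rows 1–20 — PSSM channels.** The 20 log-odds columns of a PSI-BLAST
position-specific scoring matrix supplied by the user (the package never
runs PSI-BLAST). Each channel is averaged over the `N`-window centred at
`j`, with `(N−1)/2` zeros appended at both sequence ends. A BLOSUM62
pseudo-profile (each residue's substitution row) is available behind an
explicit flag for profile-free operation.

**Rows 21–30 — scale channels.** Seven physicochemical descriptors
(steric parameter, polarizability, volume, hydrophobicity, isoelectric
point, helix and sheet probability; Meiler et al. 2001) and three disorder
propensities, averaged with the same zero padding. The propensity tables
shipped by default are synthetic stand-ins that reproduce the canonical
disorder-promoting (P, E, S, Q, K, G high) versus order-promoting
(W, C, F, I, Y low) split; they are flagged as synthetic in their
provenance strings and can be replaced from a JSON file.

**Row 31 — Shannon entropy.** `−Σ f_a log2 f_a` over residue frequencies
in the window. Entropy windows are padded with copies of the terminal
residues, not zeros; the two padding conventions (zeros for averaged scalar
channels, terminal copies for entropy channels) are followed deliberately.

**Row 32 — topological entropy.** Subword-complexity entropy: for the
largest word length `n` with `20^n + n − 1 ≤ N`, the value is
`log20(#distinct n-subwords of the first 20^n + n − 1 window characters)/n`,
in [0, 1]. With the default `N = 33` this calibrates to `n = 1` (distinct
residues among the first 20 window characters). Windows below 20 residues
cannot calibrate any word length; the track errors there, and feature
assembly therefore computes this row with window `max(N, 21)` so that
window-size sweeps down to `N = 3` still run.

**Row 33 — persistent entropy.** Each window is embedded on the unit
cylinder in R³: residue `m` (1-based in the window) with canonical
alphabet index `I ∈ {1..20}` maps to
`(cos(2πI/20), sin(2πI/20), (m−1)/(N−1))`, so residue identity becomes an
angle and window position a height. The Vietoris–Rips filtration of this
cloud is computed under the ball-intersection convention (a simplex enters
at half its longest pairwise distance). The persistent entropy of the
diagram is `E = −Σ p_i log2 p_i` with `p_i` the normalised bar lengths.
Choices the construction leaves open, fixed here:

* **Filtration cap `K`:** half the cloud diameter (configurable). At that
  scale the complex is complete, so the full dimension-0 merge tree is
  observed and exactly the one never-dying component is truncated at `K`.
* **Homology dimensions:** 0 and 1 pooled into one diagram (configurable).
  The circular residue embedding makes loops the informative signal beyond
  cluster structure.
* **Infinite bars** are truncated at `K`; zero-length bars are dropped
  (they would contribute `p_i = 0`).
* **Nonstandard residues** (B, J, O, U, X, Z) in a window are substituted
  by the window's most frequent standard residue (ties toward the lowest
  alphabet index) before embedding, keeping the track length `L`.
* Entropy is invariant under isometries and under rescaling of the cloud
  (the `p_i` are scale-free), which also makes it independent of the
  factor-of-two ambiguity between the ball-intersection and
  distance-threshold Rips conventions. Exported diagrams use the
  ball-intersection values.

Dimension-0 persistence is computed by Kruskal union-find over the edge
filtration; dimension-1 by Z2 reduction of the triangle boundary matrix
with bit-packed columns (numba-jitted, pure-Python fallback), with ties in
filtration values broken by vertex order for determinism. An independent
textbook full-reduction oracle in the test suite checks exact agreement on
random small clouds.

**Rows 34–35 — PCAA2/PCAA3 k-mer tracks.** Dipeptide and tripeptide
occurrence counts over a training corpus (sliding by one residue) are
normalised to probabilities and min–max scaled to [0, 1]; if all
probabilities are equal the scaled values are defined as 1. Position `j`
averages the scaled values of the 1..k k-mers covering it (fixed 1/2 and
1/3 weights at the near-terminal positions). K-mers containing nonstandard
residues are skipped in counting and contribute 0 to the averages, keeping
the probability normalisation over the standard alphabet. Query proteins
need not belong to the counting corpus; the pipeline builds tables on the
training split only.

## Classifier

Per residue, the 35-vector passes through:

1. **MLP1**: hidden layers of 35 and 3675 ReLU units; the 3675-vector
   output is reshaped to a 35×35×3 image.
2. **VGG19-style backbone**: five blocks of (2,2,4,4,4) 3×3 same-padding
   ReLU convolutions with (64,128,256,512,512) channels, 2×2 max pooling
   after each block (35→17→8→4→2→1 with floor pooling); no fully connected
   head.
3. The flattened backbone output (width 512) is linearly projected to 3675
   and **summed with MLP1's output** (skip connection). The projection is
   needed because the conv stack's flattened width cannot equal 3675 on a
   35×35×3 input; it is the minimal trainable repair that lets the two
   3675-wide branches be added.
4. **MLP2**: one 3675-unit ReLU hidden layer with 50% (inverted) dropout,
   then a single sigmoid unit giving the disorder probability. Calls use
   `probability ≥ threshold` (default 0.5, configurable).

Training pools residues across all proteins, shuffles them once (seeded)
into fixed "packages" of 128, and runs plain SGD (learning rate 1e-4 by
default) on the mean binary cross-entropy per package, with probabilities
clipped to [1e-7, 1−1e-7]. Epochs repeat until the epoch-mean loss moves
less than a tolerance or a maximum epoch count is reached. The dropout
stream is re-seeded identically at the start of each epoch, making a run a
pure function of (data, seed) and a zero learning rate a strict no-op.
Conv weights may be initialised from a user-supplied pretrained checkpoint
(`.npz`); random (He) initialisation is the default and the only mode used
in tests. No class re-weighting is applied by default despite the ~1:4
disorder/order imbalance; a `pos_weight` option exists.

The network is implemented directly in numpy (float32) with hand-written
backpropagation; convolutions run as nine shifted GEMM accumulations. A
`small` configuration divides backbone channel widths by 8 for desk-scale
work; the 35/3675 widths that define the architecture are unchanged.

## Evaluation

Per-residue confusion counts (positive = disordered) pooled over all
proteins give Sens = TP/(TP+FN), Spec = TN/(TN+FP), BACC = (Sens+Spec)/2
and MCC. Conventions: an empty marginal in the MCC denominator gives
MCC = 0; Sens/Spec undefined by the truth labels are reported as NaN with
a warning. Cross-validation splits at the protein level with a seeded
permutation dealt round-robin, trains on k−1 folds and pools metrics over
held-out residues (per-fold reports are also emitted).

## Synthetic data

The generator emulates curated disorder corpora: proteins are alternating
ordered/disordered blocks; disordered blocks draw residues from a
composition with P, E, S, Q, K, G up-weighted ×3 over uniform, ordered
blocks with W, C, F, I, Y, V, L up-weighted ×3; disordered block lengths
are geometric with mean 30 and ordered blocks with mean 30·(1−f)/f so the
expected disordered fraction is `f = 0.2`, the rough disorder rate of
curated corpora. Fabricated PSSMs carry, per residue, the integer-rounded
log-odds of the generating state's composition against a uniform
background plus Gaussian noise (σ = 1), written and re-read through the
real PSI-BLAST ASCII writer/parser. Two documented configurations exist:
`small` (60 proteins, lengths 120–200) and `standard` (400 proteins,
lengths 100–600).

What the generator does **not** emulate: evolutionary correlation between
sequence positions, real profile structure from homology search,
annotation ambiguity, or the long-tailed length distribution of real
disordered regions. Passing the planted-recovery test therefore shows the
pipeline is correctly wired and can learn a compositional disorder signal;
it does not certify accuracy on real proteins, which additionally depends
on genuine PSI-BLAST profiles and curated training data.

## The planted-recovery experiment

The desk-scale end-to-end check (also what `scripts/acceptance.py`
recomputes): generate the `small` corpus, hold out 25% of proteins, build
k-mer tables on the training split, featurize with `N = 33`, z-score the
features on training residues (raw rows live on very different scales;
standardisation conditions the SGD), train the `small` network for up to 4
epochs at learning rate 0.01, and report pooled held-out metrics. Four
epochs suffice because the planted signal is strong — the loss drops to a
plateau within the first epoch — and keep the experiment to a few minutes
on one core. Typical results: BACC ≈ 0.92, MCC ≈ 0.82.

## Numerical and design notes

* All randomness flows through `numpy.random.default_rng` with explicit
  integer seeds; corpora, fold splits, package divisions, weight
  initialisation and dropout are each deterministic functions of their
  seed.
* Rips filtration values use exact pairwise distances; no grid
  discretisation of the scale parameter.
* The k-mer index is the mixed-radix expansion over the canonical residue
  order A,R,N,D,C,Q,E,G,H,I,L,K,M,F,P,S,T,W,Y,V ("AA"→1, "VV"→400,
  "AAA"→1, "VVV"→8000); PSSM columns and the embedding angle use the same
  order.
* Residue indexing is 1-based in every output file; internal arrays are
  0-based.
* Degenerate inputs: single-point clouds get one bar capped at 1; an
  all-equal k-mer probability table scales to all ones; empty corpora and
  empty confusion tables are errors, not silent zeros.

## Known limitations

* Dimension ≥ 2 homology falls back to a slow generic reduction.
* The full-width network (≈48M parameters) trains impractically slowly on
  one CPU core; the `small` configuration is the supported desk scale.
* The three propensity scales are stand-ins, not the published GlobPlot
  tables (see above); results on real data should substitute measured
  tables via the JSON config.
* Window sweeps below `N = 21` compute the topological-entropy row at the
  minimum calibrated window rather than `N` itself.
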