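# Methods

## Model

The predictor is a four-layer convolutional network over a one-hot encoded
500-bp window (4 channels, A/C/G/T; ambiguous bases are all-zero rows so the
input stays binary). The output is the seven-way accessibility category
O ∈ {1,…,7} over (iPSC, LCL, iPSC-CM): 1 = iPSC-CM alone, 2 = LCL alone,
3 = iPSC-CM∧LCL, 4 = iPSC alone, 5 = iPSC∧iPSC-CM, 6 = iPSC∧LCL, 7 = all
three. A locus open in no cell type is outside the label universe.

**Frozen PWM layer.** Each TF's position weight matrix is converted to
log2-odds weights, `log2((p_wb + ε)/(bg_b + ε))` with pseudocount ε = 1e-3
and a configurable background (default uniform 0.25; human-like backgrounds
can be supplied). Filters are zero-padded to the bank's maximum width; zero
columns contribute nothing to any dot product. Strand handling defaults to
`rc_max`: each TF is scored with its forward filter and its reverse
complement and the positionwise maximum is kept, since accessibility is
strand-symmetric. Forward filters are padded on the right and
reverse-complement filters on the left — with that convention the valid scan
offsets map onto each other under reverse-complementing the sequence
(i ↔ L − Wmax − i), so the per-TF maximum over positions is exactly
strand-invariant even for banks of mixed filter widths. A `forward_only`
policy is retained for oracle tests. Only valid (no sequence padding)
convolution is used, so the scan has 500 − Wmax + 1 offsets.

**Trainable head.** frozen conv → ReLU → non-overlapping max-pool (width 8,
trailing remainder positions dropped) → learnable conv (64 filters, width 8)
→ ReLU → global max-pool → dense (128) → ReLU → 7 sigmoid units. Layer
sizes are configuration with these defaults; the skeleton (fixed conv →
learnable conv → dense → output) is fixed. The seven sigmoid units are
trained with per-unit cross-entropy against the one-hot category and
renormalized at prediction time; a softmax head is available
(`output_head="softmax"`) since a sigmoid over a categorical variable admits
both readings. Per-cell-type open probability marginalizes the category
scores: p_t = Σ_{O ∋ t} s_O / Σ_O s_O.

**Training.** ADADELTA with the original defaults (ρ = 0.95, ε = 1e-6,
lr = 1.0), batch size 128, 12 epochs by default. Forward, backward and the
optimizer are plain numpy; all randomness (initialization, shuffling,
splits) flows from explicit seeds, so identical seeds give identical final
losses and byte-identical simulation outputs. Because the first layer never
changes, its pooled activations are precomputed once per dataset; a SHA-256
checksum of the filter bank is verified before and after training. AUCs are
computed per cell type from p_t against the binary open flag
(rank-sum/Mann–Whitney formulation via scikit-learn); cross-cell-type
transfer is summarized by scoring cell type s's marginal probability against
cell type t's labels, which probes the same cell-type-specificity claim as
training separate per-cell-type models without leaving the seven-way
architecture.

## Attribution

DeepLIFT contributions are propagated from a target output (a category's
sigmoid score, or the summed score of the categories containing a cell
type) down to the post-ReLU activations of the frozen layer, giving a TF ×
scan-position score matrix per locus. Rules:

* linear layers — multipliers through the transposed weights;
* ReLU and sigmoid — the Rescale rule m = Δout/Δin, with m = 0 when
  Δin = 0 (Δout is then 0 too); for these activations m is bounded, so no
  numerical guard is needed;
* max-pooling (both pooling layers) — the window's output delta is
  distributed over the input deltas proportionally to Δx_i², i.e.
  m_i = m_out · Δy · Δx_i / Σ_j Δx_j². This preserves summation-to-delta
  *exactly* at every layer (a winner-takes-all rule does not when the argmax
  differs between input and reference), and the tests verify completeness to
  ~1e-14 relative.

The default reference input is a window of background base frequencies
(0.25 per channel) — "no sequence information"; all-zeros and
shuffled-sequence references are selectable. The key TF of a locus is the
argmax over TFs of the summed positive contributions across positions
(max-over-positions available behind a flag); exact ties break
lexicographically by tf_id, and a none-sentinel is returned when no TF
aggregates above zero. Category-level summaries count, among loci whose
predicted category equals the true category, the fraction explained by each
key TF.

Saturation mutagenesis computes Δpred = f(window with position p set to
base b) − f(window) for all 1,500 single-base substitutions, batched; the
entry at the window's own base is exactly zero by construction, and every
entry equals an independent single-mutation forward pass.

## caQTL effects

Candidate loci carry posteriors πl (locus is a caQTL) and πs (SNP is causal
given the locus is); selection keeps πl > 0.99 AND πs > 0.99 with strict
inequalities. These posteriors are consumed from an input table — the
upstream Bayesian hierarchical model that produces them is a separate tool
and is not reimplemented. For a selected SNP, every phased haplotype of the
panel gets a window sequence with *all* phased in-window SNVs substituted
(restriction to the focal SNP alone is a flag; indels and multiallelic
records are skipped with a warning, since window length must stay 500).
The predicted effect is median(p_t over alt-allele haplotypes) −
median(p_t over ref-allele haplotypes) per cell type — exactly antisymmetric
under allele swap. Observed allelic imbalance (alt-allele read fraction q)
is compared to the predicted effect by Pearson correlation after centering
(q − 0.5); raw and logit transforms, and a Spearman variant, are available.

## Synthetic benchmark

The generator emulates the study design at desk scale and is itself
first-class, tested code.

* **PWMs** — per cell type, `motifs_per_celltype` (default 2) random
  sparse-consensus PWMs of width 8–12, plus `n_shared_motifs` (default 1)
  shared motifs; every column puts `planting_strength` (default 0.9) on a
  random consensus base. Strength 0.25 is the no-information limit; column
  information content is monotone in strength.
* **Windows** — i.i.d. background with 41% GC (human-like). A locus of
  category O carries one instance of every motif of every open cell type,
  plus the shared motifs, each *sampled from the PWM* (not hard consensus),
  planted at a uniform random position on a random strand without overlap.
  Plants are restricted to the region a valid convolution with the widest
  filter can see, so no planted site is edge-invisible to the scanner.
  Labels follow the planting deterministically. Default scale is 300 loci
  per category; the full-scale runs use 2,285 per category (~14,000
  training / 2,000 held-out windows), which trains in well under a minute
  of CPU.
* **caQTL panels** — for each of `n_caqtl` (default 200) causal loci, a
  planted motif instance near the window center and a focal SNP at a random
  motif column whose alternate allele changes the site's PWM log2-odds by
  d; the expected alternate-allele read fraction is
  p_eff = clip(0.5 − effect_size · d/d_max, 0.05, 0.95) (effect_size 0.35,
  read depth 100), so motif-disrupting alleles reduce accessibility on the
  alt haplotype and motif-restoring alleles increase it. Because planted
  instances are sampled from the PWM, d takes positive, negative and zero
  values; the planted direction is undefined when d = 0. Decoy loci
  (default 200) place the SNP in background sequence with πs < 0.5.
  A phased diploid panel (default 60 individuals) is drawn with focal
  allele frequency ~ U(0.1, 0.9), both alleles forced present, plus two
  background SNVs per window; observed counts are Binomial(depth, p_eff).
  The Monte-Carlo generative correlation (mean Pearson r between planted
  effects and freshly sampled imbalance fractions, 10,000 draws) is the
  reference the pipeline correlation is compared against.

What the generator does **not** model: repeat structure, dinucleotide
composition, chromatin-fragmentation or Tn5 bias, LD beyond the focal
window, and overdispersion of allelic counts. Passing tests therefore
demonstrate that the mechanism works when its assumptions hold, not that
the printed accuracies transfer to real ATAC-seq data.

## V_n (inter-individual variability)

For a phenotype matrix of N individuals × L loci,

    V_n = N / (L (N − 1)) · Σ_l (χ_nl − χ̄_l)² / χ̄_l²

reported as log2(V_n) (V_n = 0 → −inf). Loci with zero mean are dropped
(and counted) before L is determined; the statistic is invariant to global
rescaling, and under multiplicative Gaussian noise with coefficient of
variation σ its mean approaches σ². A two-sample Mann–Whitney rank test is
provided for comparing V_n vectors between groups.

## Numerical and design notes

* The frozen-layer scan runs in float64; conv-vs-oracle agreement is tested
  at 1e-6 absolute.
* Duplicate tf_ids across sources are disambiguated by suffixing the source.
* PWM parsing (MEME minimal, JASPAR/pfm, TRANSFAC-like) is delegated to
  Bio.motifs with added validation: declared vs parsed motif widths are
  compared (the minimal parser otherwise truncates silently at a malformed
  row), count matrices are normalized as (c + pseudocount)/Σ(c + pseudocount),
  and zero-sum rows are rejected. Matrices of width < 4 are accepted on
  input; the width-≥4 floor applies to generated motifs.
* Coordinates are 0-based half-open throughout; window center is
  floor((start+end)/2); windows overhanging chromosome ends are errors at
  extraction and dropped (with a logged count) during dataset assembly.
* The held-out split is stratified by category (scikit-learn) under a fixed
  seed; categories with fewer than 2 loci are rejected with advice.
* "Open in cell type t" for a union locus means ≥ 1 bp overlap with a merged
  peak of t (a minimum-overlap fraction is configurable); peak merging
  discards calls below 15× fold enrichment and unions overlapping or
  book-ended intervals, idempotently.

## Known limitations

* Predicted caQTL effect *magnitudes* are noisy: within groups of equal
  generative disruption the spread of the model's allele-difference equals
  its mean, which caps the predicted-vs-observed imbalance correlation near
  0.3–0.5 even when the generative signal is almost noise-free. Direction
  (sign) recovery is ≥ 95% on clearly disrupting alleles.
* Cross-cell-type transfer is evaluated with the single multi-task model's
  marginal scores, not with independently retrained per-cell-type models.
* The model head sizes (pool widths, filter counts, dense units, dropout
  absent) are package defaults, not fitted to any external dataset.
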