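# Methods

## Problem and model

Given a set of drugs and a set of microbes with a sparse list of known
associations, the task is to rank all unobserved drug–microbe pairs by their
likelihood of being true associations. The method works entirely from the
binary adjacency matrix `S ∈ {0,1}^{Nr×Nm}` (drugs on rows, microbes on
columns), optionally augmented by externally computed drug structural and
microbe functional similarity matrices.

Two complementary feature families are computed per entity type:

**Inter-node diffusion features (RWR).** The Gaussian interaction-profile
(GIP) kernel similarity between association profiles,

    G(i,j) = exp(−μ ‖p_i − p_j‖²),   μ = 1 / ( (1/N) Σ_i ‖p_i‖² ),

defines a weighted network per entity type (profiles `p_i` are rows of `S`
for drugs, columns for microbes). The similarity is column-normalized into a
transition matrix `M` and a restart random walk

    q_i ← λ M q_i + (1−λ) e_i,   q_i⁰ = e_i

is iterated to convergence for every node, giving the diffusion profile
matrices `DR` (Nr×Nr) and `MR` (Nm×Nm) whose row i is the stationary
profile of node i.

**Node attribute features (SAE + attention).** The cosine similarity of the
same profiles, plus the external structural/functional similarity (or the
cosine matrix again as a documented fallback when no external matrix is
supplied), are each fed to an independent stacked autoencoder: encoders
d₀→128→64→32 with ReLU, mirrored decoders with a logistic output layer
matching the [0,1] input range, greedy layer-wise pretraining followed by
end-to-end fine-tuning of the reconstruction loss `‖X − X′‖²` with
full-batch Adam. A multi-head scaled-dot-product self-attention block —
tokens are the node rows of the reconstruction — is applied to the final
decoder output with a residual connection, so the returned attribute
features `SAEr1, SAEr2, SAEm1, SAEm2` keep the shape of their inputs.

**Fusion and scoring.** The features are concatenated with adjacency copies,

    IFMr = [DR | S | SAEr1 | S | SAEr2 | S]
    IFMm = [Sᵀ | MR | Sᵀ | SAEm1 | Sᵀ | SAEm2]

(both Nr or Nm × 3(Nr+Nm)), and every pair is scored by
`Score = sigmoid(IFMr · IFMmᵀ)`. The adjacency copies make the two block
layouts align, so the logit decomposes into six interpretable block products
(`DR·S + S·MRᵀ + SAEr1·S + S·SAEm1ᵀ + SAEr2·S + S·SAEm2ᵀ`), exposed as a
diagnostic.

## Parameters

| parameter | default | meaning |
|---|---|---|
| λ (`restart_lambda`) | 0.1 | weight of the walk term in the literal update; 1−λ is the restart mass |
| RWR tol / max_iter | 1e-6 / 1000 | L1 convergence threshold; the walk contracts by λ per step so ~7 iterations suffice at λ=0.1 |
| hidden sizes (n₁) | 128, 64, 32 | encoder widths of the 3 stacked autoencoders (n₂=3) |
| heads (h) | 4 | attention heads; the model dimension is padded to the next multiple when h does not divide it |
| learning rate | 0.01 | Adam step size, pretraining and fine-tuning |
| epochs / pretrain epochs | 200 / 50 | full-batch fine-tuning; greedy pretraining per autoencoder |
| k / n_repeats | 5 / 1 | cross-validation folds and repeats |

The λ parameterization deserves a note: in the update as implemented, λ
multiplies the walk term, so λ=0.1 means 90 % restart mass and profiles
close to the identity plus a diffusion correction. A `swap_lambda` flag
selects the conventional reading (λ as restart weight); both fixed points
are related by swapping λ ↔ 1−λ.

Epoch counts, batch size (the full matrix) and Adam moments (0.9/0.999) are
package choices made for stable convergence at these matrix sizes; all are
exposed in `SAEConfig`.

## Evaluation protocol

Cross-validation folds the **known positive pairs**: the positives are
randomly partitioned into k near-equal subsets; each subset in turn is
zeroed in `S`, the entire pipeline — including the GIP/cosine similarities —
is recomputed from the masked matrix (`mask_mode="per_fold_similarity"`,
the default), and the held-out positives are ranked against all pairs
unknown in the complete dataset. Computing similarities from the full
matrix (`global_similarity`) is supported for comparison but leaks held-out
associations into the features. AUC is rank-based (Mann–Whitney, midranks
for ties) and computed on raw logits: with thousands of nonnegative feature
columns the logistic saturates to 1.0 at float precision, and the logistic
is strictly monotone, so logits give the identical ordering without
saturation ties. A `sampled_1to1` negative policy (one sampled negative per
test positive) is available for speed.

The attention ablation runs two cross-validations on identical folds and
seeds differing only in `use_attention`, and reports paired per-fold AUC
deltas.

## Synthetic data

The generator plants co-cluster structure: drugs and microbes are assigned
to `n_blocks` balanced blocks; a pair is associated with probability
`within_block_prob` (default 0.3) inside a co-cluster and
`background_prob` (default 0.01) otherwise, with optional independent label
flips. Default sizes are 200 drugs × 60 microbes with 4 blocks, small
enough for desk-scale runs while leaving ~1000 positives. Synthetic
stand-ins for the external similarity matrices mix the exact block
indicator with symmetric uniform noise at a chosen reliability.

A block model was chosen over low-rank Gaussian structure because every
feature in the pipeline is association-profile-based: co-clusters produce
exactly the profile similarity the method exploits, with a controllable
signal strength. What passing tests on this generator demonstrate is that
the pipeline recovers planted profile structure well above a
degree-product popularity baseline and far above chance; they do not
demonstrate performance on real pharmacological data, whose degree
distributions are heavy-tailed, whose similarity matrices encode chemistry
and genomics rather than block membership, and whose "negatives" are
unverified unknowns.

## Numerical choices and degenerate inputs

- Zero-profile cosine similarity is defined as 0, including the diagonal:
  an entity with no associations carries no direction, and this avoids NaN
  propagation. The GIP bandwidth is undefined on an all-zero matrix and
  raises instead of silently returning identity.
- RWR profiles are computed for all nodes jointly as one matrix iteration
  (identical to per-node iteration by linearity) and validated against the
  dense closed-form solve `(1−λ)(I−λM)⁻¹`.
- The SAE is plain numpy with hand-written gradients (dense layers,
  softmax attention, Adam); a central finite-difference check over every
  parameter tensor guards the backward pass.
- All randomness (weight init, fold assignment, generators) flows from
  explicit integer seeds; two runs with the same config and seed are
  bitwise identical.
- The four autoencoders are independent (no weight sharing), each seeded
  by a child seed of the run seed.

## Known limitations

- The reconstruction-plus-attention features are unsupervised; no label
  signal enters training, so the score is a fixed transform of the masked
  adjacency — there is no trained classifier head to calibrate score
  magnitudes.
- Hidden layers wider than the input (e.g. 128 for a 60-node network) are
  over-complete; training still converges but the warning is surfaced.
- Dense linear algebra throughout: fine to a few thousand nodes, not
  designed for much larger networks.
- External structural/functional similarities are inputs, not computed
  here; with the cosine fallback the two attribute streams per entity are
  trained on the same matrix (different initializations), which weakens
  the benefit of the second stream.
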