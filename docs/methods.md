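# Methods

This note records the modelling choices behind `latentmol`, their
defaults, and what the test battery does and does not demonstrate.

## Graph representation

A molecule is encoded as a one-hot node-type matrix `V (dn × dv)` and a
one-hot edge-type tensor `E (dn × dn × de)`.  Heavy atoms only;
hydrogens are implicit.  The element vocabulary is derived from the
curated dataset, ordered by the fixed whitelist order
(C, N, O, F, P, S, Cl, Se, Br, I), with one reserved padding/virtual
type at the last index; the bond channels are {single, double, triple}
plus a reserved no-bond channel, also last.  Aromatic rings are
**kekulized** before encoding so no aromatic bond channel is needed
(`de = 4`); decoding re-aromatizes through RDKit sanitization, so round
trips compare equal on canonical SMILES.  Atom order inside the tensor
follows RDKit's canonical atom ranking, which makes the encoding a
deterministic function of the canonical SMILES.  `dn` is the maximum
heavy-atom count of the curated set and is frozen into the model
configuration.

Stereochemistry, 3-D conformers, formal charges and tautomers are not
represented; charged input structures are neutralized during curation
where chemically possible and rejected otherwise.

## Curation of screening tables

Rules applied to a raw (NSC, SMILES, cell line, GI50) table, in order:
cell-line selection; parse check; ion pairs reduced to the largest
connected component (heavy-atom count, ties by lexicographic canonical
SMILES); element whitelist; positively charged oxygen rejected (checked
on the retained component, after splitting); charge neutralization;
replicate experiments of the same source structure mean-averaged; and
canonical-SMILES collisions between distinct source structures resolved
by keeping the minimum (most potent) per-structure average.  The
minimum is taken over per-structure *averages*, not raw replicates —
the two readings are both defensible; this one never lets a single
noisy replicate of a well-replicated structure win.  Provenance
counters satisfy `rows_in = rows_kept + Σ rejections` exactly.

## Flows

Both factors of `P(G) = P(E)·P(V|E)` are stacks of affine coupling
layers that split the input along the *channel* dimension
(`split = de//2` for bonds, `dv//2` for atoms) and use a sigmoid scale,
which is bounded in (0, 1) and therefore numerically stable under deep
stacking.  Successive layers alternate which slab passes through
unchanged, so every channel is transformed.  The bond nets are a
3×3 same-padded convolution (width 16 at desk scale, 128 at full
scale) followed by a zero-initialized 1×1 projection; the atom nets are
an embedding + 2 rounds of relational message passing (one learned map
per real bond channel, sum aggregation over neighbours) + a tanh MLP
with a zero-initialized output.  Zero initialization makes a fresh
coupling exactly `y₂ = 0.5·x₂` with log-det `m·ln ½` — an analytic
anchor the tests assert exactly — and keeps the initial model a
well-conditioned affine map.

Dequantization adds uniform noise on `[0, 0.6)`: any bound below 1
preserves argmax decodability; 0.6 leaves a 0.4 margin while filling a
reasonable fraction of the unit cell.  The priors on both latents are
standard normals; the training loss is the exact NLL in nats.  The atom
flow is conditioned on the *discrete* bond tensor in both training and
decoding, which keeps the conditioning identical across the two phases.
Training uses Adam (lr 1e-3) with global gradient-norm clipping at 5,
minibatch 10, on a bundled NumPy reverse-mode autodiff engine (the
environment's scientific stack is NumPy-based); its gradients are
finite-difference checked in the test suite.

Decoding inverts the bond flow, symmetrizes the continuous edge tensor
by channel-wise averaging of `E[i,j,:]` and `E[j,i,:]` (the flow acts
on a generic tensor and cannot guarantee symmetry), takes per-pair
argmax, inverts the atom flow conditioned on the discrete bonds, takes
per-row argmax, and finally repairs chemistry: while an atom exceeds
its standard maximum valence (C 4, N 3, O 2, F 1, P 5, S 6, Cl 1, Se 6,
Br 1, I 1) its highest-order bond is demoted one step (ties broken by
lowest partner index), and of a disconnected result only the largest
component is kept (ties by lowest atom index — cheaper than the
canonical-SMILES tie-break used in curation and equally deterministic).
The repair is total and idempotent; a graph that still fails RDKit
sanitization afterwards (not observed in testing) degrades to its first
atom.

## GI50 head

The head consumes the flattened latent, H block first then Z, row-major
(`fvc`).  Its architecture is shaped by a sample-complexity argument:
the latent has `dn²·de + dn·dv` coordinates (423 at desk scale), while
curated screening sets are not much larger, so *any* dense estimator —
we verified this with closed-form ridge and lasso — carries
an irreducible noise-fitting excess of order `σ²·p/n`.  The latent
blocks, however, have node/pair structure, so the head:

1. standardizes all input columns (statistics stored at fit time);
2. prepends channel-wise pooled means of the H block (over node pairs)
   and the Z block (over nodes) — `dv + de` exchangeable summaries;
3. runs a tanh hidden stack (default 64/32) on the pooled summaries;
4. adds a linear skip over the full augmented vector whose
   raw-coordinate block carries a decoupled L2 penalty (decay applied
   after each Adam step; folding it into Adam's normalized gradient
   neutralizes it) selected from {0, 3, 30, 100} on an internal
   validation split (1/6 of the data, candidates trained at a third of
   the epoch budget, winner refit on everything).

When the signal is a function of composition and bond statistics — the
synthetic fixture's regime, and plausibly much of a real GI50 signal —
the selector suppresses the raw block and the head attains near the
OLS-oracle noise floor; when the signal is a dense, non-exchangeable
function of the latent, the selector turns the penalty off and the
skip recovers the dense linear map (correlation > 0.99 with a random
ground-truth map at n = 1000 in the tests).  Targets are standardized
for training and de-standardized at prediction; the zero-initialized
output layer makes the untrained head predict the training mean.
Training latents are noise-free encodings, so each molecule has a
deterministic target representation.

## Generation

Seeds are either the k most potent training molecules (default k = 140,
ties by lexicographic SMILES) or a user-supplied newline-delimited
SMILES list validated through the same curation filters.  Each seed is
encoded noise-free and descended by `z ← z − η·∇z p(z)` for each step
size η in {0.1, 0.5, 1.0, 2.0} (50 steps by default) — the magnitudes
are package choices, exposed in the configuration, spanning local edits
to long jumps.  The flow and head stay frozen; the gradient is taken
with respect to the flattened latent and reshaped.

Every iterate is decoded and the *decoded molecule* (its noise-free
re-encoding) is what the reported predicted GI50 scores; scoring the
free latent point instead lets the head's linear path extrapolate
without bound once the iterate leaves the data manifold, which we
observed directly.  Decode failures are recorded in the trajectory with
the latent-point prediction and never truncate a run.  Candidate
reports deduplicate by canonical SMILES (best prediction kept), exclude
the seeds themselves, optionally filter by a normalized-SAS ceiling and
a similarity floor, and sort ascending by predicted GI50.  Predicted
score descent along a trajectory is guaranteed (and asserted) only for
the analytic quadratic head; for a learned head it is logged, not
asserted.

Scoring metrics: Tanimoto similarity of Morgan fingerprints (radius 2,
2048 bits, configurable — the fingerprint family is standard, the
parameters are package defaults) and the fragment-contribution /
complexity-penalty synthetic-accessibility score mapped from its native
[1, 10] to [0, 1] by `(raw − 1)/9`.

## Synthetic data generator

Fixture tables emulate a single-cell-line GI50 screen: seeded random
assembly from a curated scaffold set (alkanes, alcohols, amines,
ethers, simple rings) decorated with single-bonded substituents, capped
at 9 heavy atoms by default, with

```
GI50 = −0.5·(heavy atoms) − 1.0·(rings) + ε,   ε ~ N(0, 0.5²).
```

The linear map over cheap descriptors makes the head's attainable error
floor *exactly computable* (OLS on the true descriptors), and its
negative coefficients give the latent optimizer a meaningful descent
direction at toy scale.  The dirty-row mode appends one hand-audited
specimen of every curation hazard (ion pair, charged oxygen,
off-whitelist element, unparseable row, replicate pair averaging to
−5.5, collision pair resolving to −7.0) plus two off-panel cell-line
rows, together with a ledger of the exact expected outcomes.

What the fixture does *not* emulate: the real NCI-60 chemical space
(≈130-atom molecules, charged species, complex ring systems), its GI50
distribution, or any structure–activity relationship beyond size and
ring count.  Passing tests therefore demonstrate the correctness of the
machinery — exact invertibility, likelihoods, curation arithmetic,
optimizer algebra, head recovery under a known map — not biological
validity of generated candidates on real screens.

## Problem sizes and numerics

The test and acceptance runs use dn = 9, 2 coupling layers per flow,
width 16, 30 epochs on 50 molecules for the flow, and n = 500 with a
fresh 500-molecule held-out draw for the head study; full-scale
defaults (10 layers, width 128) are provided in
`FlowConfig.full_scale` and the architecture is size-independent.
Held-out error for the head study is measured on a fresh generator draw
rather than a small split because a 100-row test set estimates MSE with
a standard error comparable to the tolerance of interest.  Coupling
inverses raise a structured underflow error if a sigmoid scale reaches
zero numerically (≈ |s| > 700); inversion error is otherwise at machine
precision (< 1e-14 observed, 1e-5 asserted).  All randomness flows
through explicit NumPy generators; every entry point takes a seed.

## Known limitations

- Latent gradient descent quickly leaves the data manifold at large
  step counts/sizes: similarity to the seed decays and SAS rises, the
  same drift the candidate filters exist to manage.
- The head's pooled summaries discard positional information by
  construction; a signal tied to specific latent coordinates is only
  reachable through the penalized dense path, at dense-estimator sample
  cost.
- Kekulization means an aromatic system may decode to a different but
  chemically equivalent Kekulé assignment before re-aromatization.
- Training is CPU-bound NumPy; full-scale (46k molecules, dn ≈ 130)
  training is architecturally supported but not practical in this
  implementation without a GPU tensor backend.
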