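# Methods

This note documents the models, the synthetic data, the numerical choices
and the limitations of `molgenrl`. It states no result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Molecular representations

Two graph views are used. The **property encoder** sees a directed-bond
graph: atoms carry 133-d feature vectors laid out as one-hot blocks for
atomic number (1–100), total degree (0–5), formal charge (−2…+2), chiral
tag (0–3), H count (0–4) and hybridization (SP…SP3D2) — each block with a
trailing slot that absorbs out-of-range values — plus an aromaticity flag
and the atomic mass × 0.01. Bonds carry 14-d vectors: bond-present flag,
single/double/triple one-hot, aromatic, conjugated, in-ring, and a 7-slot
stereo code. Each chemical bond contributes two directed bonds whose input
is the 147-d concatenation of the source atom's features with the bond
features. Where the printed block sizes are internally inconsistent (the
degree block has 7 slots for 6 common values), the index ranges and the
total dimension of 133 are treated as authoritative.

The **generator** sees a dense state (A, E, F): adjacency, a three-slice
edge tensor (single/double/triple) and node features. Since the edge tensor
has no aromatic slice, molecules are kekulized on conversion; aromaticity is
re-perceived whenever a molecule is scored. Hydrogens are implicit
everywhere and "atom count" means heavy atoms.

## Property model

The encoder follows the directed-MPNN convention: depth-0 bond messages are
a rectified linear transform of the 147-d inputs; at each further depth the
incoming messages of a bond's source atom — excluding the reverse twin, a
convention switchable with `include_reverse` — are summed and transformed
(ReLU + dropout). Atom messages concatenate the raw atom features with the
summed incoming bond messages (so a bondless single atom reduces to a
transform of its zero-augmented features), and the molecule embedding is the
*mean* over atom messages. A feed-forward network of constant width
regresses the score. All weights use Xavier initialization.

Training: random 80/10/10 split by seed, Adam, two warmup epochs with the
learning rate rising linearly 1e−4 → 1e−3, then exponential decay reaching
1e−4 at the last epoch; the returned model is the checkpoint with the best
validation RMSE. The default batch size is 50; the desk-scale tests use
batch 5 because with a few hundred molecules 100 epochs at batch 50 give
only a few hundred optimizer steps, an order of magnitude fewer than the
same schedule on datasets of realistic size.

### Adaptive robust loss

The loss f(x, α, c) and its negative log-likelihood are given in the
README. Implementation specifics:

* α is parameterized as `1e−3 + (2 − 1e−3)·sigmoid(latent)` and c as
  `softplus(latent) + 1e−6`, so both are trained unconstrained; α is
  restricted to (0, 2] because Z(α) diverges for α < 0 and the NLL
  formulation needs a finite partition function.
* The singular points α→0 and α→2 use their analytic limits
  (log(½(x/c)²+1) and ½(x/c)²) inside a 1e−4 switch-over window; the
  α-derivative inside the window falls back to central differences.
* Z(α) is computed by adaptive quadrature and cached as log Z on a
  256-point α grid with linear interpolation; the interpolant's slope
  serves as d log Z/dα during training. Endpoints match the closed forms
  √(2π) and π√2; normalization of the implied density is verified to 1e−3
  over an (α, c) grid in the tests.

### Hyperparameter search

Ten-fold cross-validation on the train+validation portion (test held out
first), model score = mean fold RMSE, minimized by a Gaussian-process
surrogate (Matern ν=2.5) with an expected-improvement acquisition over the
discrete candidate grid after a small random initial design. Expected
improvement is a choice; the method contract only requires sequential
model-based minimization.

## Generation environment

Actions are (first atom, second atom, bond type, stop): `first` indexes
current atoms, `second` either closes a ring (existing atom) or appends a
new atom from an ordered element menu (default C, N, O, S, F, Cl, Br, I,
P), `edge` selects single/double/triple. Chemically invalid outcomes
(valence violations, duplicate bonds) leave the state unchanged with zero
bonus (an optional negative penalty is off by default); valid growth steps
earn +0.05 (configurable — the magnitude is an implementation policy).
Episodes end on the stop action, on reaching the heavy-atom cap (25 or 15
in the reference experiments) or on a `max_steps` safeguard (default
10× the cap); cap- and safeguard-terminated episodes still receive the
final reward. Disconnected fragments are impossible by construction since
the first atom is always part of the current molecule.

Final reward: Σ w_k·(predicted property k) + QED + 2·SA_norm + 1[no steric
strain] + 1[passes functional-group filters] + optional adversarial term.
SA_norm = (10 − SA)/9 maps the raw synthetic-accessibility scale (1 easy …
10 hard) to [0, 1] with higher = easier, which is what a ">0.8" filter
threshold presupposes. The strain check embeds a conformer (seeded ETKDG),
relaxes it with MMFF94 and passes iff the isolated angle-bend energy is
below 0.82 kcal/mol per heavy atom (a configurable heuristic; molecules
that cannot be embedded pass with a warning by default). The
functional-group catalog is a package-shipped, editable SMARTS file of
reactive/promiscuous groups; it is a documented stand-in, not a copy of any
proprietary catalog.

## Policy network and training

Node embeddings: L layers (default 3) of edge-sliced graph convolution
H ← mean_i ReLU(D̃_i^{−1/2}(E_i+I)D̃_i^{−1/2} H W_i), computed over the
current atoms plus c edgeless candidate-type nodes whose features are
one-hot element identity padded to atom-feature width. Four 2-layer MLP
heads produce the factorized action distribution (first | existing atoms,
masked; second | all n+c rows with the first atom's embedding broadcast
row-wise; edge | 3 from the concatenated pair embedding; stop | 2 from the
mean embedding), sampled ancestrally; `second == first` draws are rejected
and resampled up to 10 times, after which the environment treats the action
as invalid. The composite log-probability is exactly the sum of the four
head terms. The value head is an MLP on the mean embedding and shares the
convolution trunk; the discriminator is an independent GCN + MLP with a
terminal sigmoid.

PPO uses the clipped surrogate (ε = 0.2) on advantages from generalized
advantage estimation (γ = 0.99, λ = 0.95 defaults; all configurable),
advantage normalization per batch, a 0.5-weighted value regression to
empirical returns, and an optional expert-imitation term whose weight can
decay linearly. The adversarial reward added to final molecules is
−log(1 − D(x)), the standard non-saturating generator signal, with D
clamped to [1e−6, 1−1e−6]; the discriminator trains one cross-entropy step
per iteration on expert-vs-generated batches. Expert pairs are sampled by
growing a random connected induced subgraph of an expert molecule and
choosing a uniform frontier bond as the action; applying the action always
yields a subgraph of the parent (tested by substructure match). A
divergence guard aborts if the mean |advantage| exceeds a configured bound.

For the *episodic, terminal-reward* smoke experiments the tests pass γ = 1:
with a discount, stopping earlier is rewarded purely for being earlier,
which drives the policy toward emitting minimal molecules.

## Synthetic fixtures

`toy_oracle` is a deterministic linear function of five interpretable
descriptors — ring count, aromatic-ring count, heteroatom fraction,
heavy-atom count, and carbon fraction as a hydrophobicity-like term —
clamped to a pKi-like [2, 10]; defaults give a spread of roughly 4.8–8.5
(SD ≈ 0.8) over the fixture pool, comparable to curated binding data.
Datasets decorate a 42-scaffold pool with small substituents, add Gaussian
label noise and shift a chosen fraction of labels by a constant
(default −3), mimicking censored weak-binder records: one-sided, gross, and
disjoint from the noise. The expert-set generator emits valid decorated
molecules of ≤ 25 heavy atoms.

What passing tests show: the pipeline recovers a known structure–property
mapping from contaminated labels, and the robust loss demonstrably
outperforms L2 under that contamination. What they do not show: performance
on real assay data, whose label noise is not i.i.d., whose chemistry is far
more diverse than the fixture pool, and whose structure–activity landscape
contains cliffs no smooth descriptor oracle reproduces.

## Problem sizes

Desk-scale settings used by the test and acceptance suites, chosen as the
smallest sizes at which each phenomenon is stable: property recovery uses
400 molecules (10% outliers, shift −3), a depth-3/width-64 encoder, batch 5,
100 epochs, 5 seeds; the RL smoke test uses a C/N/O menu, 12-atom cap,
36-step episodes, 16 episodes × 30 iterations × 3 seeds; the validity check
runs 200 untrained episodes at the 25-atom cap. Full-scale settings (25-atom
menu of 9 elements, 128-d embeddings, millions of PPO steps, 1300-d message
vectors) are configuration changes, not code changes.

## Known limitations

* The autodiff core is eager and unbatched across RL steps; PPO cost grows
  linearly with total collected steps. This bounds desk-scale experiment
  sizes but does not affect correctness.
* Stereochemistry is encoded for prediction but the generator neither sets
  nor optimizes stereocenters; 3-D information enters only through the
  steric-strain check.
* The kekulization policy means the generator must discover aromatic rings
  as alternating single/double patterns.
* RDKit's sanitizer accepts some exotic valence states (e.g. hypervalent
  iodine), so "chemically valid" means RDKit-sanitizable, which is the
  standard operational definition in this literature.
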