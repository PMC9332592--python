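# Methods

`securedx` implements a privacy-preserving disease-prediction workflow for
tabular clinical records: a registering patient authenticates with a
substitution-cipher token, their feature table travels to the analysis side
under elliptic-curve hybrid encryption, and the receiver cleans the table,
reduces it with Gaussian-kernel linear discriminant analysis, and classifies
it with a small neural network whose weights are found by an
elephant-herding + genetic-algorithm metaheuristic rather than
backpropagation. This note records the models, the parameter choices, and
the design decisions taken where the design was genuinely open.

## Authentication

The combined text is the concatenation of patient id and hospital id; it is
encrypted with a keyed cyclic-shift substitution cipher (letters mod 26,
case preserved; digits mod 10; other characters unchanged) and the result
is stored as a third login credential. Verification requires username,
password, and the presented token to match; the first failing check is
named in the decision. The shift key defaults to 3 and is configurable —
nothing pins a particular shift, and the cipher is a registration token
scheme, not a confidentiality mechanism. Passwords are stored salted and
SHA-256 hashed; the extended-alphabet map is a bijection for every shift,
so tokens are always invertible by the negated shift.

## LR-ECC encrypted transfer

Messages are embedded as points on a short Weierstrass curve over a prime
field (default: the secp256r1 domain parameters; the toy curve
y² = x³ + 2x + 2 over F₁₇ with base point (5,1) of order 19 ships for
exhaustive oracle testing). Embedding is Koblitz try-and-increment: the
length-prefixed payload is split into blocks of ⌊(bitlen(p) − 16)/8⌋ bytes,
and block integer m maps to the first x = 256·m + j whose cubic is a
quadratic residue; 8 bits absorb the counter and 8 more guarantee x < p.
Each increment fails with probability ≈ 1/2, so the embedding failure
probability is ≈ 2⁻²⁵⁶ and decoding is exact.

Sender and receiver hold key pairs (k, kG). Encryption derives the ECDH
shared point S, the integer secret scalar

    K_se = max(1, round(ln(x_S + 2))),

draws a nonce Rn uniformly from (1, n − 1), and adds the mask
M = (Rn · K_se mod n) · S to every message point; decryption recomputes S,
K_se and M from the receiver's private key and subtracts. The log-derived
scalar is computed from the shared point because that is the only quantity
both parties hold without extra transmission; the +2 offset keeps the
logarithm positive for any affine x ≥ 0 and the floor at 1 keeps the mask a
nontrivial group action. The nonce travels in the clear inside the payload;
recovering M from Rn still requires a private key. The arithmetic is not
constant-time and no indistinguishability property is claimed — this is a
method study, not production cryptography.

## Preprocessing

Cleaning runs dedup → impute → matrix → normalize. Deduplication keeps the
first occurrence of each fully identical row (and precedes imputation so
rows made identical *by* imputation are not silently merged). Imputation
replaces each `'?'` with its column's mean over observed values, computed
once before any replacement; a fully missing column is an error. Min–max
normalization maps each attribute to [0, 1]; a constant column maps to 0.0
(the ratio is undefined and the column is information-free either way).
Held-out data reuse the training bounds and are clipped to [0, 1]. The
label column never participates in imputation statistics or normalization.

## Gaussian-kernel LDA

Fisher's criterion tr(RᵀBR)/tr(RᵀWR) is maximized by the generalized
eigenproblem B r = λ (W + εI) r, with B the class-size-weighted
between-class scatter and W the pooled within-class scatter. The ridge
ε defaults to 10⁻⁶ · tr(W)/P and guards the small-sample-size singularity
of W. The top c − 1 eigenvectors are retained (c = class count);
eigenvector signs are fixed by making the largest-magnitude component
positive so fits are reproducible bit-for-bit.

Kernel mode is the kernel Fisher discriminant: samples are represented by
rows of the centred Gaussian Gram matrix K_ij = exp(−γ‖x_i − x_j‖²)
(centring takes the feature-space scatter about the feature-space mean) and
the same eigenproblem is solved in that L-dimensional space; projection of
new data evaluates the kernel against the training rows, applies the stored
centring statistics, and multiplies by the dual coefficients. A single
kernel width is used for all pairs; γ defaults to the median heuristic
1/(2·median²) of the pairwise training distances. Linear mode (no kernel)
is also exposed and is checked against an explicit W⁻¹B eigendecomposition
oracle in the tests.

## EHGA-DLNN classifier

The network is fully connected with sigmoid units throughout, default
architecture [d, 16, out]: one output unit for binary labels (threshold
0.5), one-per-class with argmax otherwise. A candidate solution is the
flattened weight/bias vector; fitness is the mean squared error between
network outputs and the desired targets over the whole training set.

The population (default 10 clans × 10) evolves per iteration and clan by:

1. **Crossover + mutation** — members are paired; two-point crossover swaps
   the segment [⌊|T|/3⌋, ⌊|T|/3⌋ + ⌊|T|/2⌋) (the upper point capped at
   |T| − 1 so the segment is always valid); offspring genes mutate with
   probability `mutation_rate` (default 0.1) to a fresh uniform draw in
   bounds, redrawn until it differs from its predecessor. Each child
   replaces its parent only if it lowers the loss.
2. **Clan update** — non-matriarch members move by α·g·(T_best − T) with
   scalar g ~ U[0,1] per member and α = 0.5; the matriarch moves to
   β · clan-centre (β = 0.5). Moves are accepted greedily.
3. **Separation** — the clan's worst member is replaced gene-wise by
   T_min + (T_max − T_min)·fr, fr ~ U[0,1] per gene, unconditionally: this
   is the exploration step and greedy acceptance would negate it.

Search bounds default to [−5, 5] per gene and every operator's output is
clipped to them. A global best-ever genome is kept elitistically, so the
best-fitness trace is nonincreasing by construction; training stops when
the best loss reaches `loss_threshold` (default 0, i.e. run all
iterations) or after `max_iterations`. All randomness flows from one
seeded generator, and the fitness-evaluation count is tracked (population
+ per iteration: one evaluation per CM child, per clan-update candidate,
and per separation replacement), which bounds runtime linearly in
population × iterations × training rows. When configured, `sample_count`
must equal the training row count exactly — a mismatch is a configuration
error, not a warning.

Greedy acceptance replaces a literal "multiply the new position by the
best position" selection step, which squares magnitudes and diverges;
similarly the loss is MSE because a sum of raw outputs has no minimizer.
Both readings are documented deviations recorded at the operator level.

## Synthetic data

The generator emulates the *shape* of UCI heart-disease-style tables:
L records × P numeric attributes (default 13), integer labels (default
binary), `'?'` missing markers, comma-separated text. Class k's features
are Gaussian with mean k·s·u along a fixed unit direction u (so adjacent
class means are s apart; s is `class_mean_separation`) and isotropic noise
`noise_sd` (default 1.0). Labels are uniform over classes — the simplest
exchangeable design. Duplicates (a configurable fraction, copied verbatim)
are injected after generation and missing markers after duplication, so
deduplication and imputation are separately exercisable. Identical config
and seed give byte-identical CSV output.

What this does *not* emulate: the real datasets' marginal distributions,
attribute semantics, categorical codings, class imbalance, or structured
(non-random) missingness. Passing tests therefore demonstrate that each
stage implements its contract and that the assembled system learns
learnable structure — not clinical-grade accuracy on real records.

## Problem sizes and numerical choices

The test and acceptance runs use desk-scale problem sizes chosen to
exercise every code path: 100 encryption round trips and 100 key pairs on
secp256r1; the exhaustive 19 × 19 addition table on the toy curve;
150-row, 8-attribute, 5-class Gaussian data for the eigen-residual and
Fisher-criterion checks; the learning-sanity run uses 200 training and 100
held-out rows of 5-attribute, 4σ-separated binary data with a 10 × 10
population for 200 iterations; the end-to-end equivalence run uses an
80-row table with 5% duplicates and 5% missing cells. Scatter matrices are
accepted as symmetric PSD to 10⁻¹⁰; generalized-eigen residuals are
required below 10⁻⁸ relative; linear-mode eigenvalues agree with the dense
oracle to 10⁻⁶ relative. Ties in deduplication resolve to the first
occurrence; degenerate inputs (empty tables, fully missing columns,
single-class labels, off-curve points, identity shared points) raise typed
errors rather than propagating NaNs.

## Known limitations

- The cipher-token scheme authenticates registration state only; it is a
  shared-secret check, not a cryptographic signature.
- LR-ECC's integer secret scalar takes few distinct values (it is a rounded
  logarithm); security rests on the ECDH shared point, and no formal
  security analysis is offered or implied.
- The metaheuristic trainer is derivative-free and population-based: it is
  robust on the low-dimensional reduced features it is designed for, but it
  does not scale to large networks, and its accuracy has run-to-run
  variance across seeds.
- Kernel-mode reduction stores the training rows in the basis (projection
  needs kernel evaluations against them), so the persisted basis grows with
  the training set.
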