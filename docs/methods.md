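# Methods

This note documents the models, parameter choices and numerical decisions
behind `thermomimic`, and what the synthetic fixtures do and do not
emulate.

## Descriptor profiles and the surrogate predictor

A thermodynamic profile assigns every residue i of a protein two
4-vectors of ensemble energetics, {ΔG, ΔH_ap, ΔH_pol, TΔS_conf} in
kcal/mol, one for the native and one for the denatured state. Real
profiles come from a trained sequence-based predictor whose parameters are
not redistributable here; `thermomimic` therefore ships a **windowed-mean
propensity surrogate**: a 20×8 table of per-amino-acid descriptor
propensities, and the descriptor at residue i is the mean of the table
rows over a symmetric window of width `window` centred at i, truncated at
chain ends.

- `window` default 7 (odd, inclusive of both ends, residues 1-based).
  A local-stability profile is inherently a short-range average over the
  chain; seven residues is roughly two helical turns and keeps adjacent
  residues correlated without erasing local features. `window=1`
  degenerates to a per-residue lookup.
- The shipped default table (`data/propensity_default.tsv`) was drawn once
  from Gaussians with per-descriptor locations/scales patterned on the
  magnitudes of local folding energetics (free energies of a few kcal/mol,
  enthalpies around ten); the generation seed is recorded in the file
  header. It is a versioned fixture, not a trained model: any externally
  produced profile can be imported via the profile TSV reader
  (`read_profiles_tsv`), making the surrogate fully replaceable.
- Ambiguous FASTA letters (B, J, O, U, X, Z) are stripped with a logged
  warning by default; a strict `error` policy is available. Proteome FASTA
  files routinely contain X, so hard failure is the wrong default.

The surrogate preserves exactly the properties the downstream algorithms
consume — per-residue 8-descriptor vectors whose local structure follows
the sequence — which is what makes the alignment and fragment machinery
testable end-to-end. It does not reproduce any real protein's energetics.

## Thermodynamic environments

Descriptor vectors are pooled over a training corpus, z-scored per
descriptor (separately per state, since native and denatured energetics
live on different scales), and clustered with k-means (k = 8 per state,
k-means++ initialization, up to 100 restarts, relative tolerance 1e-6,
fixed seed). A residue's environment is the index of the nearest centroid
in standardized Euclidean space; ties break to the lowest index. Fitted
centroids are sorted lexicographically so environment labels are stable
across refits of the same data.

Whether the published environment alphabet standardizes descriptors, and
which metric it uses, is not documented; per-descriptor z-scoring with
Euclidean distance is this package's choice (unstandardized distance would
be dominated by the largest-magnitude descriptor).

## Substitution matrix

From a corpus of encoded profiles, co-occurrence counts C(e, a) of
environment e with amino acid a are smoothed with a pseudocount (default
1.0) and converted to log-odds:

    s(e, a) = log2[ P(e, a) / (P(e) P(a)) ].

Uniform counts give the all-zero matrix; the expected score under
independent sampling from the smoothed marginals is ≤ 0, the usual
requirement for a local-similarity score. The matrix file records the
derivation corpus size and the marginal frequencies (the null-model
calibration samples from them).

## Gapless register alignment and the null model

The shorter of (encoded profile, target sequence) slides through all
|Δlength| + 1 full-containment registers of the longer; a register's raw
score is the sum of s(e_i, a_j) over aligned positions. Partial-overlap
registers are excluded — full containment avoids edge-length
normalization ambiguity and gives the clean register count.

Best-register raw scores of random pairs (environments i.i.d. from the
corpus environment frequencies, residues i.i.d. from a supplied
composition) are modelled as a Gumbel with location linear in ln(m·n):

    p(raw) = 1 − exp(−exp(−(raw − μ(m,n)) / β)),   μ(m,n) = a + b·ln(m·n).

Calibration simulates `n_shuffles` pairs at each grid point (m, n), fits a
per-point Gumbel, regresses locations on ln(m·n), and pools the scale as
the across-grid mean. Two choices matter:

- **Quantile-matching fit.** The per-point location is the empirical
  exp(−1) quantile (for a Gumbel, G(μ) = e⁻¹) and the scale comes from the
  spread of the 95th percentile above it. The true best-register law has a
  slightly lighter upper tail than a Gumbel; moment matching centres the
  nominal 5% type-I error near 4.6%, and maximum likelihood near 3%,
  whereas anchoring the scale at the 95th percentile keeps the 5% tail
  accurate while leaving the body fit (KS ≈ 0.03–0.05 against uniformity
  at 2,000 replicates) essentially unchanged.
- **Fixed-query-length grids.** Per-position scores have negative
  expectation, so the best-register location contains a drift term
  proportional to the overlap length min(m, n) as well as the
  ln(register-count) growth. A grid that varies both lengths conflates the
  two and can even produce b < 0. Calibrating with m fixed and n growing
  makes ln(m·n) track the register count (the E-value regime) and is how
  the shipped calibrations and tests are run. Significance values for
  query lengths far from the calibration grid are extrapolations and
  should be treated as rankings rather than exact p-values.

p-values are floored at 1e-300 so S = −log₁₀(p_nat) − log₁₀(p_den) stays
finite; log base 10 is used for reported significances. The best register
maximizes S, ties to the lowest offset. Scores of −0.0 (both p exactly 1)
are canonicalized to 0.0.

## Fragment vector comparison

Windows of length L are flattened residue-major, each residue contributing
its four native then four denatured descriptors (8·L dimensions; the order
is recoverable via `FragmentVector.unflatten`). Cosines are computed on
raw descriptor values by default. An optional `normalize` flag z-scores
each descriptor over the pooled pair first: raw profiles whose descriptors
share a large constant offset (e.g. enthalpies around −10 kcal/mol) have
all cosines compressed towards 1, and pooled z-scoring restores
discrimination. The flag defaults off to keep the raw-profile behaviour.

- Zero-norm windows have undefined cosine; such pairs are excluded from
  the background with a logged count.
- Cosines are clamped to [−1, 1] after the dot product (floating-point
  round-off can exceed the bound by ~1e-16).
- The epitope test compares the published register's cosine against the
  **arithmetic mean** of the all-pairs background (strictly greater); a
  panel of k-of-n epitopes above average is scored by the exact binomial
  upper tail at p₀ = ½.
- The weight f = M/N restricts to in-register window pairs at the
  full-length eTFR offset, with L = 20 and cutoff 0.95 by default; ties at
  exactly the cutoff are excluded from M ("strictly greater"). The source
  material states the cutoff inconsistently (0.95 in the procedure
  description, 0.99 in a figure caption); 0.95 is the default and the
  cutoff is exposed everywhere. When the overlap is shorter than L the
  weight is undefined and reported as missing, never imputed.

## Correlation pipeline

Chip measurements are summed native + denatured Z-scores; a missing
denatured value is substituted by the native one (z_sum = 2·z_native) and
flagged. Correlations are Pearson r with the two-sided t-test p-value at
n − 2 degrees of freedom, plus the OLS slope and intercept; records with a
missing x value (e.g. undefined f) are dropped with a logged count, never
imputed. The sequence-identity control is a Smith–Waterman local
alignment with BLOSUM62 and affine gaps (open 11, extend 1), reporting
percent identity over the optimal local span; when no positive-scoring
path exists the result is 0% over an empty span. Gap penalties are
configurable; the control's conclusion (no correlation between identity
and binding) is insensitive to the exact choice on synthetic fixtures.

## Synthetic fixtures: what they emulate

The generators are pure functions of (config, seed) and reproduce the
statistical structure of the study design:

- 70 pairs by default (a 7-antibody × 10-binder panel), protein lengths
  100–1,200, uniform amino-acid composition.
- Chip tables plant z_sum = α·S + ε, ε ~ N(0, σ²), with σ chosen
  analytically for a target population r² (default 0.10, the
  modest-correlation regime): r² = α²Var(S) / (α²Var(S) + σ²).
- Environment-clustering ground truth comes from descriptor corpora drawn
  from 8 well-separated Gaussian blobs per state (separation 6 within-blob
  SDs by default).
- Epitope fixtures plant a copied descriptor block between two otherwise
  independent profiles, so the planted register is provably the background
  maximum (cosine 1).

They do **not** emulate: realistic amino-acid composition biases, domain
architecture or secondary-structure correlation in descriptors,
non-Gaussian chip noise, batch effects, or any actual antibody biology.
Passing tests therefore demonstrate the *algorithms* are correct and the
statistical machinery calibrated — not that the surrogate predictor
captures real protein energetics.

## Problem sizes used by the test suite

Chosen as the smallest sizes at which each statistical property is
informative: corpora of 40 proteins of 60–120 residues for environment
fitting and matrices; null calibration grids at query length 60 with
targets 300–800 and 5,000 shuffles per point, validated on 2,000 fresh
replicates; 100 shuffled decoys for self-recognition; 500–1,000
simulations for planted-correlation recovery at the 70-pair design.

## Known limitations

- The surrogate predictor is a fixture, not a physical model; absolute S
  values depend on the profile corpus used to derive the matrix and null.
- μ(m, n) extrapolation away from the calibration grid degrades p-value
  accuracy (rankings remain valid).
- The exact binomial panel test treats epitopes as independent with
  p₀ = ½ under the null; correlated epitopes (shared proteins) would
  require a permutation scheme instead.
- Local-identity tie-breaking returns the aligner's first optimal
  alignment (deterministic), not an exhaustive
  shortest-span/lowest-start enumeration.
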