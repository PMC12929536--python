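# thermomimic

Tools for detecting **ensemble molecular mimicry (EMM)**: the hypothesis
that an antibody raised against one protein can cross-react with a second,
sequence-dissimilar protein because the two proteins' *conformational
ensembles* overlap thermodynamically, even when no sequence or structural
similarity is detectable.

The package is aimed at computational immunologists and protein
biophysicists who want to (1) score how compatible one protein's
thermodynamic ensemble is with another protein's amino-acid sequence,
(2) locate epitope-sized regions of local thermodynamic similarity between
two proteins, and (3) test whether those computed similarities track
experimental antibody-binding measurements from proteome chips.

## The model

Binding free energy decomposes as ΔG_total = ΔG_int + ΔG_conf: an
interfacial term from antibody-antigen contacts and a conformational term —
the cost for the antigen to populate a binding-competent conformation.
`thermomimic` quantifies proxies for the two observable pieces:

- **ΔG_total proxy — chip Z-score.** The summed native + denatured
  fluorescence Z-scores of a protein on a proteome chip probed with an
  anti-virus polyclonal antibody (relative binding affinity).
- **ΔG_conf proxy — eTFR significance S.** Each residue of a protein is
  described by four thermodynamic descriptors, {ΔG, ΔH_ap, ΔH_pol,
  TΔS_conf} (kcal/mol), for the native and the denatured state. Residues
  are encoded as one of 8 **thermodynamic environments** per state (nearest
  centroid of a k-means clustering of descriptor space). The encoded
  profile is aligned **gaplessly** against an amino-acid sequence in all
  |Δlength| + 1 full-containment registers, each register scored by an
  8×20 environment × amino-acid log-odds substitution matrix. Best-register
  raw scores are converted to p-values under a calibrated extreme-value
  (Gumbel) null with location μ(m, n) = a + b·ln(m·n), and

      S = −log₁₀(p_native) − log₁₀(p_denatured),

  maximized over registers, is the eTFR significance.
- **FVC — Fragment Vector Comparison.** Every length-L window of a
  thermodynamic profile is flattened into an 8·L-dimensional vector and
  compared against every window of a second profile by cosine similarity.
  The full all-pairs score set is the *background distribution*; a
  published epitope register can be tested against it ("higher than the
  background average?"), and an exact binomial tail P(X ≥ k | n, ½) scores
  a panel of such epitopes.
- **Weight f = M/N.** Restricting FVC (L = 20) to the window pairs in the
  register of the full-length eTFR alignment, N is the number of in-register
  windows and M the number with cosine > 0.95; S·f down-weights full-length
  significance by the fraction of "very similar" local matches.
- **Identity control.** Smith–Waterman local alignment (BLOSUM62, gap open
  11 / extend 1) provides the percent-identity axis expected to show *no*
  correlation with binding.

Because the upstream descriptor predictor is a trained model whose
parameters are not redistributable, `thermomimic` ships a windowed-mean
propensity surrogate (documented in `docs/methods.md`) and reads externally
produced descriptor tables in a simple TSV format, so real predictor output
can be dropped in.

## Worked example

```python
from thermomimic import (predict_profile, fit_environment_model, assign_environments,
                         build_substitution_matrix, calibrate_null, etfr_align,
                         alignment_weight, binomial_tail)
from thermomimic.synthetic import generate_propensity_table, generate_sequences

# synthetic corpus: 40 random proteins, 60-120 residues
table = generate_propensity_table(seed=11, window=7)
seqs = generate_sequences(40, (60, 120), seed=7)
profiles = {s.id: predict_profile(s, table) for s in seqs}

# thermodynamic-environment alphabet, substitution matrices, Gumbel null
model = fit_environment_model(list(profiles.values()), seed=3)
encoded = {sid: assign_environments(p, model) for sid, p in profiles.items()}
matrices = {st: build_substitution_matrix(list(encoded.values()), st)
            for st in ("native", "denatured")}
grid = [(60, 300), (60, 500), (60, 800)]
nulls = {st: calibrate_null(matrices[st], matrices[st].aa_freq, grid,
                            n_shuffles=1000, seed=19)
         for st in ("native", "denatured")}

# eTFR: protein 0's profile vs protein 1's sequence, and vs its own sequence
query, target = seqs[0], seqs[1]
aln = etfr_align(encoded[query.id], target, matrices, nulls)
self_aln = etfr_align(encoded[query.id], query, matrices, nulls)
f, M, N = alignment_weight(profiles[query.id], profiles[target.id],
                           aln.offset, L=20, cutoff=0.95, normalize=True)
```

This prints:

```
query=syn0000 target=syn0001 offset=0
p_native=1  p_denatured=1  S=0.00
self-alignment S=10.95
f=0.000 (M=0 of N=79 windows > 0.95)  S*f=0.00
P(X >= 9 | n=11, p=0.5) = 0.0327
```

Read: an unrelated random pair has no detectable ensemble compatibility
(p ≈ 1 in both states, S ≈ 0, no very-similar local windows, so f = 0),
while the same profile aligned to its *own* generating sequence is
recognized at S ≈ 11 — the self-recognition property that anchors the
method. The last line is the exact binomial significance of 9 out of 11
epitopes scoring above their background average: p ≈ 0.033 < 0.05.

## Command line

One executable, `emm`, with a subcommand per stage:

```bash
emm simulate  --outdir bundle --seed 1          # synthetic fixture bundle
emm profile   --fasta seqs.fasta --out prof.tsv # descriptor profiles
emm fit-env   --profiles prof.tsv --out env.json
emm encode    --profiles prof.tsv --model env.json --out enc.tsv
emm build-matrix --profiles prof.tsv --model env.json --state native --out nat.tsv
emm calibrate --matrix nat.tsv --out nat_null.json
emm etfr      --query prof.tsv --targets db.fasta --model env.json \
              --matrix-nat nat.tsv --matrix-den den.tsv \
              --null-nat nat_null.json --null-den den_null.json --out hits.tsv
emm fvc       --a profA.tsv --b profB.tsv -L 15 --out cosines.tsv
emm weight    --a profA.tsv --b profB.tsv --offset 12 -L 20 --cutoff 0.95
emm correlate --pairs pairs.tsv --x S_weighted
emm pipeline  --outdir run1 --seed 1            # full synthetic end-to-end
```

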