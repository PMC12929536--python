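"""Synthetic fixture generators for the whole tool surface.

Every generator is a pure function of its configuration and seed, so test
inputs are reproducible and never shipped as data files.  The generators
emulate the statistical structure of the study design: random protein
sequences, per-amino-acid descriptor propensity tables, descriptor corpora
drawn from separated Gaussian blobs (so the environment clustering has a
known ground truth), protein pairs with a planted thermodynamically
identical fragment (the epitope fixture), and chip tables in which the
summed Z-score depends linearly on the eTFR significance with Gaussian
noise (the modest-correlation regime of the 70-pair panel).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .pipeline import PairRecord
from .profiles import (AMINO_ACIDS, N_DESCRIPTORS, PropensityTable,
                       ProteinSequence, ThermodynamicProfile)

#: Per-descriptor location/scale (kcal/mol) used when drawing propensity
#: tables; loosely patterned on the magnitudes of local folding energetics
#: (free energies of a few kcal/mol, enthalpies around ten).
_NATIVE_LOC = np.array([2.0, -10.0, 8.0, 3.0])
_NATIVE_SCALE = np.array([1.5, 4.0, 3.0, 1.5])
_DENATURED_LOC = np.array([0.5, -4.0, 3.0, 5.0])
_DENATURED_SCALE = np.array([1.0, 3.0, 2.0, 1.5])


@dataclass(frozen=True)
class FixtureConfig:
    """Study-condition defaults for synthetic fixtures.

    70 pairs mirrors the 7-antibody x 10-binder panel; lengths span the
    viral antigens and human binders involved; the planted population
    r-squared of 0.10 matches the modest-correlation regime.
    """

    seed: int = 0
    n_proteins: int = 70
    length_range: tuple[int, int] = (100, 1200)
    composition: np.ndarray = field(
        default_factory=lambda: np.full(20, 0.05))
    blob_separation: float = 6.0
    alpha: float = 1.0
    r_squared: float = 0.10
    fragment_length: int = 20

    def __post_init__(self) -> None:
        comp = np.asarray(self.composition, dtype=float)
        if comp.shape != (20,) or not np.isclose(comp.sum(), 1.0):
            raise ValueError("composition must be 20 frequencies summing to 1")
        object.__setattr__(self, "composition", comp)

    def with_seed(self, seed: int) -> "FixtureConfig":
        return replace(self, seed=seed)


def generate_sequences(n: int, length_range: tuple[int, int] = (100, 1200),
                       composition: np.ndarray | None = None,
                       seed: int = 0, id_prefix: str = "syn") -> list[ProteinSequence]:
    """i.i.d. random sequences; lengths uniform over ``length_range``."""
    rng = np.random.default_rng(seed)
    comp = (np.full(20, 0.05) if composition is None
            else np.asarray(composition, dtype=float))
    comp = comp / comp.sum()
    lo, hi = length_range
    if lo < 1:
        raise ValueError("minimum length must be >= 1")
    seqs = []
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        letters = rng.choice(list(AMINO_ACIDS), size=L, p=comp)
        seqs.append(ProteinSequence(id=f"{id_prefix}{i:04d}", residues="".join(letters)))
    return seqs


def generate_propensity_table(seed: int = 0, window: int = 7) -> PropensityTable:
    """Draw a 20x8 propensity table with descriptor-scale magnitudes."""
    rng = np.random.default_rng(seed)
    native = _NATIVE_LOC + _NATIVE_SCALE * rng.standard_normal((20, N_DESCRIPTORS))
    denat = _DENATURED_LOC + _DENATURED_SCALE * rng.standard_normal((20, N_DESCRIPTORS))
    return PropensityTable(values=np.hstack([native, denat]), window=window)


def generate_blob_profiles(n_proteins: int = 30, length: int = 120,
                           separation: float = 6.0, k: int = 8,
                           seed: int = 0
                           ) -> tuple[list[ThermodynamicProfile], np.ndarray, np.ndarray]:
    """Profiles whose residue descriptors come from k separated Gaussian blobs.

    Per state, k blob centres are placed on a scaled simplex-like layout
    (pairwise distance ~ ``separation`` in units of the within-blob SD of 1)
    and each residue's 4-vector is centre + standard normal noise.  Returns
    the profiles plus the true native and denatured centres, for clustering
    ground-truth tests.
    """
    rng = np.random.default_rng(seed)
    seqs = generate_sequences(n_proteins, (length, length), seed=seed + 1,
                              id_prefix="blob")

    def centres() -> np.ndarray:
        # random directions, pushed apart to the requested separation
        c = rng.standard_normal((k, N_DESCRIPTORS))
        c *= separation / np.sqrt(2.0)
        return c

    nat_centres = centres()
    den_centres = centres()
    profiles = []
    for seq in seqs:
        labels_nat = rng.integers(0, k, size=len(seq))
        labels_den = rng.integers(0, k, size=len(seq))
        native = nat_centres[labels_nat] + rng.standard_normal((len(seq), N_DESCRIPTORS))
        denat = den_centres[labels_den] + rng.standard_normal((len(seq), N_DESCRIPTORS))
        profiles.append(ThermodynamicProfile(sequence=seq, native=native,
                                             denatured=denat))
    return profiles, nat_centres, den_centres


def random_profile(seq: ProteinSequence, seed: int = 0,
                   loc: float = 0.0, scale: float = 1.0) -> ThermodynamicProfile:
    """A profile with i.i.d. Gaussian descriptors (no sequence dependence)."""
    rng = np.random.default_rng(seed)
    shape = (len(seq), N_DESCRIPTORS)
    return ThermodynamicProfile(sequence=seq,
                                native=loc + scale * rng.standard_normal(shape),
                                denatured=loc + scale * rng.standard_normal(shape))


def plant_fragment(profileA: ThermodynamicProfile, profileB: ThermodynamicProfile,
                   length: int, startA: int, startB: int
                   ) -> tuple[ThermodynamicProfile, ThermodynamicProfile]:
    """Copy a descriptor block of ``length`` residues from A into B.

    ``startA``/``startB`` are 1-based.  Returns (A unchanged, modified B);
    inputs are not mutated.  A zero-length plant returns the pair unchanged.
    """
    if length == 0:
        return profileA, profileB
    if length < 0:
        raise ValueError("fragment length must be >= 0")
    if not (1 <= startA and startA + length - 1 <= len(profileA)):
        raise ValueError(f"fragment [{startA}, {startA + length - 1}] out of "
                         f"range for protein A of length {len(profileA)}")
    if not (1 <= startB and startB + length - 1 <= len(profileB)):
        raise ValueError(f"fragment [{startB}, {startB + length - 1}] out of "
                         f"range for protein B of length {len(profileB)}")
    a0, b0 = startA - 1, startB - 1
    native = profileB.native.copy()
    denat = profileB.denatured.copy()
    native[b0:b0 + length] = profileA.native[a0:a0 + length]
    denat[b0:b0 + length] = profileA.denatured[a0:a0 + length]
    return profileA, ThermodynamicProfile(sequence=profileB.sequence,
                                          native=native, denatured=denat)


def noise_sd_for_r_squared(alpha: float, s_values: np.ndarray,
                           r_squared: float) -> float:
    """Residual SD giving a planted population r-squared.

    r2 = alpha^2 Var(S) / (alpha^2 Var(S) + sigma^2), solved for sigma.
    """
    if not 0 < r_squared < 1:
        raise ValueError("r_squared must lie in (0, 1)")
    var_s = float(np.var(np.asarray(s_values, dtype=float)))
    if var_s <= 0:
        raise ValueError("S values have zero variance")
    return abs(alpha) * np.sqrt(var_s) * np.sqrt((1 - r_squared) / r_squared)


def generate_chip_table(s_values: Sequence[float], alpha: float, sigma: float,
                        seed: int = 0, n_viruses: int = 7) -> list[PairRecord]:
    """Pair records with z_sum = alpha*S + Gaussian(0, sigma) noise.

    Pairs are labelled as a viruses x humans panel in row-major order.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = np.random.default_rng(seed)
    s = np.asarray(s_values, dtype=float)
    z = alpha * s + rng.normal(0.0, sigma, size=len(s))
    per_virus = max(1, len(s) // n_viruses)
    records = []
    for i, (si, zi) in enumerate(zip(s, z)):
        records.append(PairRecord(virus_id=f"virus{i // per_virus:02d}",
                                  human_id=f"human{i:03d}",
                                  z_sum=float(zi), S=float(si)))
    return records


def generate_significances(n: int = 70, seed: int = 0, mean: float = 4.0,
                           sd: float = 1.5) -> np.ndarray:
    """Plausible eTFR significances: truncated-at-zero Gaussian spread."""
    rng = np.random.default_rng(seed)
    return np.abs(rng.normal(mean, sd, size=n))


def write_fixture_bundle(outdir: str | Path, config: FixtureConfig) -> dict:
    """Write a self-describing FASTA + TSV fixture bundle with a manifest."""
    import json

    from .profiles import write_fasta
    from .pipeline import write_pair_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seqs = generate_sequences(config.n_proteins, config.length_range,
                              config.composition, seed=config.seed)
    write_fasta(seqs, outdir / "sequences.fasta")
    table = generate_propensity_table(seed=config.seed + 1)
    table.to_tsv(outdir / "propensity.tsv")
    s_values = generate_significances(config.n_proteins, seed=config.seed + 2)
    sigma = noise_sd_for_r_squared(config.alpha, s_values, config.r_squared)
    records = generate_chip_table(s_values, config.alpha, sigma,
                                  seed=config.seed + 3)
    write_pair_table(records, outdir / "pairs.tsv")
    manifest = {"seed": config.seed, "n_proteins": config.n_proteins,
                "length_range": list(config.length_range),
                "alpha": config.alpha, "r_squared": config.r_squared,
                "sigma": sigma,
                "files": ["sequences.fasta", "propensity.tsv", "pairs.tsv"]}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
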