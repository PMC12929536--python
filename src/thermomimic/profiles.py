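"""Sequences, per-residue thermodynamic descriptor profiles, and environment encoding.

A protein's conformational ensemble is summarized per residue by four
thermodynamic descriptors -- the local folding free energy dG and its
apolar-enthalpy, polar-enthalpy and conformational-entropy components
(dH_ap, dH_pol, TdS_conf; kcal/mol) -- computed separately for the native
and the denatured state.  Residues are then mapped to one of eight
"thermodynamic environments" per state: the index of the nearest centroid
of a k-means clustering of a descriptor database.  The resulting pair of
integer strings over an eight-letter alphabet is the input to thermodynamic
fold recognition (:mod:`thermomimic.etfr`).

The descriptor predictor shipped here is a windowed-mean propensity model:
each descriptor at residue i is the mean of per-amino-acid propensity
values over a symmetric window centred at i (truncated at chain ends).
Externally produced descriptor tables can be imported through
:func:`read_profiles_tsv`, so the predictor is replaceable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
from Bio import SeqIO
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

#: Canonical 20-letter amino-acid alphabet, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Letters accepted in input FASTA but not part of the canonical alphabet.
AMBIGUOUS_LETTERS = set("BJOUXZ*")

#: Descriptor column order used throughout the package.
DESCRIPTORS = ("dG", "dH_ap", "dH_pol", "TdS_conf")
N_DESCRIPTORS = len(DESCRIPTORS)

State = Literal["native", "denatured"]
STATES: tuple[State, State] = ("native", "denatured")

#: Number of thermodynamic environments per state.
N_ENVIRONMENTS = 8


class AmbiguousResidueError(ValueError):
    """Raised when a sequence contains non-canonical letters under policy='error'."""


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence over the canonical 20-letter alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-canonical letters {sorted(bad)}; "
                "sanitize with sanitize_sequence() first"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def indices(self) -> np.ndarray:
        """Residues as integer indices into :data:`AMINO_ACIDS`."""
        return np.fromiter((AA_INDEX[a] for a in self.residues), dtype=np.intp,
                           count=len(self.residues))


def sanitize_sequence(seq_id: str, raw: str,
                      ambiguous: Literal["strip", "error"] = "strip") -> ProteinSequence:
    """Uppercase ``raw`` and resolve non-canonical letters.

    ``strip`` removes ambiguous letters (B, J, O, U, X, Z and ``*``) with a
    logged warning; ``error`` raises :class:`AmbiguousResidueError`.
    """
    upper = raw.upper().replace("-", "").replace(" ", "")
    bad = [a for a in upper if a not in AA_INDEX]
    if bad:
        if ambiguous == "error":
            raise AmbiguousResidueError(
                f"sequence {seq_id!r} contains ambiguous residues {sorted(set(bad))}")
        logger.warning("sequence %r: stripped %d ambiguous residue(s) %s",
                       seq_id, len(bad), sorted(set(bad)))
        upper = "".join(a for a in upper if a in AA_INDEX)
    if not upper:
        raise ValueError(f"sequence {seq_id!r} has no residues after sanitization")
    return ProteinSequence(id=seq_id, residues=upper)


def read_fasta(path: str | Path,
               ambiguous: Literal["strip", "error"] = "strip") -> list[ProteinSequence]:
    """Read a FASTA file into :class:`ProteinSequence` records, in file order.

    Record ids are the header up to the first whitespace.  An empty file or a
    record with an empty sequence is an error.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        records.append(sanitize_sequence(rec.id, str(rec.seq), ambiguous=ambiguous))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path,
                width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Propensity tables and the windowed-mean descriptor predictor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PropensityTable:
    """Per-amino-acid descriptor propensities: 20 rows x 8 columns.

    Columns are the four descriptors for the native state followed by the
    four for the denatured state, in :data:`DESCRIPTORS` order.  ``window``
    is the odd width of the symmetric smoothing window used by
    :func:`predict_profile`.
    """

    values: np.ndarray  # (20, 8), row order = AMINO_ACIDS
    window: int = 7

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (20, 2 * N_DESCRIPTORS):
            raise ValueError(f"propensity table must be 20x8, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("propensity table contains non-finite values")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 1, got {self.window}")
        object.__setattr__(self, "values", v)

    def row(self, aa: str) -> np.ndarray:
        try:
            return self.values[AA_INDEX[aa]]
        except KeyError:
            raise KeyError(f"amino acid {aa!r} absent from propensity table") from None

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        cols = [f"{d}_{s}" for s in STATES for d in DESCRIPTORS]
        with path.open("w") as fh:
            fh.write(f"# window={self.window}\n")
            fh.write("aa\t" + "\t".join(cols) + "\n")
            for i, aa in enumerate(AMINO_ACIDS):
                fh.write(aa + "\t" + "\t".join(f"{x:.6f}" for x in self.values[i]) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PropensityTable":
        path = Path(path)
        window = 7
        rows: dict[str, list[float]] = {}
        with path.open() as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "window=" in line:
                        window = int(line.split("window=")[1].split()[0])
                    continue
                parts = line.split("\t")
                if parts[0] == "aa":
                    continue
                rows[parts[0]] = [float(x) for x in parts[1:]]
        missing = set(AMINO_ACIDS) - set(rows)
        if missing:
            raise ValueError(f"propensity table missing amino acids {sorted(missing)}")
        values = np.array([rows[aa] for aa in AMINO_ACIDS])
        return cls(values=values, window=window)


def default_propensity_table() -> PropensityTable:
    """The versioned propensity table shipped with the package."""
    path = Path(__file__).parent / "data" / "propensity_default.tsv"
    return PropensityTable.from_tsv(path)


@dataclass(frozen=True)
class ThermodynamicProfile:
    """Per-residue thermodynamic descriptors for one protein, both states.

    ``native`` and ``denatured`` are (L, 4) arrays in :data:`DESCRIPTORS`
    column order, one row per residue (1-based residue i is row i-1).
    """

    sequence: ProteinSequence
    native: np.ndarray
    denatured: np.ndarray

    def __post_init__(self) -> None:
        L = len(self.sequence)
        for name in ("native", "denatured"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (L, N_DESCRIPTORS):
                raise ValueError(f"{name} descriptor array must be ({L}, 4), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} descriptors contain non-finite values")
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return len(self.sequence)

    def state(self, state: State) -> np.ndarray:
        if state not in STATES:
            raise ValueError(f"unknown state {state!r}")
        return self.native if state == "native" else self.denatured

    def stacked(self) -> np.ndarray:
        """(L, 8) array: native then denatured descriptors per residue."""
        return np.hstack([self.native, self.denatured])


def predict_profile(seq: ProteinSequence, table: PropensityTable) -> ThermodynamicProfile:
    """Windowed-mean descriptor prediction.

    Each descriptor at residue i is the mean of the propensity-table values
    of the residues in a symmetric window of width ``table.window`` centred
    at i, truncated at the chain ends (windows are shorter near termini).
    """
    idx = seq.indices()
    per_residue = table.values[idx]          # (L, 8)
    L = len(seq)
    half = table.window // 2
    if half == 0:
        smoothed = per_residue
    else:
        # cumulative-sum sliding mean with edge truncation
        csum = np.vstack([np.zeros((1, per_residue.shape[1])),
                          np.cumsum(per_residue, axis=0)])
        starts = np.maximum(np.arange(L) - half, 0)
        stops = np.minimum(np.arange(L) + half + 1, L)
        smoothed = (csum[stops] - csum[starts]) / (stops - starts)[:, None]
    return ThermodynamicProfile(sequence=seq,
                                native=smoothed[:, :N_DESCRIPTORS],
                                denatured=smoothed[:, N_DESCRIPTORS:])


# ---------------------------------------------------------------------------
# Profile TSV import/export
# ---------------------------------------------------------------------------

def write_profiles_tsv(profiles: Iterable[ThermodynamicProfile], path: str | Path) -> None:
    """Write profiles as long-format TSV (6-decimal round trip).

    Columns: id, position (1-based), aa, state, dG, dH_ap, dH_pol, TdS_conf.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id\tposition\taa\tstate\t" + "\t".join(DESCRIPTORS) + "\n")
        for prof in profiles:
            for state in STATES:
                arr = prof.state(state)
                for i in range(len(prof)):
                    vals = "\t".join(f"{x:.6f}" for x in arr[i])
                    fh.write(f"{prof.sequence.id}\t{i + 1}\t"
                             f"{prof.sequence.residues[i]}\t{state}\t{vals}\n")


def read_profiles_tsv(path: str | Path) -> list[ThermodynamicProfile]:
    """Read profiles written by :func:`write_profiles_tsv` (or eScape exports
    in the same long format)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"id", "position", "aa", "state", *DESCRIPTORS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile TSV {path} missing columns {sorted(missing)}")
    profiles = []
    for pid, grp in df.groupby("id", sort=False):
        arrays: dict[str, np.ndarray] = {}
        residues = None
        for state in STATES:
            sub = grp[grp["state"] == state].sort_values("position")
            if sub.empty:
                raise ValueError(f"profile {pid!r}: no rows for state {state!r}")
            positions = sub["position"].to_numpy()
            if not np.array_equal(positions, np.arange(1, len(sub) + 1)):
                raise ValueError(f"profile {pid!r}, state {state!r}: positions not 1..L")
            arrays[state] = sub[list(DESCRIPTORS)].to_numpy(dtype=float)
            residues = "".join(sub["aa"])
        seq = ProteinSequence(id=str(pid), residues=residues)
        profiles.append(ThermodynamicProfile(sequence=seq,
                                             native=arrays["native"],
                                             denatured=arrays["denatured"]))
    if not profiles:
        raise ValueError(f"no profiles found in {path}")
    return profiles


# ---------------------------------------------------------------------------
# Thermodynamic-environment model (per-state k-means over descriptor space)
# ---------------------------------------------------------------------------

@dataclass
class EnvironmentModel:
    """Eight thermodynamic-environment centroids per state.

    Centroids live in *standardized* descriptor space; ``mean``/``std`` hold
    the per-state, per-descriptor standardization constants estimated from
    the training corpus.  Centroids are sorted lexicographically after
    fitting so environment indices are stable across refits of the same data.
    """

    native_centroids: np.ndarray     # (k, 4), standardized space
    denatured_centroids: np.ndarray  # (k, 4)
    native_mean: np.ndarray
    native_std: np.ndarray
    denatured_mean: np.ndarray
    denatured_std: np.ndarray
    k: int = N_ENVIRONMENTS
    seed: int | None = None
    provenance: dict = field(default_factory=dict)

    def centroids(self, state: State) -> np.ndarray:
        return self.native_centroids if state == "native" else self.denatured_centroids

    def standardize(self, x: np.ndarray, state: State) -> np.ndarray:
        if state == "native":
            return (x - self.native_mean) / self.native_std
        return (x - self.denatured_mean) / self.denatured_std

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "seed": self.seed,
            "provenance": self.provenance,
            "descriptors": list(DESCRIPTORS),
        }
        for state in STATES:
            payload[f"{state}_centroids"] = self.centroids(state).tolist()
        payload["native_mean"] = self.native_mean.tolist()
        payload["native_std"] = self.native_std.tolist()
        payload["denatured_mean"] = self.denatured_mean.tolist()
        payload["denatured_std"] = self.denatured_std.tolist()
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "EnvironmentModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            native_centroids=np.array(payload["native_centroids"]),
            denatured_centroids=np.array(payload["denatured_centroids"]),
            native_mean=np.array(payload["native_mean"]),
            native_std=np.array(payload["native_std"]),
            denatured_mean=np.array(payload["denatured_mean"]),
            denatured_std=np.array(payload["denatured_std"]),
            k=payload["k"],
            seed=payload.get("seed"),
            provenance=payload.get("provenance", {}),
        )


def _fit_state(points: np.ndarray, k: int, seed: int, n_init: int,
               tol: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if len(np.unique(points, axis=0)) < k:
        raise ValueError(f"fewer than k={k} distinct descriptor vectors")
    mean = points.mean(axis=0)
    std = points.std(axis=0, ddof=0)
    if np.any(std <= 0):
        raise ValueError("degenerate descriptor dimension: zero standard deviation")
    z = (points - mean) / std
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, tol=tol,
                random_state=seed)
    km.fit(z)
    # lexicographic sort keeps environment labels stable across refits
    order = np.lexsort(km.cluster_centers_.T[::-1])
    return km.cluster_centers_[order], mean, std


def fit_environment_model(profiles: Sequence[ThermodynamicProfile],
                          k: int = N_ENVIRONMENTS, seed: int = 0,
                          n_init: int = 100, tol: float = 1e-6) -> EnvironmentModel:
    """Fit per-state k-means environment centroids on a profile corpus.

    Descriptor vectors are pooled across all profiles, z-scored per
    descriptor (per state), and clustered with k-means++ initialization.
    Deterministic for a fixed seed.
    """
    if not profiles:
        raise ValueError("cannot fit an environment model on an empty corpus")
    nat = np.vstack([p.native for p in profiles])
    den = np.vstack([p.denatured for p in profiles])
    if len(nat) < k:
        raise ValueError(f"need at least k={k} pooled residues, got {len(nat)}")
    nat_c, nat_m, nat_s = _fit_state(nat, k, seed, n_init, tol)
    den_c, den_m, den_s = _fit_state(den, k, seed, n_init, tol)
    return EnvironmentModel(
        native_centroids=nat_c, denatured_centroids=den_c,
        native_mean=nat_m, native_std=nat_s,
        denatured_mean=den_m, denatured_std=den_s,
        k=k, seed=seed,
        provenance={"n_profiles": len(profiles), "n_residues": int(len(nat)),
                    "n_init": n_init, "tol": tol},
    )


@dataclass(frozen=True)
class EncodedProfile:
    """Per-residue thermodynamic-environment indices (0..k-1) for both states."""

    sequence: ProteinSequence
    native_env: np.ndarray
    denatured_env: np.ndarray

    def __post_init__(self) -> None:
        L = len(self.sequence)
        for name in ("native_env", "denatured_env"):
            arr = np.asarray(getattr(self, name), dtype=np.intp)
            if arr.shape != (L,):
                raise ValueError(f"{name} must have length {L}, got {arr.shape}")
            if arr.min(initial=0) < 0 or arr.max(initial=0) >= N_ENVIRONMENTS:
                raise ValueError(f"{name} values outside [0, {N_ENVIRONMENTS - 1}]")
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return len(self.sequence)

    def env(self, state: State) -> np.ndarray:
        return self.native_env if state == "native" else self.denatured_env


def assign_environments(profile: ThermodynamicProfile,
                        model: EnvironmentModel) -> EncodedProfile:
    """Assign each residue the index of its nearest environment centroid.

    Distances are Euclidean in the model's standardized descriptor space;
    ties go to the lowest centroid index (argmin convention).
    """
    envs = {}
    for state in STATES:
        z = model.standardize(profile.state(state), state)
        d2 = ((z[:, None, :] - model.centroids(state)[None, :, :]) ** 2).sum(axis=2)
        envs[state] = np.argmin(d2, axis=1)
    return EncodedProfile(sequence=profile.sequence,
                          native_env=envs["native"],
                          denatured_env=envs["denatured"])


def encode_corpus(profiles: Iterable[ThermodynamicProfile],
                  model: EnvironmentModel) -> Iterator[EncodedProfile]:
    for p in profiles:
        yield assign_environments(p, model)
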