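"""Fragment Vector Comparison: windowed cosine similarity of thermodynamic profiles.

Every length-L window of a profile is flattened into an 8*L-dimensional
vector (residue-major; per residue the four native descriptors then the
four denatured ones) and compared against every window of a second profile
by cosine similarity.  The full all-pairs score set for a protein pair is
the *background distribution* against which a published epitope register is
judged; the fraction f = M/N of in-register windows above a cutoff weights
the full-length eTFR significance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass


import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .profiles import N_DESCRIPTORS, ThermodynamicProfile

logger = logging.getLogger(__name__)

#: Default fragment window (residues) for the in-register weight f = M/N.
DEFAULT_WINDOW = 20
#: Default "very similar" cosine cutoff for the weight f = M/N.
DEFAULT_CUTOFF = 0.95


@dataclass(frozen=True)
class FragmentVector:
    """One flattened 8*L window of a thermodynamic profile."""

    protein_id: str
    start: int  # 1-based
    L: int
    v: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.v, dtype=float)
        if v.shape != (2 * N_DESCRIPTORS * self.L,):
            raise ValueError(f"fragment vector must have dimension {8 * self.L}")
        object.__setattr__(self, "v", v)

    def unflatten(self) -> tuple[np.ndarray, np.ndarray]:
        """Recover the (L, 4) native and denatured profile slices."""
        block = self.v.reshape(self.L, 2 * N_DESCRIPTORS)
        return block[:, :N_DESCRIPTORS], block[:, N_DESCRIPTORS:]


@dataclass(frozen=True)
class FragmentMatch:
    startA: int  # 1-based
    startB: int
    L: int
    cosine: float


@dataclass
class BackgroundDistribution:
    """All pairwise window cosines for one protein pair at window length L."""

    idA: str
    idB: str
    L: int
    scores: np.ndarray          # defined (non-degenerate) cosines, flat
    n_total: int                # (L_A-L+1)*(L_B-L+1)
    n_missing: int              # zero-norm window pairs excluded

    @property
    def mean(self) -> float:
        return float(self.scores.mean())

    def summary(self) -> dict:
        q1, med, q3 = np.percentile(self.scores, [25, 50, 75])
        return {"min": float(self.scores.min()), "q1": float(q1),
                "median": float(med), "mean": self.mean, "q3": float(q3),
                "max": float(self.scores.max()), "count": int(self.scores.size)}


@dataclass(frozen=True)
class EpitopeTest:
    """One published epitope register judged against its pair background."""

    idA: str
    idB: str
    startA: int
    startB: int
    L: int
    epitope_cosine: float
    background_mean: float
    above_average: bool


def _windows_from_stacked(stacked: np.ndarray, L: int) -> np.ndarray:
    n = stacked.shape[0]
    wins = sliding_window_view(stacked, L, axis=0)  # (n-L+1, 8, L)
    return np.ascontiguousarray(wins.transpose(0, 2, 1).reshape(n - L + 1, -1))


def window_matrix(profile: ThermodynamicProfile, L: int) -> np.ndarray:
    """(n_windows, 8*L) matrix of flattened windows, starts 1..len-L+1."""
    n = len(profile)
    if not 1 <= L <= n:
        raise ValueError(f"window length {L} invalid for protein of length {n}")
    return _windows_from_stacked(profile.stacked(), L)


def _stacked_pair(profileA: ThermodynamicProfile, profileB: ThermodynamicProfile,
                  normalize: bool) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue 8-descriptor arrays for both profiles.

    With ``normalize``, each descriptor is z-scored using the pooled mean
    and SD of the two profiles, so descriptors with large constant offsets
    (e.g. enthalpies around -10 kcal/mol) do not dominate the cosine.
    """
    sa, sb = profileA.stacked(), profileB.stacked()
    if normalize:
        pooled = np.vstack([sa, sb])
        mean = pooled.mean(axis=0)
        sd = pooled.std(axis=0)
        sd[sd == 0] = 1.0
        sa = (sa - mean) / sd
        sb = (sb - mean) / sd
    return sa, sb


def fragment_vectors(profile: ThermodynamicProfile, L: int) -> list[FragmentVector]:
    mat = window_matrix(profile, L)
    pid = profile.sequence.id
    return [FragmentVector(protein_id=pid, start=i + 1, L=L, v=mat[i])
            for i in range(mat.shape[0])]


def _cosine_matrix(profileA: ThermodynamicProfile, profileB: ThermodynamicProfile,
                   L: int, normalize: bool = False) -> np.ndarray:
    """All-pairs cosine matrix; zero-norm windows produce NaN rows/columns."""
    for prof in (profileA, profileB):
        if not 1 <= L <= len(prof):
            raise ValueError(f"window length {L} invalid for protein "
                             f"{prof.sequence.id!r} of length {len(prof)}")
    sa, sb = _stacked_pair(profileA, profileB, normalize)
    A = _windows_from_stacked(sa, L)
    B = _windows_from_stacked(sb, L)
    normA = np.linalg.norm(A, axis=1)
    normB = np.linalg.norm(B, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = (A @ B.T) / np.outer(normA, normB)
    C[normA == 0, :] = np.nan
    C[:, normB == 0] = np.nan
    np.clip(C, -1.0, 1.0, out=C)  # NaN (undefined) entries pass through
    return C


def fvc_compare(profileA: ThermodynamicProfile, profileB: ThermodynamicProfile,
                L: int, cutoff: float = 0.0, normalize: bool = False
                ) -> tuple[list[FragmentMatch], BackgroundDistribution]:
    """All-pairs windowed cosine comparison of two profiles.

    Returns matches with cosine >= ``cutoff`` sorted by descending cosine
    (ties by startA then startB), plus the full background distribution.
    Cosines operate on raw descriptor values by default; ``normalize``
    z-scores each descriptor over the pooled pair first.  Window pairs
    involving a zero-norm fragment have undefined cosine and are excluded,
    with a logged count.
    """
    if not -1.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [-1, 1]")
    C = _cosine_matrix(profileA, profileB, L, normalize)
    missing = np.isnan(C)
    n_missing = int(missing.sum())
    if n_missing:
        logger.warning("fvc_compare(%s, %s, L=%d): %d zero-norm window pair(s) excluded",
                       profileA.sequence.id, profileB.sequence.id, L, n_missing)
    background = BackgroundDistribution(
        idA=profileA.sequence.id, idB=profileB.sequence.id, L=L,
        scores=C[~missing].ravel(), n_total=C.size, n_missing=n_missing)
    ia, ib = np.nonzero(~missing & (C >= cutoff))
    order = np.lexsort((ib, ia, -C[ia, ib]))
    matches = [FragmentMatch(startA=int(ia[k]) + 1, startB=int(ib[k]) + 1,
                             L=L, cosine=float(C[ia[k], ib[k]]))
               for k in order]
    return matches, background


def epitope_background_test(profileA: ThermodynamicProfile,
                            profileB: ThermodynamicProfile,
                            L: int, startA: int, startB: int,
                            normalize: bool = False) -> EpitopeTest:
    """Compare a published epitope register's cosine with the pair background.

    ``startA``/``startB`` are the 1-based window starts of the published
    alignment; ``above_average`` is a strict comparison with the arithmetic
    mean of all window-pair cosines for this pair at length L.
    """
    C = _cosine_matrix(profileA, profileB, L, normalize)
    nA, nB = C.shape
    if not (1 <= startA <= nA and 1 <= startB <= nB):
        raise ValueError(
            f"epitope register ({startA}, {startB}) with L={L} out of range "
            f"for proteins of length {len(profileA)} and {len(profileB)}")
    epi = C[startA - 1, startB - 1]
    if math.isnan(epi):
        raise ValueError("epitope fragment has zero norm; cosine undefined")
    mean = float(np.nanmean(C))
    return EpitopeTest(idA=profileA.sequence.id, idB=profileB.sequence.id,
                       startA=startA, startB=startB, L=L,
                       epitope_cosine=float(epi), background_mean=mean,
                       above_average=bool(epi > mean))


def binomial_tail(k: int, n: int, p0: float = 0.5) -> float:
    """Exact upper-tail binomial probability P(X >= k), X ~ Binomial(n, p0).

    Used for the epitope panel: the chance that at least k of n epitopes
    score above their background average if each did so with probability p0.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    return float(sum(math.comb(n, i) * p0 ** i * (1 - p0) ** (n - i)
                     for i in range(k, n + 1)))


def alignment_weight(profileA: ThermodynamicProfile,
                     profileB: ThermodynamicProfile,
                     etfr_offset: int, L: int = DEFAULT_WINDOW,
                     cutoff: float = DEFAULT_CUTOFF,
                     normalize: bool = False) -> tuple[float | None, int, int]:
    """The in-register weight f = M/N at a full-length eTFR register.

    Only window pairs in the register of the full-length alignment are
    considered: the shorter protein's window at start s pairs with the
    longer's window at start s + offset, both windows inside the overlap.
    N is the number of such pairs, M the number with cosine strictly greater
    than ``cutoff``, and f = M/N.  If the overlap is shorter than L the
    weight is undefined and (None, 0, 0) is returned.
    """
    # cosine is symmetric, so only shorter-vs-longer orientation matters
    if len(profileA) <= len(profileB):
        short, long_ = profileA, profileB
    else:
        short, long_ = profileB, profileA
    if not 0 <= etfr_offset <= len(long_) - len(short):
        raise ValueError(f"offset {etfr_offset} outside [0, {len(long_) - len(short)}]")
    overlap = len(short)
    if overlap < L:
        logger.warning("alignment_weight: overlap %d < window %d; f undefined",
                       overlap, L)
        return None, 0, 0
    ss, sl = _stacked_pair(short, long_, normalize)
    Ws = _windows_from_stacked(ss, L)                  # starts 1..overlap-L+1
    Wl = _windows_from_stacked(sl, L)[etfr_offset:etfr_offset + Ws.shape[0]]
    num = (Ws * Wl).sum(axis=1)
    den = np.linalg.norm(Ws, axis=1) * np.linalg.norm(Wl, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = num / den
    defined = ~np.isnan(cos)
    n_missing = int((~defined).sum())
    if n_missing:
        logger.warning("alignment_weight: %d zero-norm window pair(s) excluded", n_missing)
    N = int(defined.sum())
    if N == 0:
        return None, 0, 0
    M = int((cos[defined] > cutoff).sum())
    return M / N, M, N
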