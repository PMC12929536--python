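"""Cross-reactivity analysis: chip Z-scores vs thermodynamic similarity.

Proteome-chip binding of a human protein to an anti-virus polyclonal is
summarized as the sum of its native-condition and denatured-condition
Z-scores (a relative-affinity proxy).  For each virus-human pair this
module correlates that summed Z with the eTFR significance S, with the
FVC-weighted significance S*f, or with the percent sequence identity of a
Smith-Waterman/BLOSUM62 local alignment (the identity control expected to
show no correlation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

from .profiles import ProteinSequence

logger = logging.getLogger(__name__)


class ZSum(NamedTuple):
    z_sum: float
    substituted: bool


def combine_z(native: float, denatured: float | None) -> ZSum:
    """Summed native + denatured chip Z-score for one protein.

    When the denatured measurement is missing the native value is
    substituted for it (so z_sum = 2*native), flagged in the result.
    """
    if native is None or (isinstance(native, float) and math.isnan(native)):
        raise ValueError("native Z-score is required")
    if denatured is None or (isinstance(denatured, float) and math.isnan(denatured)):
        return ZSum(z_sum=2.0 * native, substituted=True)
    return ZSum(z_sum=native + denatured, substituted=False)


@dataclass
class PairRecord:
    """One virus antigen-human protein pair and its derived quantities.

    z_sum proxies the total binding free energy; the eTFR significance S
    proxies the conformational contribution; f is the in-register FVC
    weight (None when the overlap is too short for the window).
    """

    virus_id: str
    human_id: str
    z_sum: float
    S: float
    f: float | None = None
    M: int | None = None
    N: int | None = None
    identity_pct: float | None = None

    def __post_init__(self) -> None:
        if self.S < 0:
            raise ValueError("eTFR significance S must be >= 0")
        if self.f is not None and not 0.0 <= self.f <= 1.0:
            raise ValueError(f"weight f must lie in [0, 1], got {self.f}")

    @property
    def S_weighted(self) -> float | None:
        return None if self.f is None else self.S * self.f


def weighted_significance(record: PairRecord) -> float | None:
    """S * f; weighting never increases significance since f <= 1."""
    return record.S_weighted


@dataclass(frozen=True)
class CorrelationResult:
    n: int
    r: float
    r_squared: float
    p_two_sided: float
    slope: float
    intercept: float


XField = Literal["S", "S_weighted", "identity_pct"]


def correlate_pairs(records: Sequence[PairRecord], x_field: XField = "S",
                    y_field: str = "z_sum") -> CorrelationResult:
    """Pearson correlation of z_sum against a thermodynamic or identity axis.

    The two-sided p-value comes from the t-distribution with n-2 degrees of
    freedom; OLS slope/intercept accompany the fit.  Records whose x value
    is missing are dropped with a logged count.
    """
    xs, ys = [], []
    dropped = 0
    for rec in records:
        x = getattr(rec, x_field)
        y = getattr(rec, y_field)
        if x is None or (isinstance(x, float) and math.isnan(x)):
            dropped += 1
            continue
        xs.append(float(x))
        ys.append(float(y))
    if dropped:
        logger.warning("correlate_pairs: dropped %d record(s) with missing %s",
                       dropped, x_field)
    if len(xs) < 3:
        raise ValueError(f"need at least 3 complete records, got {len(xs)}")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    fit = stats.linregress(x, y)
    return CorrelationResult(n=len(x), r=float(fit.rvalue),
                             r_squared=float(fit.rvalue ** 2),
                             p_two_sided=float(fit.pvalue),
                             slope=float(fit.slope),
                             intercept=float(fit.intercept))


# ---------------------------------------------------------------------------
# Sequence-identity control (Smith-Waterman, BLOSUM62)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocalIdentity:
    identity_pct: float
    spanA: tuple[int, int]  # 1-based inclusive; (0, 0) when no positive path
    spanB: tuple[int, int]
    score: float
    n_columns: int


def _make_aligner(gap_open: float = 11.0, gap_extend: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_identity(seqA: ProteinSequence, seqB: ProteinSequence,
                   gap_open: float = 11.0, gap_extend: float = 1.0) -> LocalIdentity:
    """Percent identity of the optimal Smith-Waterman local alignment.

    BLOSUM62 scores with affine gaps (open 11, extend 1).  Identity is
    counted over alignment columns of the optimal local alignment span.  If
    no positive-scoring path exists the result is 0% over an empty span.
    """
    aligner = _make_aligner(gap_open, gap_extend)
    score = aligner.score(seqA.residues, seqB.residues)
    if score <= 0:
        return LocalIdentity(identity_pct=0.0, spanA=(0, 0), spanB=(0, 0),
                             score=float(score), n_columns=0)
    aln = aligner.align(seqA.residues, seqB.residues)[0]
    blocksA, blocksB = aln.aligned
    matches = 0
    columns = 0
    prev_a_end = prev_b_end = None
    for (a0, a1), (b0, b1) in zip(blocksA, blocksB):
        if prev_a_end is not None:
            columns += (a0 - prev_a_end) + (b0 - prev_b_end)  # gap columns
        seg_a = seqA.residues[a0:a1]
        seg_b = seqB.residues[b0:b1]
        matches += sum(1 for x, y in zip(seg_a, seg_b) if x == y)
        columns += a1 - a0
        prev_a_end, prev_b_end = a1, b1
    spanA = (int(blocksA[0][0]) + 1, int(blocksA[-1][1]))
    spanB = (int(blocksB[0][0]) + 1, int(blocksB[-1][1]))
    return LocalIdentity(identity_pct=100.0 * matches / columns,
                         spanA=spanA, spanB=spanB, score=float(score),
                         n_columns=columns)


# ---------------------------------------------------------------------------
# Chip and pair tables
# ---------------------------------------------------------------------------

def read_chip_table(path: str | Path) -> pd.DataFrame:
    """Chip TSV: protein_id, z_native, z_denatured (empty cell = missing).

    Adds z_sum and a `substituted` flag column via :func:`combine_z`.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"protein_id", "z_native", "z_denatured"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"chip table {path} missing columns {sorted(missing)}")
    sums, flags = [], []
    for _, row in df.iterrows():
        den = row["z_denatured"]
        res = combine_z(float(row["z_native"]),
                        None if pd.isna(den) else float(den))
        sums.append(res.z_sum)
        flags.append(res.substituted)
    df = df.copy()
    df["z_sum"] = sums
    df["substituted"] = flags
    n_sub = int(np.sum(flags))
    if n_sub:
        logger.warning("read_chip_table: native value substituted for %d "
                       "missing denatured measurement(s)", n_sub)
    return df


def read_pair_table(path: str | Path) -> list[PairRecord]:
    """Pair TSV: virus_id, human_id, z_sum, S, and optionally f, M, N."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"virus_id", "human_id", "z_sum", "S"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pair table {path} missing columns {sorted(missing)}")
    key = df[["virus_id", "human_id"]].apply(tuple, axis=1)
    if key.duplicated().any():
        dupes = sorted(set(key[key.duplicated()]))
        raise ValueError(f"duplicate pair keys in {path}: {dupes[:5]}")
    records = []
    for _, row in df.iterrows():
        f = row.get("f")
        records.append(PairRecord(
            virus_id=str(row["virus_id"]), human_id=str(row["human_id"]),
            z_sum=float(row["z_sum"]), S=float(row["S"]),
            f=None if f is None or pd.isna(f) else float(f),
            M=None if "M" not in df.columns or pd.isna(row["M"]) else int(row["M"]),
            N=None if "N" not in df.columns or pd.isna(row["N"]) else int(row["N"]),
            identity_pct=(float(row["identity_pct"])
                          if "identity_pct" in df.columns
                          and not pd.isna(row["identity_pct"]) else None)))
    return records


def write_pair_table(records: Iterable[PairRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({"virus_id": r.virus_id, "human_id": r.human_id,
                     "z_sum": r.z_sum, "S": r.S, "f": r.f, "M": r.M, "N": r.N,
                     "identity_pct": r.identity_pct})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
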