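"""Statistics for comparing distance vectors: rank/linear correlation,
Euclidean distance, and uncorrected p-distances from an alignment.

Rank correlation (Kendall's tau) is the primary comparison statistic for
distance-vs-DDH performance because some distance functions saturate more
quickly than others, breaking any assumed linear relationship; tau depends
on the ranks only and is therefore invariant under strictly monotone
transforms such as the logarithmic distance variants.  The tie-corrected
tau-b is used since DDH tables contain tied values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedVector",
    "kendall_tau",
    "pearson_r",
    "euclidean_distance",
    "p_distance_matrix",
]

_P_DISTANCE_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class PairedVector:
    """Two observations per pair, e.g. GGD vs DDH or GGD vs 16S p-distance."""

    labels: tuple[str, ...]
    a: tuple[float, ...]
    b: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.a) == len(self.b)):
            raise ValueError("labels, a and b must have equal lengths")
        if len(self.a) < 2:
            raise ValueError("need at least 2 paired observations")
        if any(np.isnan(self.a)) or any(np.isnan(self.b)):
            raise ValueError("paired vectors must not contain missing values")

    @classmethod
    def from_arrays(cls, a, b, labels=None) -> "PairedVector":
        a = tuple(float(v) for v in a)
        b = tuple(float(v) for v in b)
        if labels is None:
            labels = tuple(str(i) for i in range(len(a)))
        return cls(tuple(labels), a, b)


def _check_non_constant(x: np.ndarray, name: str) -> None:
    if np.all(x == x[0]):
        raise ValueError(f"{name} is constant: correlation undefined")


def kendall_tau(paired: PairedVector) -> float:
    """Kendall's tau-b (tie-corrected) between the paired vectors."""
    a = np.asarray(paired.a, dtype=float)
    b = np.asarray(paired.b, dtype=float)
    _check_non_constant(a, "vector a")
    _check_non_constant(b, "vector b")
    tau = stats.kendalltau(a, b, variant="b").statistic
    return float(tau)


def pearson_r(paired: PairedVector) -> float:
    """Pearson's product-moment correlation between the paired vectors."""
    a = np.asarray(paired.a, dtype=float)
    b = np.asarray(paired.b, dtype=float)
    _check_non_constant(a, "vector a")
    _check_non_constant(b, "vector b")
    return float(stats.pearsonr(a, b).statistic)


def euclidean_distance(vec_a: Sequence[float], vec_b: Sequence[float]) -> float:
    """Plain (unnormalised) Euclidean distance between two vectors."""
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def p_distance_matrix(
    aligned_sequences: Mapping[str, str] | Sequence[tuple[str, str]],
    ignore_missing: bool = True,
) -> pd.DataFrame:
    """Pairwise uncorrected p-distances from an alignment.

    ``p = mismatches / valid sites`` per pair.  With ``ignore_missing``
    (pairwise deletion), any column holding a gap, N or other ambiguity
    character in *either* sequence of the pair is excluded from both counts;
    U is read as T.  A pair with zero comparable sites is recorded as
    missing (NaN).
    """
    if isinstance(aligned_sequences, Mapping):
        items = list(aligned_sequences.items())
    else:
        items = list(aligned_sequences)
    if len(items) < 2:
        raise ValueError("need at least 2 aligned sequences")
    names = [name for name, _ in items]
    if len(names) != len(set(names)):
        raise ValueError("duplicate sequence names in alignment")
    length = len(items[0][1])
    for name, seq in items:
        if len(seq) != length:
            raise ValueError(
                f"sequence {name!r} length {len(seq)} != alignment length "
                f"{length}"
            )
    # encode: 0..3 = ACGT, -1 = missing (gap/N/ambiguity)
    code = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
    mats = np.full((len(items), length), -1, dtype=np.int8)
    for i, (_, seq) in enumerate(items):
        for j, ch in enumerate(seq.upper()):
            mats[i, j] = code.get(ch, -1)
    if not ignore_missing:
        keep = np.all(mats >= 0, axis=0)
        mats = mats[:, keep]
    n = len(items)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = (mats[i] >= 0) & (mats[j] >= 0)
            n_valid = int(valid.sum())
            if n_valid == 0:
                p = np.nan
            else:
                p = float(np.sum(mats[i][valid] != mats[j][valid])) / n_valid
            out[i, j] = out[j, i] = p
    return pd.DataFrame(out, index=names, columns=names)
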