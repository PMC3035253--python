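"""The ten GBDP genome-to-genome distance functions.

Let H_xy be the total length of all matches and I_xy the total number of
identical base pairs over all matches found by querying genome x against
genome y; H_yx and I_yx come from the opposite direction.  With λ a
normalising function of the two genome lengths (their sum, or twice the
shorter length), the three similarity families are

    family 1:  s = (H_xy + H_yx) / λ          (match coverage)
    family 2:  s = (I_xy + I_yx) / (H_xy + H_yx)   (identity fraction,
               the only family independent of genome length)
    family 3:  s = (I_xy + I_yx) / λ          (identity coverage)

and each distance is d = 1 − s, clamped to [0, 1], optionally transformed
as d' = −ln(1 − d).  Crossing the three families with the two λ variants
(families 1 and 3 only) and the optional log transform yields ten distance
functions, conventionally numbered 0–9:

    index:        0    1    2    3    4    5    6    7    8    9
    family:       1    1    1    1    2    2    3    3    3    3
    λ:           sum  2min sum  2min  —    —   sum  2min sum  2min
    log:          no   no  yes  yes   no  yes   no   no  yes  yes

Family 2 degenerates to distance 0 on exact-match-only inputs (I = H by
construction, e.g. MUMs or the internal matcher); a warning is emitted in
that case.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_io import Genome, PathOrHandle, _open_maybe
from .matchset import DirectedMatchSet

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceComponents",
    "DistanceSpec",
    "PairResult",
    "IdentityOnlyWarning",
    "compute_components",
    "ggd",
    "distance_matrix",
    "write_phylip",
    "write_long_tsv",
    "ALL_INDICES",
]

ALL_INDICES = tuple(range(10))

# index -> (family, denominator, log_transform); None denominator = family 2
_INDEX_TABLE: dict[int, tuple[int, str | None, bool]] = {
    0: (1, "sum_lengths", False),
    1: (1, "twice_min_length", False),
    2: (1, "sum_lengths", True),
    3: (1, "twice_min_length", True),
    4: (2, None, False),
    5: (2, None, True),
    6: (3, "sum_lengths", False),
    7: (3, "twice_min_length", False),
    8: (3, "sum_lengths", True),
    9: (3, "twice_min_length", True),
}

_LOG_CLAMP = 1.0 - 1e-12


class IdentityOnlyWarning(UserWarning):
    """Family 2 requested on an identity-only (I == H) match set."""


@dataclass(frozen=True)
class DistanceComponents:
    """The H/I/length sextuple a genome pair reduces to."""

    h_xy: float
    h_yx: float
    i_xy: float
    i_yx: float
    len_x: int
    len_y: int

    def __post_init__(self) -> None:
        if not (0 <= self.i_xy <= self.h_xy or self.h_xy == self.i_xy == 0):
            raise ValueError("need 0 <= I_xy <= H_xy")
        if not (0 <= self.i_yx <= self.h_yx or self.h_yx == self.i_yx == 0):
            raise ValueError("need 0 <= I_yx <= H_yx")
        if self.len_x <= 0 or self.len_y <= 0:
            raise ValueError("genome lengths must be > 0")


@dataclass(frozen=True)
class DistanceSpec:
    """One of the ten distance functions plus pipeline switches.

    ``reduction`` and ``evalue_filter`` do not enter the formula itself but
    record how the match sets are to be reduced before the components are
    summed ('trim' = greedy-with-trimming, 'coverage' = footprint union).
    """

    family: int = 3
    denominator: str = "sum_lengths"
    log_transform: bool = False
    reduction: str = "trim"
    evalue_filter: bool = False

    def __post_init__(self) -> None:
        if self.family not in (1, 2, 3):
            raise ValueError("family must be 1, 2 or 3")
        if self.denominator not in ("sum_lengths", "twice_min_length"):
            raise ValueError(
                "denominator must be 'sum_lengths' or 'twice_min_length'"
            )
        if self.reduction not in ("trim", "coverage"):
            raise ValueError("reduction must be 'trim' or 'coverage'")

    @property
    def gbdp_index(self) -> int:
        for idx, (fam, denom, log) in _INDEX_TABLE.items():
            if fam == self.family and log == self.log_transform and (
                fam == 2 or denom == self.denominator
            ):
                return idx
        raise AssertionError("unreachable: spec outside index table")

    @classmethod
    def from_index(
        cls,
        index: int,
        reduction: str = "trim",
        evalue_filter: bool = False,
    ) -> "DistanceSpec":
        if index not in _INDEX_TABLE:
            raise ValueError(f"GBDP index must be 0..9, got {index}")
        family, denominator, log = _INDEX_TABLE[index]
        return cls(
            family=family,
            denominator=denominator or "sum_lengths",
            log_transform=log,
            reduction=reduction,
            evalue_filter=evalue_filter,
        )


@dataclass(frozen=True)
class PairResult:
    spec: DistanceSpec
    distance: float
    components: DistanceComponents


def compute_components(
    set_xy_reduced,
    set_yx_reduced,
    genome_x: Genome,
    genome_y: Genome,
) -> DistanceComponents:
    """Sum reduced match sets of both directions into H/I components.

    Accepts anything exposing ``total_h()``/``total_i()`` (a
    :class:`~ggdist.trimming.TrimmedMatchSet` or a raw
    :class:`~ggdist.matchset.DirectedMatchSet`).
    """
    if (
        set_xy_reduced.query_genome_id != genome_x.genome_id
        or set_xy_reduced.subject_genome_id != genome_y.genome_id
    ):
        raise ValueError(
            "x->y match set genome ids do not match the supplied genomes"
        )
    if (
        set_yx_reduced.query_genome_id != genome_y.genome_id
        or set_yx_reduced.subject_genome_id != genome_x.genome_id
    ):
        raise ValueError(
            "y->x match set genome ids do not match the supplied genomes"
        )
    return DistanceComponents(
        h_xy=float(set_xy_reduced.total_h()),
        h_yx=float(set_yx_reduced.total_h()),
        i_xy=float(set_xy_reduced.total_i()),
        i_yx=float(set_yx_reduced.total_i()),
        len_x=genome_x.total_length,
        len_y=genome_y.total_length,
    )


def ggd(components: DistanceComponents, spec: DistanceSpec) -> PairResult:
    """Evaluate one distance function on a pair's components.

    Degenerate inputs are mapped to maximal distance: when no match exists
    in either direction (H_xy + H_yx = 0) every family returns d = 1,
    defining family 2's 0/0 as maximal distance.  Similarity ratios above 1
    (possible in raw-sum coverage mode with repeats) clamp to d = 0.
    """
    c = components
    h_sum = c.h_xy + c.h_yx
    i_sum = c.i_xy + c.i_yx
    if spec.denominator == "sum_lengths":
        lam = float(c.len_x + c.len_y)
    else:
        lam = 2.0 * min(c.len_x, c.len_y)
    if h_sum == 0:
        d = 1.0
    else:
        if spec.family == 1:
            s = h_sum / lam
        elif spec.family == 2:
            if i_sum == h_sum:
                warnings.warn(
                    "family 2 on an identity-only match set (I == H): "
                    "distance is identically 0; exact matches (MUMs) carry "
                    "no identity information for this family",
                    IdentityOnlyWarning,
                    stacklevel=2,
                )
            s = i_sum / h_sum
        else:
            s = i_sum / lam
        d = min(max(1.0 - s, 0.0), 1.0)
    if spec.log_transform:
        d = -math.log(1.0 - min(d, _LOG_CLAMP))
    return PairResult(spec=spec, distance=d, components=c)


def distance_matrix(
    genomes: Sequence[Genome],
    matchset_provider: Callable[[Genome, Genome], DirectedMatchSet],
    spec: DistanceSpec,
) -> tuple[pd.DataFrame, dict[tuple[str, str], PairResult], list[tuple[str, str, str]]]:
    """All-vs-all distances under one distance function.

    ``matchset_provider(x, y)`` must return the directed x→y match set; the
    provider is called once per direction per pair, and the resulting matrix
    is symmetric by construction.  A failing provider marks that pair as
    missing (NaN) and the run continues; failures are returned as
    ``(id_a, id_b, message)`` triples.
    """
    from .pipeline import reduce_match_set  # local import to avoid a cycle

    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    ids = [g.genome_id for g in genomes]
    if len(ids) != len(set(ids)):
        raise ValueError("genome ids must be unique")
    df = pd.DataFrame(
        np.zeros((len(ids), len(ids))), index=ids, columns=ids
    )
    results: dict[tuple[str, str], PairResult] = {}
    failures: list[tuple[str, str, str]] = []
    for a in range(len(genomes)):
        for b in range(a + 1, len(genomes)):
            gx, gy = genomes[a], genomes[b]
            try:
                set_xy = matchset_provider(gx, gy)
                set_yx = matchset_provider(gy, gx)
                red_xy = reduce_match_set(set_xy, spec)
                red_yx = reduce_match_set(set_yx, spec)
                comp = compute_components(red_xy, red_yx, gx, gy)
                res = ggd(comp, spec)
            except Exception as exc:  # noqa: BLE001 — record and continue
                logger.error(
                    "pair (%s, %s) failed: %s", gx.genome_id, gy.genome_id, exc
                )
                failures.append((gx.genome_id, gy.genome_id, str(exc)))
                df.loc[gx.genome_id, gy.genome_id] = np.nan
                df.loc[gy.genome_id, gx.genome_id] = np.nan
                continue
            results[(gx.genome_id, gy.genome_id)] = res
            df.loc[gx.genome_id, gy.genome_id] = res.distance
            df.loc[gy.genome_id, gx.genome_id] = res.distance
    return df, results, failures


def write_phylip(matrix: pd.DataFrame, target: PathOrHandle) -> None:
    """Write a square distance matrix in PHYLIP format."""
    handle, close = _open_maybe(target, "w")
    try:
        handle.write(f"{len(matrix)}\n")
        for name in matrix.index:
            row = " ".join(f"{v:.6f}" for v in matrix.loc[name])
            handle.write(f"{str(name)[:10]:<10} {row}\n")
    finally:
        if close:
            handle.close()


def write_long_tsv(
    results: dict[int, dict[tuple[str, str], PairResult]],
    target: PathOrHandle,
) -> None:
    """Long-form TSV: one row per genome pair and GBDP index."""
    rows = []
    for index in sorted(results):
        for (ga, gb), res in results[index].items():
            c = res.components
            rows.append(
                {
                    "genome_a": ga,
                    "genome_b": gb,
                    "gbdp_index": index,
                    "distance": res.distance,
                    "H_xy": c.h_xy,
                    "H_yx": c.h_yx,
                    "I_xy": c.i_xy,
                    "I_yx": c.i_yx,
                }
            )
    df = pd.DataFrame(rows)
    handle, close = _open_maybe(target, "w")
    try:
        df.to_csv(handle, sep="\t", index=False)
    finally:
        if close:
            handle.close()
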