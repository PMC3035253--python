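"""Species delineation: the distance threshold that mimics the 70% DDH cutoff.

Wet-lab DDH values at most 70% conventionally indicate that two strains
belong to different species.  Given calibration pairs carrying both a
genome-to-genome distance (GGD) and a DDH percentage, the threshold T that
best reproduces the cutoff minimises the error ratio

    (false positives + false negatives) / number of pairs,

where a false positive is a pair with distance <= T but DDH < cutoff, and a
false negative a pair with distance > T but DDH >= cutoff.  T is scanned on
an inclusive grid from the smallest to the largest observed distance with a
step of 1/1000 of the range (1001 evaluations); among equally good grid
points the smallest T is reported, which is conservative toward predicting
distinct species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import CalibrationRecord

__all__ = [
    "ThresholdScan",
    "error_ratio",
    "optimal_threshold",
    "predict_species_identity",
    "DEFAULT_DDH_CUTOFF",
    "SAME_SPECIES",
    "DIFFERENT_SPECIES",
]

DEFAULT_DDH_CUTOFF = 70.0
SAME_SPECIES = "same_species"
DIFFERENT_SPECIES = "different_species"


@dataclass(frozen=True)
class ThresholdScan:
    """Result of an error-ratio threshold scan over a calibration set."""

    optimal_t: float
    min_error_ratio: float
    grid_step: float
    errors_by_t: pd.DataFrame  # columns: T, error_ratio
    ddh_cutoff: float


def error_ratio(
    records: Sequence[CalibrationRecord],
    threshold: float,
    ddh_cutoff: float = DEFAULT_DDH_CUTOFF,
) -> float:
    """Misclassification fraction of the threshold rule at ``threshold``.

    Pairs with distance at most as large as the threshold are called
    same-species (predicted DDH >= cutoff); the boundary is inclusive.
    """
    if not records:
        raise ValueError("empty calibration record list")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    ggd = np.array([r.ggd for r in records])
    ddh = np.array([r.ddh for r in records])
    fp = int(np.sum((ggd <= threshold) & (ddh < ddh_cutoff)))
    fn = int(np.sum((ggd > threshold) & (ddh >= ddh_cutoff)))
    return (fp + fn) / len(records)


def optimal_threshold(
    records: Sequence[CalibrationRecord],
    ddh_cutoff: float = DEFAULT_DDH_CUTOFF,
    grid_steps: int = 1000,
) -> ThresholdScan:
    """Scan the observed distance range for the error-ratio-optimal T.

    The grid runs from the minimum to the maximum observed distance,
    endpoints included, in ``grid_steps`` equal steps (``grid_steps + 1``
    evaluations).  The smallest grid point attaining the minimum error
    ratio is reported.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 calibration records")
    ggd = np.array([r.ggd for r in records])
    ddh = np.array([r.ddh for r in records])
    lo, hi = float(ggd.min()), float(ggd.max())
    if lo == hi:
        raise ValueError(
            "all distances identical: threshold scan range is empty"
        )
    grid = np.linspace(lo, hi, grid_steps + 1)
    # piecewise-constant in T: count errors at every grid point (vectorised
    # over the grid x records plane)
    same = ggd[None, :] <= grid[:, None]
    fp = np.sum(same & (ddh < ddh_cutoff)[None, :], axis=1)
    fn = np.sum(~same & (ddh >= ddh_cutoff)[None, :], axis=1)
    errors = (fp + fn) / len(records)
    best = int(np.argmin(errors))  # argmin returns the first == smallest T
    return ThresholdScan(
        optimal_t=float(grid[best]),
        min_error_ratio=float(errors[best]),
        grid_step=float((hi - lo) / grid_steps),
        errors_by_t=pd.DataFrame({"T": grid, "error_ratio": errors}),
        ddh_cutoff=ddh_cutoff,
    )


def predict_species_identity(distance: float, threshold: float) -> str:
    """Call a pair same- or different-species from its distance and T.

    The boundary is inclusive: distance == T predicts DDH >= cutoff, i.e.
    same species.
    """
    return SAME_SPECIES if distance <= threshold else DIFFERENT_SPECIES
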