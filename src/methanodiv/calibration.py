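"""Cross-marker OTU-threshold calibration.

Protein-coding markers like mcrA diverge faster than 16S rRNA genes, so an
OTU similarity criterion chosen for 16S cannot be reused directly. The
calibration regresses mcrA amino-acid distances (Y) on 16S distances (X)
through the origin over paired reference taxa, then maps the 16S distance
cutoff through the fitted slope: mapped_cutoff = slope x reference_cutoff,
and the working similarity criterion is floor(100 x (1 - mapped_cutoff)).

R-squared is reported in the uncentered form (denominator sum y^2), the
standard definition for through-origin fits; the centered form can be
negative and misleading without an intercept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .distances import DistanceModel, distance_matrix
from .errors import CalibrationError
from .io import Alignment


@dataclass(frozen=True)
class PairedDistances:
    """Paired (x = 16S distance, y = mcrA distance) over the same taxon pairs."""

    x: tuple[float, ...]
    y: tuple[float, ...]
    taxon_pair_labels: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise CalibrationError("x and y must have equal length")
        if len(self.x) < 2:
            raise CalibrationError("need at least 2 paired distances")
        if any(v < 0 for v in self.x) or any(v < 0 for v in self.y):
            raise CalibrationError("distances must be >= 0")


@dataclass(frozen=True)
class CalibrationResult:
    slope: float
    r_squared_uncentered: float
    reference_cutoff: float
    mapped_cutoff: float
    similarity_criterion_pct: int
    r_squared_definition: str = "uncentered (1 - RSS / sum y^2)"


def through_origin_regression(paired: PairedDistances) -> tuple[float, float]:
    """Least-squares slope through the origin and uncentered R-squared.

    slope = sum(x y) / sum(x^2); R^2 = 1 - sum((y - b x)^2) / sum(y^2).
    """
    x = np.asarray(paired.x, dtype=float)
    y = np.asarray(paired.y, dtype=float)
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise CalibrationError("all x are zero: regressor is degenerate")
    slope = float(np.sum(x * y)) / sxx
    syy = float(np.sum(y * y))
    rss = float(np.sum((y - slope * x) ** 2))
    r2 = 1.0 - rss / syy if syy > 0 else 1.0
    return slope, r2


def map_cutoff(slope: float, reference_cutoff: float) -> CalibrationResult:
    """Map a reference-marker distance cutoff through the calibration slope."""
    if slope <= 0:
        raise CalibrationError("slope must be positive")
    if not 0 <= reference_cutoff < 1:
        raise CalibrationError("reference cutoff must lie in [0, 1)")
    mapped = slope * reference_cutoff
    if mapped >= 1:
        raise CalibrationError(
            f"mapped cutoff {mapped:.4f} >= 1 is not a valid p-distance"
        )
    criterion = math.floor(100.0 * (1.0 - mapped))
    return CalibrationResult(
        slope=slope,
        r_squared_uncentered=float("nan"),
        reference_cutoff=reference_cutoff,
        mapped_cutoff=mapped,
        similarity_criterion_pct=criterion,
    )


def paired_from_matrices(dmatrix_x, dmatrix_y) -> PairedDistances:
    """All n(n-1)/2 taxon-pair distances from two matrices over the same taxa."""
    missing = set(dmatrix_x.labels) ^ set(dmatrix_y.labels)
    if missing:
        raise CalibrationError(
            f"taxa present in only one matrix: {sorted(missing)}"
        )
    labels = list(dmatrix_x.labels)
    xs, ys, pairs = [], [], []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            xs.append(dmatrix_x.get(a, b))
            ys.append(dmatrix_y.get(a, b))
            pairs.append((a, b))
    return PairedDistances(tuple(xs), tuple(ys), tuple(pairs))


def calibrate_from_paired(
    paired: PairedDistances, reference_cutoff: float = 0.02
) -> CalibrationResult:
    slope, r2 = through_origin_regression(paired)
    result = map_cutoff(slope, reference_cutoff)
    return CalibrationResult(
        slope=result.slope,
        r_squared_uncentered=r2,
        reference_cutoff=reference_cutoff,
        mapped_cutoff=result.mapped_cutoff,
        similarity_criterion_pct=result.similarity_criterion_pct,
    )


def calibrate_from_alignments(
    ref_16s_alignment: Alignment,
    ref_mcra_alignment: Alignment,
    model: DistanceModel = DistanceModel(),
    reference_cutoff: float = 0.02,
) -> CalibrationResult:
    """Calibrate from two reference alignments over the same taxa.

    Taxa are matched by record id; distances use ``model`` for both
    markers; all pairwise taxon-pair distances enter the regression.
    """
    ids_16s, ids_mcra = set(ref_16s_alignment.ids), set(ref_mcra_alignment.ids)
    if len(ids_16s & ids_mcra) < 3:
        raise CalibrationError("need at least 3 taxa shared by both alignments")
    if ids_16s != ids_mcra:
        raise CalibrationError(
            f"taxa present in only one alignment: {sorted(ids_16s ^ ids_mcra)}"
        )
    # thresholds live on the p-distance scale; only the gap policy is taken
    # from the caller's model
    pdist = DistanceModel("p_distance", model.gap_policy)
    dm_x = distance_matrix(ref_16s_alignment, pdist)
    dm_y = distance_matrix(ref_mcra_alignment, pdist)
    return calibrate_from_paired(paired_from_matrices(dm_x, dm_y), reference_cutoff)
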