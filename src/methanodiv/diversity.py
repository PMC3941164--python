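"""Per-library diversity statistics from OTU abundance vectors.

Implements the Shannon-Wiener index H' (natural log), evenness, Good's
coverage, and the classic Chao-1 richness estimator. Evenness and coverage
each come in two conventions because published clone-library tables are
inconsistent about them:

* evenness ``formula`` = H'/ln(S)  (the textbook Pielou form),
  ``printed`` = H'/ln(N) — many tables normalize by clone count instead;
* coverage ``clones`` = (1 - F1/N) x 100  (Good's estimator),
  ``otus`` = (1 - F1/S) x 100 — the fraction of OTUs that are not
  singletons, which some tables print as "coverage".

The convention used is always recorded in the report.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import UndefinedStatisticError
from .otu import OTUTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AbundanceVector:
    """Positive clone counts per OTU for one library."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if any((not isinstance(c, (int,)) and not float(c).is_integer()) or c < 1 for c in self.counts):
            raise UndefinedStatisticError(
                "abundances must be positive integers (drop zero-count OTUs)"
            )
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))

    @property
    def N(self) -> int:
        return sum(self.counts)

    @property
    def S(self) -> int:
        return len(self.counts)

    @property
    def F1(self) -> int:
        """Number of singleton OTUs."""
        return sum(1 for c in self.counts if c == 1)

    @property
    def F2(self) -> int:
        """Number of doubleton OTUs."""
        return sum(1 for c in self.counts if c == 2)


def _as_vector(abundance) -> AbundanceVector:
    if isinstance(abundance, AbundanceVector):
        return abundance
    return AbundanceVector(tuple(abundance))


def shannon(abundance: Sequence[int] | AbundanceVector) -> float:
    """Shannon-Wiener index H' = -sum p_i ln p_i in nats."""
    v = _as_vector(abundance)
    if v.S == 0:
        raise UndefinedStatisticError("Shannon index undefined for empty vector")
    n = v.N
    return -sum((c / n) * math.log(c / n) for c in v.counts)


def evenness(abundance, convention: str = "printed") -> float:
    """Evenness E = H'/H_max.

    ``formula``: H_max = ln(S) (requires S >= 2); ``printed``: H_max = ln(N).
    """
    v = _as_vector(abundance)
    h = shannon(v)
    if convention == "formula":
        if v.S < 2:
            raise UndefinedStatisticError(
                "evenness H'/ln(S) undefined for a single OTU"
            )
        return h / math.log(v.S)
    if convention == "printed":
        if v.N < 2:
            raise UndefinedStatisticError("evenness H'/ln(N) undefined for N < 2")
        return h / math.log(v.N)
    raise ValueError(f"unknown evenness convention {convention!r}")


def good_coverage(abundance, denominator: str = "otus") -> float:
    """Coverage percentage (1 - singletons/denominator) x 100.

    ``clones``: denominator N (Good's estimator); ``otus``: denominator S.
    """
    v = _as_vector(abundance)
    if v.S == 0:
        raise UndefinedStatisticError("coverage undefined for empty vector")
    if denominator == "clones":
        return (1.0 - v.F1 / v.N) * 100.0
    if denominator == "otus":
        return (1.0 - v.F1 / v.S) * 100.0
    raise ValueError(f"unknown coverage denominator {denominator!r}")


def chao1(abundance) -> float:
    """Classic Chao-1 richness: S + F1^2/(2 F2), or S + F1(F1-1)/2 when F2=0."""
    v = _as_vector(abundance)
    if v.S == 0:
        raise UndefinedStatisticError("Chao-1 undefined for empty vector")
    if v.F2 > 0:
        return v.S + v.F1**2 / (2.0 * v.F2)
    return v.S + v.F1 * (v.F1 - 1) / 2.0


@dataclass(frozen=True)
class DiversityReport:
    """All per-library statistics, with both convention variants."""

    library: str
    N: int
    S_obs: int
    F1: int
    F2: int
    H_prime: float
    evenness_formula: float | None
    evenness_printed: float
    coverage_clones_pct: float
    coverage_otus_pct: float
    chao1: float


def diversity_report(table: OTUTable) -> list[DiversityReport]:
    """One :class:`DiversityReport` per library column of an OTU table.

    Zero-count OTUs are dropped per library before computation; libraries
    with zero clones are skipped with a logged warning.
    """
    out = []
    for lib in table.libraries:
        counts = table.abundances(lib)
        if not counts:
            logger.warning("library %r has zero clones; skipped", lib)
            continue
        v = AbundanceVector(tuple(counts))
        out.append(
            DiversityReport(
                library=lib,
                N=v.N,
                S_obs=v.S,
                F1=v.F1,
                F2=v.F2,
                H_prime=shannon(v),
                evenness_formula=(
                    evenness(v, "formula") if v.S >= 2 else None
                ),
                evenness_printed=evenness(v, "printed"),
                coverage_clones_pct=good_coverage(v, "clones"),
                coverage_otus_pct=good_coverage(v, "otus"),
                chao1=chao1(v),
            )
        )
    return out


def report_frame(reports: list[DiversityReport]) -> pd.DataFrame:
    """Render reports as a display table (H'/E to 2 dp, coverage/chao1 to 1 dp)."""
    rows = {}
    for r in reports:
        rows[r.library] = {
            "Number of clones": r.N,
            "Number of OTUs": r.S_obs,
            "Coverage (%) [otus]": round(r.coverage_otus_pct, 1),
            "Coverage (%) [clones]": round(r.coverage_clones_pct, 1),
            "Shannon-Wiener index (H')": round(r.H_prime, 2),
            "Evenness [printed H'/ln N]": round(r.evenness_printed, 2),
            "Evenness [formula H'/ln S]": (
                round(r.evenness_formula, 2) if r.evenness_formula is not None else float("nan")
            ),
            "Chao-1 species richness": round(r.chao1, 1),
        }
    return pd.DataFrame(rows)
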