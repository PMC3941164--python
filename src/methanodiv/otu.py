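"""Furthest-neighbor OTU clustering and OTU tables.

Sequences are grouped into operational taxonomic units (OTUs) by
agglomerative complete-linkage clustering: two clusters merge only when
every inter-cluster pair of sequences lies within the distance cutoff, the
strict (furthest-neighbor) OTU definition. Distances are used at full
precision. Similarity criteria map to cutoffs as cutoff = 1 - pct/100
(98% -> 0.02, 95% -> 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import cross_distance_values, percent_similarity
from .errors import ClusteringError, LibraryTagError
from .io import Alignment, DistanceMatrix


@dataclass(frozen=True)
class ClusterAssignment:
    """Result of furthest-neighbor clustering at a cutoff.

    ``otu_of`` maps each sequence id to a 1-based OTU index; indices are
    ordered by each OTU's first-seen member in matrix label order.
    ``merge_trace`` records (complete-linkage distance, members_a,
    members_b) for every merge performed.
    """

    cutoff: float
    otu_of: dict[str, int]
    merge_trace: tuple[tuple[float, tuple[str, ...], tuple[str, ...]], ...]

    @property
    def n_otus(self) -> int:
        return len(set(self.otu_of.values())) if self.otu_of else 0

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sid, k in self.otu_of.items():
            out.setdefault(k, []).append(sid)
        return out


def cluster_furthest_neighbor(dmatrix: DistanceMatrix, cutoff: float) -> ClusterAssignment:
    """Complete-linkage clustering stopping at the distance cutoff.

    Merges proceed in non-decreasing complete-linkage distance and stop
    when the smallest feasible merge exceeds ``cutoff``. Ties are broken
    by the lexicographically smallest (min member id, max member id) of
    the merged pair's union, making the trace deterministic.
    """
    if cutoff < 0:
        raise ClusteringError("cutoff must be >= 0")
    n = len(dmatrix)
    if n == 0:
        return ClusterAssignment(cutoff, {}, ())
    values = dmatrix.values
    if np.isnan(values).any():
        raise ClusteringError("distance matrix contains NaN")

    clusters: list[list[int]] = [[i] for i in range(n)]
    # complete-linkage distances between current clusters
    link = values.copy()
    trace: list[tuple[float, tuple[str, ...], tuple[str, ...]]] = []

    def pair_key(a: int, b: int) -> tuple[str, str]:
        ids = [dmatrix.labels[i] for i in clusters[a] + clusters[b]]
        return (min(ids), max(ids))

    while len(clusters) > 1:
        m = len(clusters)
        tri = np.triu_indices(m, k=1)
        dists = link[tri]
        best = dists.min()
        if best > cutoff:
            break
        cand = [
            (tri[0][k], tri[1][k])
            for k in np.flatnonzero(dists == best)
        ]
        a, b = min(cand, key=lambda ab: pair_key(*ab))
        trace.append(
            (
                float(best),
                tuple(dmatrix.labels[i] for i in clusters[a]),
                tuple(dmatrix.labels[i] for i in clusters[b]),
            )
        )
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
        merged = np.maximum(link[a], link[b])
        link[a, :] = merged
        link[:, a] = merged
        link = np.delete(np.delete(link, b, axis=0), b, axis=1)
        link[a - (1 if b < a else 0), a - (1 if b < a else 0)] = 0.0

    # 1-based OTU indices ordered by first-seen member in label order
    first_seen = sorted(clusters, key=lambda c: min(c))
    otu_of: dict[str, int] = {}
    for k, members in enumerate(first_seen, start=1):
        for i in members:
            otu_of[dmatrix.labels[i]] = k
    return ClusterAssignment(cutoff, otu_of, tuple(trace))


def similarity_cutoff(percent: float) -> float:
    """Distance cutoff corresponding to a percent-similarity criterion."""
    if not 0 <= percent <= 100:
        raise ClusteringError("similarity percent must be in [0, 100]")
    return 1.0 - percent / 100.0


@dataclass(frozen=True)
class OTUTable:
    """Clone counts per OTU per library, rows sorted by descending total."""

    libraries: tuple[str, ...]
    rows: tuple[tuple[int, tuple[int, ...]], ...]  # (otu_index, counts)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {lib: [c[j] for _, c in self.rows] for j, lib in enumerate(self.libraries)},
            index=[f"OTU{k}" for k, _ in self.rows],
        )
        df.index.name = "OTU"
        df["total"] = df.sum(axis=1)
        return df

    def abundances(self, library: str) -> list[int]:
        """Nonzero clone counts for one library (zero-count OTUs dropped)."""
        j = self.libraries.index(library)
        return [c[j] for _, c in self.rows if c[j] > 0]

    @classmethod
    def from_counts(cls, counts: dict[str, dict[str, int]]) -> "OTUTable":
        """Build from {library: {otu_name: count}} keeping OTU name order."""
        libraries = tuple(counts)
        otus: list[str] = []
        for lib in counts:
            for name in counts[lib]:
                if name not in otus:
                    otus.append(name)
        rows = []
        for k, name in enumerate(otus, start=1):
            rows.append((k, tuple(counts[lib].get(name, 0) for lib in libraries)))
        rows.sort(key=lambda r: (-sum(r[1]), r[0]))
        return cls(libraries, tuple(rows))


def otu_table(assignment: ClusterAssignment, alignment: Alignment) -> OTUTable:
    """Cross-tabulate clones per OTU per library from an assignment."""
    lib_of = alignment.library_of()
    for sid in assignment.otu_of:
        if sid not in lib_of:
            raise LibraryTagError(f"id {sid!r} has no library tag in the alignment")
    libraries = tuple(alignment.libraries)
    counts: dict[int, list[int]] = {}
    for sid, k in assignment.otu_of.items():
        counts.setdefault(k, [0] * len(libraries))[
            libraries.index(lib_of[sid])
        ] += 1
    rows = sorted(
        ((k, tuple(c)) for k, c in counts.items()),
        key=lambda r: (-sum(r[1]), r[0]),
    )
    return OTUTable(libraries, tuple(rows))


def nearest_reference(
    query_alignment: Alignment, reference_alignment: Alignment, model=None
) -> list[tuple[str, str, float]]:
    """Closest reference for each query as (query_id, reference_id, %similarity).

    Queries and references must share alignment coordinates. Ties are
    broken by reference input order; similarity is reported on the
    p-distance scale regardless of ``model`` (corrections would leave the
    argmin unchanged but break the percent scale).
    """
    gap_policy = getattr(model, "gap_policy", "pairwise_delete")
    dist = cross_distance_values(query_alignment, reference_alignment, gap_policy)
    out = []
    for i, qid in enumerate(query_alignment.ids):
        j = int(np.argmin(dist[i]))  # argmin takes the first minimum: input order
        out.append(
            (qid, reference_alignment.ids[j], percent_similarity(float(dist[i, j])))
        )
    return out
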