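"""Pairwise evolutionary distances from an alignment.

Distances are uncorrected p-distances by default — the scale on which
percent-similarity OTU criteria (98% for 16S rRNA genes, 95% for mcrA
amino acids) are defined — with optional Jukes-Cantor (DNA) and Poisson
(protein) corrections. Sites containing a gap or an ambiguity code (N for
DNA, X for protein) in either sequence are excluded pairwise by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import IncomparablePairError, ModelError, SaturationError
from .io import AMBIGUOUS, Alignment, DistanceMatrix

DNA_MODELS = ("p_distance", "jc69")
PROTEIN_MODELS = ("p_distance", "poisson_corrected")


@dataclass(frozen=True)
class DistanceModel:
    """A substitution-distance model plus its gap policy.

    ``jc69`` is valid for DNA only, ``poisson_corrected`` for protein only;
    ``p_distance`` applies to both. ``gap_policy`` is ``pairwise_delete``
    (default: drop sites that are gap/ambiguous in either member of a pair)
    or ``complete_delete`` (drop alignment columns containing any
    gap/ambiguous character before all comparisons).
    """

    name: str = "p_distance"
    gap_policy: str = "pairwise_delete"

    def __post_init__(self) -> None:
        if self.name not in ("p_distance", "jc69", "poisson_corrected"):
            raise ModelError(f"unknown distance model {self.name!r}")
        if self.gap_policy not in ("pairwise_delete", "complete_delete"):
            raise ModelError(f"unknown gap policy {self.gap_policy!r}")

    def check_alphabet(self, alphabet: str) -> None:
        valid = DNA_MODELS if alphabet == "dna" else PROTEIN_MODELS
        if self.name not in valid:
            raise ModelError(
                f"model {self.name!r} is not valid for {alphabet} sequences"
            )


def _correct(p: float, model: DistanceModel, pair: tuple[str, str]) -> float:
    if model.name == "p_distance":
        return p
    if model.name == "jc69":
        if p >= 0.75:
            raise SaturationError(
                f"pair {pair}: p-distance {p:.4f} >= 3/4 saturates JC69"
            )
        return -0.75 * np.log1p(-(4.0 / 3.0) * p)
    # poisson_corrected
    if p >= 1.0:
        raise SaturationError(
            f"pair {pair}: p-distance {p:.4f} saturates the Poisson correction"
        )
    return -np.log1p(-p)


def _comparable_mask(seq: str, alphabet: str) -> np.ndarray:
    ambiguous = AMBIGUOUS[alphabet]
    return np.fromiter(
        (c not in ambiguous for c in seq), dtype=bool, count=len(seq)
    )


def pairwise_distance(
    seq_a: str,
    seq_b: str,
    model: DistanceModel = DistanceModel(),
    alphabet: str = "dna",
    ids: tuple[str, str] = ("a", "b"),
) -> float:
    """Distance between two aligned sequences under ``model``.

    Raises :class:`IncomparablePairError` when no site is comparable and
    :class:`SaturationError` when p exceeds a correction's domain.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal aligned length")
    a = np.frombuffer(seq_a.encode(), dtype="S1")
    b = np.frombuffer(seq_b.encode(), dtype="S1")
    mask = _comparable_mask(seq_a, alphabet) & _comparable_mask(seq_b, alphabet)
    n_comp = int(mask.sum())
    if n_comp == 0:
        raise IncomparablePairError(
            f"pair {ids}: no comparable sites after gap policy"
        )
    p = float(np.sum(a[mask] != b[mask])) / n_comp
    return _correct(p, model, ids)


def _encode(alignment: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Alignment as byte matrix plus per-site comparability mask."""
    seqs = np.array(
        [np.frombuffer(r.sequence.encode(), dtype="S1") for r in alignment.records]
    )
    ambiguous = AMBIGUOUS[alignment.alphabet]
    bad = np.zeros(seqs.shape, dtype=bool)
    for ch in ambiguous:
        bad |= seqs == ch.encode()
    return seqs, ~bad


def p_distance_matrix_values(alignment: Alignment, gap_policy: str = "pairwise_delete") -> np.ndarray:
    """Raw p-distance matrix as an array (vectorized over all pairs)."""
    seqs, ok = _encode(alignment)
    if gap_policy == "complete_delete":
        keep = ok.all(axis=0)
        if not keep.any():
            raise IncomparablePairError(
                "no columns survive complete deletion"
            )
        seqs, ok = seqs[:, keep], ok[:, keep]
    n = len(alignment)
    values = np.zeros((n, n))
    # chunked broadcast keeps memory bounded for large alignments
    for i in range(n):
        diff = (seqs[i][None, :] != seqs[i + 1:]) & ok[i][None, :] & ok[i + 1:]
        comp = (ok[i][None, :] & ok[i + 1:]).sum(axis=1)
        if np.any(comp == 0):
            j = i + 1 + int(np.argmax(comp == 0))
            raise IncomparablePairError(
                f"pair ({alignment.ids[i]!r}, {alignment.ids[j]!r}): "
                "no comparable sites"
            )
        values[i, i + 1:] = diff.sum(axis=1) / comp
    return values + values.T


def distance_matrix(alignment: Alignment, model: DistanceModel = DistanceModel()) -> DistanceMatrix:
    """Full pairwise :class:`DistanceMatrix` over the alignment's records."""
    model.check_alphabet(alignment.alphabet)
    values = p_distance_matrix_values(alignment, model.gap_policy)
    if model.name != "p_distance":
        n = len(alignment)
        out = np.zeros_like(values)
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = _correct(
                    values[i, j], model, (alignment.ids[i], alignment.ids[j])
                )
        values = out
    return DistanceMatrix(tuple(alignment.ids), values)


def cross_distance_values(
    queries: Alignment, references: Alignment, gap_policy: str = "pairwise_delete"
) -> np.ndarray:
    """p-distances of every query (rows) against every reference (columns)."""
    if queries.alphabet != references.alphabet:
        raise ModelError("query and reference alphabets differ")
    if queries.length != references.length:
        raise ValueError("queries and references must share alignment coordinates")
    qs, qok = _encode(queries)
    rs, rok = _encode(references)
    if gap_policy == "complete_delete":
        keep = qok.all(axis=0) & rok.all(axis=0)
        qs, qok = qs[:, keep], qok[:, keep]
        rs, rok = rs[:, keep], rok[:, keep]
    out = np.zeros((len(queries), len(references)))
    for i in range(len(queries)):
        both = qok[i][None, :] & rok
        comp = both.sum(axis=1)
        if np.any(comp == 0):
            j = int(np.argmax(comp == 0))
            raise IncomparablePairError(
                f"pair ({queries.ids[i]!r}, {references.ids[j]!r}): "
                "no comparable sites"
            )
        out[i] = ((qs[i][None, :] != rs) & both).sum(axis=1) / comp
    return out


def percent_similarity(distance: float) -> float:
    """Map a p-distance in [0, 1] to percent similarity in [0, 100]."""
    if not 0.0 <= distance <= 1.0:
        raise ModelError(
            f"distance {distance} outside [0, 1]: percent similarity is "
            "defined on the p-distance scale, not on corrected distances"
        )
    return (1.0 - distance) * 100.0
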