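"""Readers and writers for the external formats the pipeline touches.

All other modules consume and produce the domain types defined here:
:class:`Alignment` (equal-length, library-tagged sequences) and
:class:`DistanceMatrix` (symmetric pairwise distances). File formats are
aligned FASTA (DNA or protein), phylip-style square and lower-triangle
distance matrices, TSV OTU tables, and Newick trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentLengthError,
    AlphabetError,
    AsymmetryError,
    DuplicateRecordError,
    LibraryTagError,
    MatrixParseError,
)

DNA_CHARS = frozenset("ACGTN-")
# 20 residues plus ambiguity X and the gap character
PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYX-")

#: characters treated as "not comparable" under pairwise deletion
AMBIGUOUS = {"dna": frozenset("N-"), "protein": frozenset("X-")}


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned sequence with its clone-library tag."""

    id: str
    library: str
    sequence: str


@dataclass(frozen=True)
class Alignment:
    """An immutable multiple alignment of library-tagged sequences.

    Invariants (checked on construction): all sequences share one length,
    ids are unique, every record carries a non-empty library tag, and all
    characters belong to the declared alphabet.
    """

    records: tuple[AlignmentRecord, ...]
    alphabet: str  # "dna" | "protein"

    def __post_init__(self) -> None:
        if self.alphabet not in ("dna", "protein"):
            raise AlphabetError(f"unknown alphabet {self.alphabet!r}")
        allowed = DNA_CHARS if self.alphabet == "dna" else PROTEIN_CHARS
        seen: set[str] = set()
        length = None
        for rec in self.records:
            if rec.id in seen:
                raise DuplicateRecordError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
            if not rec.library:
                raise LibraryTagError(f"record {rec.id!r} has no library tag")
            if length is None:
                length = len(rec.sequence)
                if length < 1:
                    raise AlignmentLengthError(f"record {rec.id!r} is empty")
            elif len(rec.sequence) != length:
                raise AlignmentLengthError(
                    f"record {rec.id!r} has length {len(rec.sequence)}, "
                    f"expected {length}"
                )
            bad = set(rec.sequence) - allowed
            if bad:
                raise AlphabetError(
                    f"record {rec.id!r} contains characters {sorted(bad)} "
                    f"outside the {self.alphabet} alphabet"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.records[0].sequence) if self.records else 0

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def libraries(self) -> list[str]:
        """Library names in order of first appearance."""
        out: list[str] = []
        for r in self.records:
            if r.library not in out:
                out.append(r.library)
        return out

    def library_of(self) -> dict[str, str]:
        return {r.id: r.library for r in self.records}

    def subset(self, ids: Sequence[str]) -> "Alignment":
        wanted = {r.id: r for r in self.records}
        return Alignment(tuple(wanted[i] for i in ids), self.alphabet)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with a deterministic label order."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise MatrixParseError(
                f"matrix shape {v.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise DuplicateRecordError("distance-matrix labels are not unique")
        if n and np.isnan(v).any():
            raise MatrixParseError("matrix contains NaN distances")
        if n and not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise MatrixParseError("diagonal is not zero")
        if n and np.any(v < 0):
            raise MatrixParseError("negative distances")
        if n and not np.allclose(v, v.T, atol=1e-8):
            raise AsymmetryError("matrix is asymmetric beyond 1e-8")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])


LibraryRule = Callable[[str], str] | Mapping[str, str] | None


def prefix_library_rule(record_id: str) -> str:
    """Default tagging rule: the id's text before the first underscore."""
    return record_id.split("_", 1)[0]


def _resolve_library(record_id: str, rule: LibraryRule) -> str:
    if rule is None:
        rule = prefix_library_rule
    if callable(rule):
        lib = rule(record_id)
    else:
        try:
            lib = rule[record_id]
        except KeyError:
            raise LibraryTagError(
                f"id {record_id!r} missing from the library map"
            ) from None
    if not lib:
        raise LibraryTagError(f"library rule gave empty tag for {record_id!r}")
    return lib


def read_aligned_fasta(path, alphabet: str, library_rule: LibraryRule = None) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Characters are upper-cased and ``.`` gaps normalized to ``-``. The
    library tag of each record comes from ``library_rule``: a callable
    ``id -> library``, an explicit ``id -> library`` mapping, or ``None``
    for the default prefix-before-underscore rule.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(".", "-")
        records.append(
            AlignmentRecord(rec.id, _resolve_library(rec.id, library_rule), seq)
        )
    return Alignment(tuple(records), alphabet)


def write_aligned_fasta(alignment: Alignment, path) -> None:
    recs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="")
        for r in alignment.records
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_library_map(path) -> dict[str, str]:
    """Read a two-column (id, library) TSV into a mapping."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise LibraryTagError(f"bad library-map line: {line!r}")
            out[parts[0]] = parts[1]
    return out


def read_distance_matrix(path, dialect: str = "square") -> DistanceMatrix:
    """Read a phylip-style distance matrix (``square`` or ``lower_triangle``).

    The first line holds the taxon count; each following row is a label
    followed by whitespace-separated values. Lower-triangle input is
    mirrored to full symmetric form.
    """
    if dialect not in ("square", "lower_triangle"):
        raise MatrixParseError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    if not lines:
        raise MatrixParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise MatrixParseError(f"{path}: first line must be the taxon count")
    rows = lines[1:]
    if len(rows) != n:
        raise MatrixParseError(
            f"{path}: expected {n} rows, found {len(rows)}"
        )
    labels: list[str] = []
    values = np.zeros((n, n))
    for i, row in enumerate(rows):
        parts = row.split()
        labels.append(parts[0])
        vals = [float(x) for x in parts[1:]]
        expected = n if dialect == "square" else i
        if len(vals) != expected:
            raise MatrixParseError(
                f"{path}: row {parts[0]!r} has {len(vals)} values, "
                f"expected {expected}"
            )
        if dialect == "square":
            values[i, :] = vals
        else:
            values[i, :i] = vals
            values[:i, i] = vals
    if dialect == "square":
        if not np.allclose(values, values.T, atol=1e-8):
            raise AsymmetryError(f"{path}: matrix asymmetric beyond 1e-8")
        values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(tuple(labels), values)


def write_distance_matrix(dmatrix: DistanceMatrix, path, dialect: str = "square") -> None:
    """Write a phylip-style matrix with 6 decimal places (bit-stable diffs)."""
    n = len(dmatrix)
    with open(path, "w") as fh:
        fh.write(f"{n}\n")
        for i, label in enumerate(dmatrix.labels):
            stop = n if dialect == "square" else i
            vals = " ".join(f"{dmatrix.values[i, j]:.6f}" for j in range(stop))
            fh.write(f"{label} {vals}".rstrip() + "\n")


def write_otu_table(table, path) -> None:
    """Write an OTU-by-library count table as TSV with a total column."""
    df = table.to_frame()
    try:
        df.to_csv(path, sep="\t")
    except OSError as exc:
        raise OSError(f"cannot write OTU table to {path}: {exc}") from exc


def write_newick(tree, path) -> None:
    """Serialize a tree to a Newick file (one line, ';'-terminated)."""
    try:
        with open(path, "w") as fh:
            fh.write(tree.to_newick() + "\n")
    except OSError as exc:
        raise OSError(f"cannot write tree to {path}: {exc}") from exc
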