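"""Synthetic clone libraries with planted structure.

Real clone libraries from this kind of survey have one dominant OTU
(roughly 58-74% of clones), a sub-dominant OTU, and a tail of singletons
and doubletons. The generators here produce alignments with exactly that
shape while keeping the ground truth analytically controlled: per-OTU
ancestor sequences are rejection-sampled to a minimum pairwise divergence,
and clones are copies of their ancestor mutated at up to
floor(intra * L / 2) distinct sites, so every intra-OTU p-distance is
bounded by ``intra_otu_divergence`` by construction. Mutations are i.i.d.
per site, uniform over the other characters; there are no indels, so
alignments stay gap-free and planted p-distances are exact.

Every generator is fully deterministic given its seed and emits its truth
(id -> planted OTU) alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .calibration import PairedDistances
from .diversity import AbundanceVector
from .errors import SpecError
from .io import Alignment, AlignmentRecord

DNA_BASES = "ACGT"
RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

_MAX_ANCESTOR_ATTEMPTS = 200


@dataclass(frozen=True)
class CommunitySpec:
    """The planted community a synthetic library is drawn from."""

    S_true: int = 8
    abundance_model: str = "geometric"  # "geometric" | "explicit"
    dominance: float = 0.6  # geometric theta; dominant share ~ theta
    explicit_counts: Optional[tuple[int, ...]] = None
    intra_otu_divergence: float = 0.005
    inter_otu_divergence: float = 0.20
    sequence_length: int = 1254
    alphabet: str = "dna"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.abundance_model not in ("geometric", "explicit"):
            raise SpecError(f"unknown abundance model {self.abundance_model!r}")
        if self.abundance_model == "explicit" and not self.explicit_counts:
            raise SpecError("explicit abundance model needs explicit_counts")
        if not 0 <= self.intra_otu_divergence < 1:
            raise SpecError("intra_otu_divergence must be in [0, 1)")
        if not 0 <= self.inter_otu_divergence < 1:
            raise SpecError("inter_otu_divergence must be in [0, 1)")
        if self.abundance_model == "geometric" and not 0 < self.dominance < 1:
            raise SpecError("geometric dominance must be in (0, 1)")
        if self.S_true < 1 or self.sequence_length < 1:
            raise SpecError("S_true and sequence_length must be positive")


@dataclass(frozen=True)
class SyntheticLibrary:
    """A generated alignment plus its planted OTU membership."""

    alignment: Alignment
    truth: dict[str, int] = field(hash=False)
    spec: CommunitySpec


def _alphabet_chars(alphabet: str) -> str:
    return DNA_BASES if alphabet == "dna" else RESIDUES


def sample_abundances(
    spec: CommunitySpec, n_clones: int, rng: Optional[np.random.Generator] = None
) -> AbundanceVector:
    """Clone counts per OTU under the spec's abundance model.

    Geometric mode draws one multinomial with weights proportional to
    theta (1 - theta)^(k-1); OTUs that receive zero clones are dropped
    (they were simply not sampled). Explicit mode returns the given
    counts verbatim.
    """
    if spec.abundance_model == "explicit":
        counts = tuple(spec.explicit_counts)
        if sum(counts) != n_clones:
            raise SpecError(
                f"explicit counts sum to {sum(counts)}, expected {n_clones}"
            )
        return AbundanceVector(counts)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    draw = _raw_abundances(spec, n_clones, rng)
    return AbundanceVector(tuple(int(c) for c in draw if c > 0))


def _raw_abundances(spec: CommunitySpec, n_clones: int, rng: np.random.Generator) -> np.ndarray:
    """Multinomial counts over all S_true categories, zeros kept.

    Keeping zero categories preserves the alignment between count indices
    and ancestor indices, which makes two libraries drawn from one
    community genuinely exchangeable (each clone i.i.d. over the pool).
    """
    theta = spec.dominance
    weights = theta * (1 - theta) ** np.arange(spec.S_true)
    weights /= weights.sum()
    return rng.multinomial(n_clones, weights)


def _sample_ancestors(
    spec: CommunitySpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n ancestor sequences with min pairwise p-distance >= inter bound."""
    chars = _alphabet_chars(spec.alphabet)
    k = len(chars)
    L = spec.sequence_length
    for _ in range(_MAX_ANCESTOR_ATTEMPTS):
        seqs = rng.integers(0, k, size=(n, L))
        ok = True
        for i in range(n):
            for j in range(i + 1, n):
                if np.mean(seqs[i] != seqs[j]) < spec.inter_otu_divergence:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return seqs
    raise SpecError(
        f"could not plant {n} ancestors at divergence >= "
        f"{spec.inter_otu_divergence} with length {L}"
    )


def _mutate(seq: np.ndarray, n_sites: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Copy of seq with n_sites distinct positions changed to another char."""
    out = seq.copy()
    if n_sites == 0:
        return out
    sites = rng.choice(len(seq), size=n_sites, replace=False)
    shift = rng.integers(1, k, size=n_sites)  # never the same character
    out[sites] = (out[sites] + shift) % k
    return out


def _clones_from_ancestors(
    spec: CommunitySpec,
    ancestors: np.ndarray,
    counts,
    library_name: str,
    rng: np.random.Generator,
    ancestor_offset: int = 0,
) -> SyntheticLibrary:
    """Clones per ancestor; ``counts`` may contain zeros (OTUs not sampled)."""
    chars = _alphabet_chars(spec.alphabet)
    k = len(chars)
    L = spec.sequence_length
    max_mut = int(np.floor(spec.intra_otu_divergence * L / 2.0))
    records = []
    truth: dict[str, int] = {}
    clone_no = 0
    for otu_idx, count in enumerate(counts):
        anc = ancestors[otu_idx]
        for _ in range(count):
            clone_no += 1
            n_mut = int(rng.integers(0, max_mut + 1))
            seq = _mutate(anc, n_mut, k, rng)
            cid = f"{library_name}_c{clone_no:03d}"
            records.append(
                AlignmentRecord(
                    cid, library_name, "".join(chars[c] for c in seq)
                )
            )
            truth[cid] = ancestor_offset + otu_idx + 1
    alignment = Alignment(tuple(records), spec.alphabet)
    return SyntheticLibrary(alignment, truth, spec)


def generate_library(
    spec: CommunitySpec,
    n_clones: int = 50,
    library_name: str = "lib",
    seed: Optional[int] = None,
) -> SyntheticLibrary:
    """One clone library with planted OTU structure.

    Guarantees by construction: every intra-OTU clone pair differs at
    <= intra_otu_divergence of sites; clones of different OTUs differ at
    >= inter_otu_divergence - intra_otu_divergence of sites.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if spec.abundance_model == "explicit":
        counts = list(sample_abundances(spec, n_clones, rng).counts)
    else:
        counts = list(_raw_abundances(spec, n_clones, rng))
    ancestors = _sample_ancestors(spec, len(counts), rng)
    return _clones_from_ancestors(spec, ancestors, counts, library_name, rng)


def generate_paired_markers(
    n_taxa: int = 23,
    slope: float = 2.1944,
    noise_sd: float = 0.05,
    seed: int = 0,
    x_range: tuple[float, float] = (0.01, 0.35),
) -> PairedDistances:
    """Paired marker distances with planted proportionality y = slope * x.

    Emulates a calibration input: one x (16S-like distance) per taxon
    pair, uniform on ``x_range``, with y = slope * x + Normal(0, noise_sd)
    truncated at zero.
    """
    if slope <= 0:
        raise SpecError("slope must be positive")
    if noise_sd < 0:
        raise SpecError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n_pairs = n_taxa * (n_taxa - 1) // 2
    x = rng.uniform(x_range[0], x_range[1], size=n_pairs)
    y = np.maximum(slope * x + rng.normal(0.0, noise_sd, size=n_pairs), 0.0)
    labels = tuple(
        (f"t{i}", f"t{j}")
        for i in range(n_taxa)
        for j in range(i + 1, n_taxa)
    )
    return PairedDistances(tuple(x), tuple(y), labels)


def generate_library_pair(
    spec_x: CommunitySpec,
    spec_y: Optional[CommunitySpec] = None,
    n_each: int = 50,
    shared: bool = True,
    seed: int = 0,
    names: tuple[str, str] = ("horse", "pony"),
) -> tuple[SyntheticLibrary, SyntheticLibrary]:
    """Two libraries for a LIBSHUFF experiment.

    ``shared=True`` draws both from one community (the null hypothesis of
    the test); ``shared=False`` uses disjoint ancestor pools so the
    dominant OTUs differ (the alternative).
    """
    if spec_y is None:
        spec_y = spec_x
    rng = np.random.default_rng(seed)
    # zeros are kept so count index i always means ancestor i: with a shared
    # pool the pooled clones are then i.i.d. draws from one community, the
    # exchangeability the LIBSHUFF null requires
    counts_x = _raw_abundances(spec_x, n_each, rng)
    counts_y = _raw_abundances(spec_y, n_each, rng)
    if shared:
        ancestors = _sample_ancestors(spec_x, spec_x.S_true, rng)
        lib_x = _clones_from_ancestors(spec_x, ancestors, counts_x, names[0], rng)
        lib_y = _clones_from_ancestors(spec_x, ancestors, counts_y, names[1], rng)
    else:
        # one pool, disjoint halves: cross-pool divergence holds for every
        # ancestor pair, so the two communities share no OTU
        s_x, s_y = spec_x.S_true, spec_y.S_true
        ancestors = _sample_ancestors(spec_x, s_x + s_y, rng)
        lib_x = _clones_from_ancestors(
            spec_x, ancestors[:s_x], counts_x, names[0], rng
        )
        lib_y = _clones_from_ancestors(
            spec_y, ancestors[s_x:], counts_y, names[1], rng,
            ancestor_offset=s_x,
        )
    return lib_x, lib_y


def write_truth(library: SyntheticLibrary, path) -> None:
    """Write the planted id -> OTU membership as a two-column TSV."""
    with open(path, "w") as fh:
        fh.write("id\totu\n")
        for cid, otu in library.truth.items():
            fh.write(f"{cid}\t{otu}\n")
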