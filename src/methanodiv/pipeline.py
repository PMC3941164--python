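"""End-to-end orchestration: distances -> OTUs -> diversity -> LIBSHUFF -> tree.

``run_analysis`` executes the stages in fixed order on one aligned FASTA,
writes every artifact into the output directory, and records a manifest
(JSON) naming the inputs, seed, conventions and artifact paths, so that a
run is reproducible from its manifest alone. Identical config and inputs
give identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .calibration import calibrate_from_alignments
from .distances import DistanceModel, distance_matrix
from .diversity import diversity_report, report_frame
from .errors import MethanodivError
from .io import (
    read_aligned_fasta,
    write_distance_matrix,
    write_newick,
    write_otu_table,
)
from .libshuff import libshuff_test
from .otu import cluster_furthest_neighbor, otu_table
from .phylogeny import bootstrap_support, neighbor_joining

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a run needs; exactly one cutoff source must be set."""

    input_fasta: str
    outdir: str
    marker: str = "16s"  # "16s" | "mcra"
    alphabet: str = "dna"
    cutoff: Optional[float] = 0.02
    calibration_16s: Optional[str] = None  # reference alignments for cutoff
    calibration_mcra: Optional[str] = None
    reference_cutoff: float = 0.02
    model: str = "p_distance"
    gap_policy: str = "pairwise_delete"
    libshuff_permutations: int = 999
    libshuff_alpha: float = 0.05
    libshuff_step: float = 0.01
    bootstrap_replicates: int = 100
    evenness_convention: str = "printed"
    coverage_convention: str = "otus"
    seed: int = 0

    def __post_init__(self) -> None:
        has_fixed = self.cutoff is not None
        has_cal = self.calibration_16s is not None or self.calibration_mcra is not None
        if has_fixed == has_cal:
            raise MethanodivError(
                "exactly one cutoff source required: a fixed cutoff or "
                "calibration alignments"
            )
        if has_cal and (self.calibration_16s is None or self.calibration_mcra is None):
            raise MethanodivError(
                "calibration needs both 16S and mcrA reference alignments"
            )


def run_analysis(config: RunConfig) -> dict:
    """Run all stages and return the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "conventions": {
            "evenness": config.evenness_convention,
            "coverage": config.coverage_convention,
            "clustering": "furthest_neighbor, full-precision distances, "
            "lexicographic tie-break",
            "libshuff_grid_step": config.libshuff_step,
            "libshuff_statistic": "sum (C_X - C_XY)^2 * step",
        },
        "artifacts": {},
    }

    def emit(name: str, path: Path) -> None:
        written.append(path)
        manifest["artifacts"][name] = str(path)

    stage = "read"
    try:
        alignment = read_aligned_fasta(config.input_fasta, config.alphabet)

        stage = "cutoff"
        if config.cutoff is not None:
            cutoff = config.cutoff
        else:
            cal = calibrate_from_alignments(
                read_aligned_fasta(config.calibration_16s, "dna"),
                read_aligned_fasta(config.calibration_mcra, "protein"),
                DistanceModel("p_distance", config.gap_policy),
                config.reference_cutoff,
            )
            cutoff = cal.mapped_cutoff
            manifest["calibration"] = dataclasses.asdict(cal)
        manifest["cutoff"] = cutoff

        stage = "distances"
        model = DistanceModel(config.model, config.gap_policy)
        dmat = distance_matrix(alignment, model)
        path = outdir / "distances.phylip"
        write_distance_matrix(dmat, path)
        emit("distance_matrix", path)

        stage = "cluster"
        assignment = cluster_furthest_neighbor(dmat, cutoff)
        table = otu_table(assignment, alignment)
        path = outdir / "otu_table.tsv"
        write_otu_table(table, path)
        emit("otu_table", path)

        stage = "diversity"
        reports = diversity_report(table)
        path = outdir / "diversity.tsv"
        report_frame(reports).to_csv(path, sep="\t")
        emit("diversity_report", path)

        stage = "libshuff"
        libraries = alignment.libraries
        if len(libraries) >= 2:
            if len(libraries) > 2:
                logger.warning(
                    "LIBSHUFF compares 2 libraries; using %s", libraries[:2]
                )
            keep = [
                r.id for r in alignment.records if r.library in libraries[:2]
            ]
            result = libshuff_test(
                dmat.submatrix(keep),
                {i: l for i, l in alignment.library_of().items() if i in set(keep)},
                n_permutations=config.libshuff_permutations,
                seed=config.seed,
                alpha=config.libshuff_alpha,
                step=config.libshuff_step,
            )
            path = outdir / "libshuff.json"
            path.write_text(json.dumps(dataclasses.asdict(result), indent=2))
            emit("libshuff", path)
        else:
            logger.warning("only one library present; LIBSHUFF stage skipped")

        stage = "tree"
        if len(alignment) >= 3:
            if config.bootstrap_replicates > 0:
                tree = bootstrap_support(
                    alignment, model, config.bootstrap_replicates, config.seed
                )
                manifest["bootstrap"] = {
                    "replicates": tree.bootstrap_replicates,
                    "skipped": tree.bootstrap_skipped,
                }
            else:
                tree = neighbor_joining(dmat)
            path = outdir / "tree.nwk"
            write_newick(tree, path)
            emit("tree", path)

        stage = "manifest"
        path = outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise MethanodivError(f"stage {stage!r} failed: {exc}") from exc
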