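"""LIBSHUFF comparison of the simulated library pairs.

Runs the two-library permutation test (999 label permutations, grid step
0.01) on the null pair (same community: expect non-significant) and on
the alternative pair (disjoint communities: expect P below the corrected
threshold in both directions). Writes results/libshuff_{null,alt}.json.
"""

import dataclasses
import json
from pathlib import Path

from methanodiv.distances import distance_matrix
from methanodiv.io import read_aligned_fasta
from methanodiv.libshuff import libshuff_test

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 42


def main() -> None:
    for tag in ("null", "alt"):
        aln = read_aligned_fasta(ROOT / "synthetic" / f"{tag}_pair.fasta", "dna")
        dm = distance_matrix(aln)
        result = libshuff_test(
            dm, aln.library_of(), n_permutations=999, seed=SEED, alpha=0.05
        )
        (ROOT / f"libshuff_{tag}.json").write_text(
            json.dumps(dataclasses.asdict(result), indent=2)
        )
        verdict = "significant" if result.significant else "not significant"
        print(
            f"{tag} pair: dC_XY={result.delta_c_xy:.6f} (p={result.p_xy:.4f}), "
            f"dC_YX={result.delta_c_yx:.6f} (p={result.p_yx:.4f}) -> {verdict} "
            f"at corrected alpha {result.pairwise_alpha:.4f}"
        )
    print(
        "note: a single null pair is flagged with probability ~alpha by "
        "construction; the type-I rate itself is checked over 1000 "
        "simulations in the test suite"
    )


if __name__ == "__main__":
    main()
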