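"""Published clone counts from the horse/pony methanogen clone-library survey.

Per-OTU clone counts for the two markers (mcrA deduced amino acids and
archaeal 16S rRNA genes) in the horse and pony fecal libraries, 50 clones
each. These tables are the canonical inputs for the diversity statistics
and serve as regression anchors for the pipeline.
"""

from __future__ import annotations

from .otu import OTUTable

#: mcrA amino-acid libraries: clones per OTU (horse, pony); 9 OTUs total.
MCRA_COUNTS: dict[str, dict[str, int]] = {
    "horse": {
        "OTU1": 29, "OTU2": 10, "OTU3": 6, "OTU4": 1, "OTU5": 0,
        "OTU6": 1, "OTU7": 1, "OTU8": 1, "OTU9": 1,
    },
    "pony": {
        "OTU1": 33, "OTU2": 13, "OTU3": 0, "OTU4": 1, "OTU5": 2,
        "OTU6": 0, "OTU7": 1, "OTU8": 0, "OTU9": 0,
    },
}

#: archaeal 16S rRNA libraries: clones per OTU (horse, pony); 10 OTUs total.
SSU_COUNTS: dict[str, dict[str, int]] = {
    "horse": {
        "OTU1": 32, "OTU2": 4, "OTU3": 0, "OTU4": 1, "OTU5": 6,
        "OTU6": 2, "OTU7": 0, "OTU8": 1, "OTU9": 2, "OTU10": 2,
    },
    "pony": {
        "OTU1": 37, "OTU2": 1, "OTU3": 1, "OTU4": 5, "OTU5": 0,
        "OTU6": 2, "OTU7": 1, "OTU8": 3, "OTU9": 0, "OTU10": 0,
    },
}


def clone_counts(marker: str) -> OTUTable:
    """The published OTU table for ``marker`` ("mcra" or "16s")."""
    if marker == "mcra":
        return OTUTable.from_counts(MCRA_COUNTS)
    if marker == "16s":
        return OTUTable.from_counts(SSU_COUNTS)
    raise ValueError(f"unknown marker {marker!r}")
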