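"""Default genome model: 22 autosomes with human-like lengths.

Sex chromosomes are deliberately excluded — the het-SNP AF-centred-at-0.5
assumption underlying the GI score fails on the male X.  Lengths are
approximate GRCh38 autosome sizes in base pairs; any mapping
``{chrom: length}`` can be substituted through the simulation config.
"""

from __future__ import annotations

AUTOSOME_LENGTHS: dict[str, int] = {
    "chr1": 248_000_000,
    "chr2": 242_000_000,
    "chr3": 198_000_000,
    "chr4": 190_000_000,
    "chr5": 182_000_000,
    "chr6": 171_000_000,
    "chr7": 159_000_000,
    "chr8": 145_000_000,
    "chr9": 138_000_000,
    "chr10": 134_000_000,
    "chr11": 135_000_000,
    "chr12": 133_000_000,
    "chr13": 114_000_000,
    "chr14": 107_000_000,
    "chr15": 102_000_000,
    "chr16": 90_000_000,
    "chr17": 83_000_000,
    "chr18": 80_000_000,
    "chr19": 59_000_000,
    "chr20": 64_000_000,
    "chr21": 47_000_000,
    "chr22": 51_000_000,
}

SEX_CHROMS = ("chrX", "chrY", "X", "Y")


def is_autosome(chrom: str) -> bool:
    return chrom not in SEX_CHROMS


def default_genome(scale: float = 1.0) -> dict[str, int]:
    """Autosome length map, optionally scaled down for desk-size runs."""
    if scale <= 0:
        raise ValueError("genome scale must be > 0")
    return {c: max(1, int(round(n * scale))) for c, n in AUTOSOME_LENGTHS.items()}
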