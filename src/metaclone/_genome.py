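"""Reference genome coordinate frame used throughout the package.

A desk-scale hg19-like frame: 22 autosomes plus chrX with approximate
megabase lengths. Internal coordinates are 0-based half-open; on-disk
formats (VCF, SEG) are 1-based inclusive. chrY and the mitochondrial
genome are outside the analysed frame (profiles run 1pter-Xqter).
"""

from __future__ import annotations

MB = 1_000_000

#: Approximate chromosome lengths in bp (hg19, rounded to 1 Mb).
CHROM_LENGTHS: dict[str, int] = {
    "chr1": 249 * MB,
    "chr2": 243 * MB,
    "chr3": 198 * MB,
    "chr4": 191 * MB,
    "chr5": 181 * MB,
    "chr6": 171 * MB,
    "chr7": 159 * MB,
    "chr8": 146 * MB,
    "chr9": 141 * MB,
    "chr10": 136 * MB,
    "chr11": 135 * MB,
    "chr12": 134 * MB,
    "chr13": 115 * MB,
    "chr14": 107 * MB,
    "chr15": 102 * MB,
    "chr16": 90 * MB,
    "chr17": 81 * MB,
    "chr18": 78 * MB,
    "chr19": 59 * MB,
    "chr20": 63 * MB,
    "chr21": 48 * MB,
    "chr22": 51 * MB,
    "chrX": 155 * MB,
}

CHROMOSOMES: tuple[str, ...] = tuple(CHROM_LENGTHS)
AUTOSOMES: tuple[str, ...] = tuple(c for c in CHROMOSOMES if c != "chrX")

_ORDER = {c: i for i, c in enumerate(CHROMOSOMES)}


def normalize_chrom(name: str) -> str:
    """Normalise a chromosome name to the 'chr'-prefixed convention."""
    name = str(name).strip()
    if not name.lower().startswith("chr"):
        name = "chr" + name
    body = name[3:]
    if body.upper() == "X":
        body = "X"
    return "chr" + body


def chrom_sort_key(name: str) -> tuple[int, str]:
    """Total order over chromosome names: chr1..chr22, chrX, then others."""
    name = normalize_chrom(name)
    return (_ORDER.get(name, len(_ORDER)), name)


def genome_length(chromosomes=CHROMOSOMES) -> int:
    return sum(CHROM_LENGTHS[c] for c in chromosomes)
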