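"""Reference genome coordinate tables (hg19).

Chromosome lengths and centromeric intervals are used by the positional
mutation filters: calls in the telomeric tails (a configurable fraction of
chromosome length) or inside centromeric gaps sit in regions where copy
number estimation is unreliable, so their CCFs are not trusted.

Coordinates are 1-based inclusive throughout the package. Centromere
intervals are the canonical UCSC hg19 gap-track windows (+/- 3 Mb around
the centromeric gap).
"""

from __future__ import annotations

HG19_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 249_250_621,
    "chr2": 243_199_373,
    "chr3": 198_022_430,
    "chr4": 191_154_276,
    "chr5": 180_915_260,
    "chr6": 171_115_067,
    "chr7": 159_138_663,
    "chr8": 146_364_022,
    "chr9": 141_213_431,
    "chr10": 135_534_747,
    "chr11": 135_006_516,
    "chr12": 133_851_895,
    "chr13": 115_169_878,
    "chr14": 107_349_540,
    "chr15": 102_531_392,
    "chr16": 90_354_753,
    "chr17": 81_195_210,
    "chr18": 78_077_248,
    "chr19": 59_128_983,
    "chr20": 63_025_520,
    "chr21": 48_129_895,
    "chr22": 51_304_566,
    "chrX": 155_270_560,
    "chrY": 59_373_566,
}

HG19_CENTROMERES: dict[str, tuple[int, int]] = {
    "chr1": (121_535_434, 124_535_434),
    "chr2": (92_326_171, 95_326_171),
    "chr3": (90_504_854, 93_504_854),
    "chr4": (49_660_117, 52_660_117),
    "chr5": (46_405_641, 49_405_641),
    "chr6": (58_830_166, 61_830_166),
    "chr7": (58_054_331, 61_054_331),
    "chr8": (43_838_887, 46_838_887),
    "chr9": (47_367_679, 50_367_679),
    "chr10": (39_254_935, 42_254_935),
    "chr11": (51_644_205, 54_644_205),
    "chr12": (34_856_694, 37_856_694),
    "chr13": (16_000_000, 19_000_000),
    "chr14": (16_000_000, 19_000_000),
    "chr15": (17_000_000, 20_000_000),
    "chr16": (35_335_801, 38_335_801),
    "chr17": (22_263_006, 25_263_006),
    "chr18": (15_460_898, 18_460_898),
    "chr19": (24_681_782, 27_681_782),
    "chr20": (26_369_569, 29_369_569),
    "chr21": (11_288_129, 14_288_129),
    "chr22": (13_000_000, 16_000_000),
    "chrX": (58_632_012, 61_632_012),
    "chrY": (10_104_553, 13_104_553),
}

AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))


def normalize_chrom(chrom: str) -> str:
    """Map '1'/'chr1' style names onto the package's 'chr1' convention."""
    c = str(chrom)
    return c if c.startswith("chr") else f"chr{c}"
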