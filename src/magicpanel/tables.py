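"""Published characterization of the GenoBaits Peanut 40K panel.

These small tables are inputs, not results: the per-chromosome variant
counts of the released panel (with the Tifrunner v1 chromosome lengths),
the chip-vs-resequencing concordance of the eight MAGIC founder lines,
and the pod-size association hits reported for the S2 population. They
feed the density report, the concordance arithmetic, the region builder,
and the default chromosome sizes of the synthetic-data generator.
"""

from __future__ import annotations

# Eight founder lines of the peanut MAGIC population: accession id -> funnel letter.
FOUNDER_LETTERS = {
    "N730": "A",  # Yuanza9102
    "N709": "B",  # Zhonghua6
    "N734": "C",  # Yuhua15
    "N743": "D",  # Weihua8
    "N745": "E",  # Yueyou20
    "N744": "F",  # Fuhuasheng
    "N741": "G",  # Silihong
    "N739": "H",  # NC94022
}

#: The single 8-way cross the genotyped S2 lines descend from.
S2_SOURCE_CROSS = "A/E//D/G///B/C//F/H"

#: Per-chromosome panel content: chromosome -> (length bp, panel variants).
#: Chromosome names are the short Arahy.NN forms of the Tifrunner v1 assembly.
PANEL_CHROMOSOMES: dict[str, tuple[int, int]] = {
    "Arahy.01": (112_420_854, 2_009),
    "Arahy.02": (102_981_163, 1_804),
    "Arahy.03": (143_813_506, 2_570),
    "Arahy.04": (128_801_742, 1_730),
    "Arahy.05": (115_930_344, 1_933),
    "Arahy.06": (115_504_342, 1_779),
    "Arahy.07": (81_119_488, 1_763),
    "Arahy.08": (51_897_010, 1_070),
    "Arahy.09": (120_519_698, 2_463),
    "Arahy.10": (117_088_237, 1_828),
    "Arahy.11": (149_299_306, 2_788),
    "Arahy.12": (120_579_088, 1_534),
    "Arahy.13": (146_725_006, 2_614),
    "Arahy.14": (143_237_272, 3_029),
    "Arahy.15": (160_879_708, 2_543),
    "Arahy.16": (154_808_347, 1_662),
    "Arahy.17": (134_922_436, 2_249),
    "Arahy.18": (135_150_084, 1_453),
    "Arahy.19": (158_625_764, 1_441),
    "Arahy.20": (143_980_330, 1_738),
}

#: Published per-chromosome marker density (bp per variant) of the 40K panel.
PANEL_RATES: dict[str, int] = {
    "Arahy.01": 55_958,
    "Arahy.02": 57_084,
    "Arahy.03": 55_958,
    "Arahy.04": 74_451,
    "Arahy.05": 59_974,
    "Arahy.06": 64_926,
    "Arahy.07": 46_012,
    "Arahy.08": 48_501,
    "Arahy.09": 48_932,
    "Arahy.10": 64_052,
    "Arahy.11": 53_550,
    "Arahy.12": 78_604,
    "Arahy.13": 56_130,
    "Arahy.14": 47_288,
    "Arahy.15": 63_263,
    "Arahy.16": 93_145,
    "Arahy.17": 59_992,
    "Arahy.18": 93_014,
    "Arahy.19": 110_080,
    "Arahy.20": 82_842,
}

PANEL_TOTAL_LENGTH = 2_538_283_725
PANEL_TOTAL_VARIANTS = 40_000
PANEL_TOTAL_RATE = 63_457

#: Founder-line chip-vs-whole-genome-resequencing comparison over the 40,000
#: panel sites: accession -> (hom diff, het diff, indel diff, missing,
#: consistent, printed accuracy %).
FOUNDER_CONCORDANCE: dict[str, tuple[int, int, int, int, int, float]] = {
    "N709": (23, 61, 3, 586, 39_327, 98.32),
    "N730": (11, 39, 2, 574, 39_374, 98.44),
    "N734": (19, 42, 2, 205, 39_732, 99.33),
    "N739": (663, 4_825, 0, 1_232, 33_280, 83.20),
    "N741": (49, 199, 2, 6_076, 33_674, 84.19),
    "N743": (23, 34, 1, 217, 39_725, 99.31),
    "N744": (18, 39, 1, 1_315, 38_627, 96.57),
    "N745": (28, 70, 1, 582, 39_319, 98.30),
}

#: Pod-size GWAS hits in the S2 population (multi-trait significant SNPs):
#: (chromosome, position bp, -log10 p, |additive effect|, sign, traits).
GWAS_HITS: list[tuple[str, int, float, float, str, tuple[str, ...]]] = [
    ("Arahy.07", 130_688, 6.27, 10.61, "-", ("area", "perimeter", "width")),
    ("Arahy.07", 292_285, 6.27, 10.70, "+", ("area", "perimeter", "width")),
    ("Arahy.07", 492_470, 5.72, 7.97, "+", ("area", "width")),
    ("Arahy.07", 586_747, 5.91, 10.80, "+", ("area", "perimeter", "width")),
    ("Arahy.07", 811_108, 5.63, 9.89, "+", ("area", "perimeter", "width")),
    ("Arahy.07", 848_538, 6.75, 9.76, "-", ("area", "width")),
    ("Arahy.07", 890_383, 5.55, 8.87, "-", ("area", "perimeter", "width")),
    ("Arahy.07", 920_314, 5.74, 9.24, "-", ("area", "perimeter", "width")),
    ("Arahy.07", 1_008_387, 6.30, 8.40, "+", ("area", "width")),
    ("Arahy.07", 1_056_718, 5.61, 9.12, "+", ("area", "perimeter", "width")),
    ("Arahy.12", 7_302_293, 5.57, 6.65, "+", ("perimeter", "length", "width")),
    ("Arahy.12", 7_423_728, 5.57, 6.65, "-", ("perimeter", "length", "width")),
    ("Arahy.12", 7_926_457, 5.51, 6.53, "-", ("perimeter", "length", "width")),
    ("Arahy.12", 7_964_822, 5.70, 6.48, "-", ("perimeter", "length", "width")),
    ("Arahy.12", 8_555_800, 5.58, 6.83, "+", ("area", "perimeter", "length", "width")),
    ("Arahy.12", 8_695_703, 5.83, 7.26, "-", ("area", "perimeter", "length", "width")),
    ("Arahy.12", 8_746_767, 6.01, 6.89, "+", ("perimeter", "length", "width")),
    ("Arahy.12", 8_817_149, 5.95, 6.70, "-", ("perimeter", "length", "width")),
    ("Arahy.12", 8_913_786, 5.88, 6.97, "+", ("perimeter", "length", "width")),
    ("Arahy.12", 9_170_907, 5.86, 7.09, "-", ("perimeter", "length", "width")),
    ("Arahy.12", 9_387_102, 5.57, 7.28, "-", ("area", "perimeter", "length", "width")),
    ("Arahy.12", 9_486_492, 5.78, 7.58, "+", ("area", "perimeter", "length", "width")),
    ("Arahy.12", 9_610_185, 5.86, 7.53, "-", ("area", "perimeter", "length", "width")),
    ("Arahy.12", 9_723_588, 5.86, 6.45, "-", ("perimeter", "width")),
    ("Arahy.12", 9_837_499, 5.86, 6.45, "-", ("perimeter", "width")),
    ("Arahy.12", 9_911_046, 5.86, 6.45, "-", ("perimeter", "width")),
    ("Arahy.17", 625_720, 6.10, 10.61, "+", ("area", "perimeter", "width")),
]


def chrom_lengths(scale: float = 1.0) -> dict[str, int]:
    """Panel chromosome lengths, optionally scaled down (e.g. 1/50 demo scale)."""
    return {c: max(1, int(round(length * scale)))
            for c, (length, _) in PANEL_CHROMOSOMES.items()}
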