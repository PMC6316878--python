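"""Published reference values used as fixed test inputs and expectations.

``VALIDATION_GENOTYPE_COUNTS``: per-variant genotype counts (common hom,
het, rare hom) observed in the 805-sample validation cohort, with the
published two-decimal MAF.  ``GENOMIC_CLASS_COUNTS`` / ``EXONIC_CLASS_COUNTS``:
published per-class variant counts of the 18,245-variant discovery set.
"""

# rs id -> (n0, n1, n2, published MAF)
VALIDATION_GENOTYPE_COUNTS = {
    "rs1043657": (660, 136, 6, 0.09),
    "rs10485828": (521, 252, 27, 0.19),
    "rs10501320": (428, 318, 51, 0.26),
    "rs1058378": (666, 134, 2, 0.09),
    "rs10868138": (681, 108, 8, 0.08),
    "rs11983326": (409, 332, 59, 0.28),
    "rs12312266": (462, 290, 44, 0.24),
    "rs12460651": (683, 111, 8, 0.08),
    "rs1555403": (432, 318, 48, 0.26),
    "rs1695": (366, 355, 76, 0.32),
    "rs17376848": (724, 76, 2, 0.05),
    "rs1801160": (729, 74, 0, 0.05),
    "rs1801466": (678, 117, 4, 0.08),
    "rs1934969": (281, 387, 135, 0.41),
    "rs2013782": (312, 389, 97, 0.37),
    "rs2032583": (639, 158, 6, 0.10),
    "rs2070677": (626, 164, 9, 0.11),
    "rs2072671": (360, 366, 66, 0.31),
    "rs2075061": (301, 383, 119, 0.39),
    "rs210134": (398, 335, 62, 0.29),
    "rs212091": (598, 186, 14, 0.13),
    "rs2180314": (251, 409, 141, 0.43),
    "rs2227291": (499, 262, 37, 0.21),
    "rs2273487": (227, 405, 161, 0.46),
    "rs2288587": (735, 59, 3, 0.04),
    "rs2293194": (229, 373, 198, 0.48),
    "rs2297595": (617, 169, 16, 0.13),
    "rs2307240": (699, 72, 1, 0.05),
    "rs2515641": (627, 166, 9, 0.11),
    "rs2612083": (332, 370, 101, 0.36),
    "rs2669429": (246, 421, 135, 0.43),
    "rs2816948": (619, 165, 11, 0.12),
    "rs28371725": (672, 112, 11, 0.08),
    "rs2856585": (719, 80, 2, 0.05),
    "rs3214587": (636, 159, 7, 0.11),
    "rs34288910": (597, 186, 19, 0.14),
    "rs3743527": (476, 278, 46, 0.23),
    "rs3803304": (407, 317, 64, 0.28),
    "rs3834939": (366, 360, 77, 0.32),
    "rs3856806": (592, 181, 26, 0.15),
    "rs3957357": (260, 412, 124, 0.41),
    "rs4148301": (644, 147, 10, 0.10),
    "rs4148413": (499, 236, 43, 0.21),
    "rs4149259": (569, 212, 22, 0.16),
    "rs4376673": (694, 106, 1, 0.07),
    "rs4658": (506, 266, 26, 0.20),
    "rs4986938": (329, 367, 103, 0.36),
    "rs61750765": (575, 208, 17, 0.15),
    "rs628031": (302, 372, 122, 0.39),
    "rs751141": (652, 137, 9, 0.10),
    "rs7543016": (240, 409, 143, 0.44),
    "rs762803": (289, 402, 108, 0.39),
    "rs76336259": (714, 87, 0, 0.05),
    "rs922483": (429, 304, 61, 0.27),
    "rs9626814": (627, 163, 9, 0.11),
}

# published responder / non-responder counts per genotype group
RESPONSE_TABLE_RS2293194 = [[42, 9], [66, 17], [19, 17]]   # p printed as 0.003
RESPONSE_TABLE_RS2227291 = [[88, 16], [29, 24], [9, 2]]    # p printed as <0.001

GENOMIC_CLASS_COUNTS = {
    "downstream": 353,
    "exonic": 3256,
    "intergenic": 372,
    "intronic": 9458,
    "splicing": 40,
    "upstream": 414,
    "UTR3": 3106,
    "UTR5": 766,
    "other": 480,
}
TOTAL_VARIANTS = 18245  # == sum of GENOMIC_CLASS_COUNTS

EXONIC_CLASS_COUNTS = {
    "frameshift deletion": 24,
    "frameshift insertion": 22,
    "non-frameshift deletion": 17,
    "non-frameshift insertion": 8,
    "non-synonymous SNV": 1646,
    "stopgain": 40,
    "stoploss": 2,
    "synonymous SNV": 1455,
    "unknown": 42,
}

N_MAF_ABOVE_005 = 7539   # of TOTAL_VARIANTS; published share 41%
N_NOVEL = 2565           # no dbSNP rs id; published share 14%
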