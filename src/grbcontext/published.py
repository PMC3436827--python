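"""Published worked examples: per-species retention triplets.

These are the printed (a, b, c) retention triplets for the top
UCNE-enriched human genes and for the top 25 UCNE clusters across the
five post-duplication fish genomes (Fugu, medaka, stickleback,
Tetraodon, zebrafish), together with the classification tallies printed
alongside them.  They serve as exact fixtures for the winner /
concordant / reciprocal rule: the triplets are inputs, the tallies the
expected outputs.

``consistent=False`` marks the two cluster rows whose printed tallies
cannot be reproduced from their own printed triplets under the stated
strict-inequality rule (documented errata); their triplets are kept for
completeness but excluded from exact-match checks.
"""
from __future__ import annotations

from dataclasses import dataclass, field

SPECIES = ("fugu", "medaka", "stickleback", "tetraodon", "zebrafish")


@dataclass(frozen=True)
class PublishedRow:
    name: str
    n_ucnes: int
    # species -> (a, b, c); species without two orthologs (or without
    # retained UCNEs) are absent
    triplets: dict[str, tuple[int, int, int]]
    # printed tally, e.g. {"winner": 4, "concordant": 1}
    printed: dict[str, int] = field(default_factory=dict)
    consistent: bool = True


def _row(name, n, triplets, printed, consistent=True):
    return PublishedRow(name, n, dict(triplets), dict(printed), consistent)


TOP_GENES: list[PublishedRow] = [
    _row("NPAS3", 53, {"fugu": (6, 0, 0), "tetraodon": (1, 0, 1)},
         {"winner": 1, "reciprocal": 1}),
    _row("DACH1", 39, {"fugu": (22, 1, 0), "medaka": (21, 2, 0),
                       "stickleback": (16, 3, 0), "tetraodon": (20, 1, 0),
                       "zebrafish": (18, 6, 0)},
         {"winner": 4, "concordant": 1}),
    _row("FOXP2", 38, {"fugu": (29, 2, 0), "tetraodon": (27, 1, 1)},
         {"winner": 2}),
    _row("EBF3", 38, {"medaka": (27, 1, 0), "stickleback": (24, 4, 1),
                      "tetraodon": (28, 0, 0), "zebrafish": (31, 0, 0)},
         {"winner": 4}),
    _row("FOXP1", 38, {"fugu": (25, 0, 0), "medaka": (19, 0, 0),
                       "stickleback": (22, 0, 0), "tetraodon": (24, 0, 0),
                       "zebrafish": (24, 0, 0)},
         {"winner": 5}),
    _row("AUTS2", 34, {"zebrafish": (15, 4, 0)}, {"concordant": 1}),
    _row("ZEB2", 27, {"fugu": (22, 0, 0), "medaka": (15, 0, 0),
                      "stickleback": (6, 1, 2), "tetraodon": (19, 0, 0),
                      "zebrafish": (8, 5, 2)},
         {"winner": 3, "reciprocal": 1, "concordant": 1}),
    _row("ZFPM2", 25, {"zebrafish": (14, 7, 0)}, {"concordant": 1}),
    _row("SOX6", 22, {"fugu": (14, 0, 0), "medaka": (13, 2, 0),
                      "stickleback": (14, 1, 0), "tetraodon": (12, 0, 0)},
         {"winner": 4}),
    _row("ESRRG", 22, {"fugu": (7, 0, 0), "medaka": (7, 0, 0),
                       "stickleback": (8, 0, 0), "tetraodon": (5, 0, 0),
                       "zebrafish": (17, 0, 0)},
         {"winner": 5}),
    _row("EBF1", 21, {"fugu": (2, 1, 2), "medaka": (4, 0, 2),
                      "stickleback": (3, 2, 0), "tetraodon": (3, 1, 0),
                      "zebrafish": (5, 5, 0)},
         {"reciprocal": 2, "concordant": 3}),
    _row("PBX3", 21, {"zebrafish": (16, 2, 0)}, {"winner": 1}),
    _row("MEIS2", 18, {"medaka": (15, 0, 0), "stickleback": (13, 3, 0),
                       "tetraodon": (14, 1, 0), "zebrafish": (7, 3, 0)},
         {"winner": 3, "concordant": 1}),
    _row("OLA1", 16, {"fugu": (14, 0, 0), "medaka": (13, 1, 0),
                      "stickleback": (14, 0, 0), "tetraodon": (11, 0, 0)},
         {"winner": 4}),
    _row("EHBP1", 15, {"fugu": (9, 0, 0), "tetraodon": (7, 0, 0)},
         {"winner": 2}),
    _row("DACH2", 12, {"zebrafish": (9, 0, 0)}, {"winner": 1}),
    _row("MEIS1", 12, {"fugu": (8, 0, 0), "zebrafish": (9, 0, 0)},
         {"winner": 2}),
    _row("NBEA", 12, {"fugu": (8, 0, 1), "medaka": (8, 0, 1),
                      "stickleback": (8, 0, 1), "tetraodon": (7, 0, 0),
                      "zebrafish": (5, 0, 0)},
         {"winner": 5}),
    _row("POLA1", 12, {"tetraodon": (5, 0, 0)}, {"winner": 1}),
    _row("SATB1", 10, {"fugu": (5, 0, 0), "medaka": (11, 0, 0),
                       "stickleback": (7, 0, 0), "tetraodon": (5, 0, 0),
                       "zebrafish": (7, 0, 0)},
         {"winner": 5}),
]


TOP_CLUSTERS: list[PublishedRow] = [
    _row("ZEB2", 134, {"fugu": (67, 0, 0), "medaka": (47, 0, 0),
                       "stickleback": (36, 1, 3), "tetraodon": (56, 0, 0),
                       "zebrafish": (24, 6, 15)},
         {"winner": 4, "reciprocal": 1}),
    _row("CCNE1/TSHZ3/ZNF507/ZNF536", 96,
         {"fugu": (37, 11, 4), "medaka": (31, 11, 4),
          "stickleback": (39, 15, 3), "tetraodon": (13, 8, 18),
          "zebrafish": (59, 4, 0)},
         {"winner": 1, "concordant": 3, "reciprocal": 1}),
    _row("EBF3/GLRX3/MGMT", 96, {"fugu": (48, 0, 0), "medaka": (48, 0, 0),
                                 "stickleback": (45, 2, 0),
                                 "tetraodon": (48, 0, 0),
                                 "zebrafish": (34, 2, 26)},
         {"winner": 4, "reciprocal": 1}),
    _row("BCL11A", 92, {"fugu": (19, 6, 1), "medaka": (24, 7, 0),
                        "stickleback": (23, 6, 1), "tetraodon": (18, 4, 1),
                        "zebrafish": (47, 3, 0)},
         {"winner": 1, "concordant": 4}),
    _row("FOXP2/MDFIC/TFEC", 83, {"fugu": (57, 1, 0), "medaka": (42, 0, 0),
                                  "stickleback": (59, 0, 0),
                                  "tetraodon": (53, 0, 1),
                                  "zebrafish": (43, 0, 24)},
         {"winner": 4, "reciprocal": 1}),
    _row("HNF4G/PEX2/ZFHX4", 79, {"fugu": (36, 0, 0), "medaka": (35, 0, 0),
                                  "stickleback": (37, 0, 0),
                                  "tetraodon": (30, 0, 0),
                                  "zebrafish": (58, 0, 0)},
         {"winner": 5}),
    _row("DACH1/MZT1", 73, {"fugu": (35, 1, 0), "medaka": (32, 1, 0),
                            "stickleback": (29, 1, 0), "tetraodon": (34, 1, 0),
                            "zebrafish": (29, 6, 0)},
         {"winner": 5}),
    _row("ESRRG/USH2A", 72, {"fugu": (18, 0, 0), "medaka": (19, 0, 0),
                             "stickleback": (22, 1, 1), "tetraodon": (10, 0, 0),
                             "zebrafish": (49, 0, 1)},
         {"winner": 5}),
    _row("AKAP6/NPAS3", 71, {"fugu": (7, 0, 2), "medaka": (9, 0, 0),
                             "stickleback": (1, 0, 0), "tetraodon": (6, 0, 0),
                             "zebrafish": (39, 0, 0)},
         {"winner": 4, "reciprocal": 1}),
    _row("ATPBD4/MEIS2", 67, {"fugu": (51, 0, 0), "medaka": (46, 2, 0),
                              "stickleback": (46, 4, 1),
                              "tetraodon": (41, 0, 0),
                              "zebrafish": (25, 3, 0)},
         {"winner": 5}),
    _row("ANKRD32/NR2F1", 67, {"fugu": (36, 0, 0), "medaka": (34, 0, 0),
                               "stickleback": (39, 0, 0),
                               "tetraodon": (32, 0, 0),
                               "zebrafish": (40, 0, 0)},
         {"winner": 5}),
    _row("AKTIP/IRX3-5-6", 60, {"fugu": (34, 3, 0), "medaka": (37, 0, 0),
                                "stickleback": (41, 0, 0),
                                "tetraodon": (22, 0, 8),
                                "zebrafish": (34, 3, 0)},
         {"winner": 4, "reciprocal": 1}),
    _row("ADK/KAT6B/ZNF503", 60, {"fugu": (15, 22, 8), "medaka": (17, 20, 6),
                                  "stickleback": (16, 22, 8),
                                  "tetraodon": (16, 22, 4),
                                  "zebrafish": (40, 0, 4)},
         {"winner": 1, "concordant": 2, "reciprocal": 2},
         consistent=False),
    _row("TSHZ1", 59, {"fugu": (12, 12, 6), "medaka": (14, 11, 2),
                       "stickleback": (11, 11, 6), "tetraodon": (9, 8, 12),
                       "zebrafish": (28, 0, 0)},
         {"winner": 1, "concordant": 1, "reciprocal": 3},
         consistent=False),
    _row("MCTP2/NR2F2", 57, {"fugu": (23, 0, 2), "medaka": (23, 1, 0),
                             "stickleback": (26, 1, 0), "tetraodon": (24, 0, 0),
                             "zebrafish": (35, 0, 0)},
         {"winner": 5}),
    _row("FOXP1/MITF", 49, {"fugu": (30, 0, 0), "medaka": (23, 0, 0),
                            "stickleback": (28, 0, 0), "tetraodon": (30, 0, 0),
                            "zebrafish": (30, 0, 0)},
         {"winner": 5}),
    _row("C1D/MEIS1/SPRED2", 45, {"fugu": (22, 0, 0), "medaka": (14, 0, 0),
                                  "tetraodon": (21, 0, 0),
                                  "zebrafish": (25, 0, 0)},
         {"winner": 4}),
    _row("MRPS9/POU3F3", 44, {"fugu": (9, 0, 0), "medaka": (17, 1, 0),
                              "stickleback": (2, 0, 2), "tetraodon": (3, 0, 0),
                              "zebrafish": (23, 1, 0)},
         {"winner": 4, "reciprocal": 1}),
    _row("FIGN/GRB14/KCNH7", 44, {"fugu": (8, 13, 3), "medaka": (10, 9, 4),
                                  "stickleback": (13, 10, 3),
                                  "tetraodon": (10, 11, 3),
                                  "zebrafish": (17, 2, 0)},
         {"winner": 1, "concordant": 4}),
    _row("BNC2/CNTLN", 43, {"fugu": (24, 0, 0), "medaka": (26, 0, 0),
                            "stickleback": (25, 0, 0), "tetraodon": (24, 0, 0),
                            "zebrafish": (17, 0, 0)},
         {"winner": 5}),
    _row("FBXL4/POU3F2", 42, {"fugu": (8, 1, 0), "medaka": (8, 0, 0),
                              "stickleback": (8, 1, 0), "tetraodon": (7, 1, 0),
                              "zebrafish": (9, 0, 0)},
         {"winner": 5}),
    _row("FAM125B/GAPVD1/PBX3", 42, {"fugu": (32, 0, 0), "medaka": (34, 0, 0),
                                     "stickleback": (35, 0, 0),
                                     "tetraodon": (30, 0, 0),
                                     "zebrafish": (27, 1, 3)},
         {"winner": 5}),
    _row("C8orf83/RUNX1T1", 41, {"fugu": (13, 0, 0), "medaka": (11, 0, 0),
                                 "stickleback": (12, 0, 0),
                                 "tetraodon": (9, 0, 0),
                                 "zebrafish": (17, 0, 0)},
         {"winner": 5}),
    _row("LMO4/PKN2", 40, {"fugu": (16, 1, 0), "medaka": (15, 0, 0),
                           "stickleback": (17, 1, 0), "tetraodon": (14, 0, 0),
                           "zebrafish": (18, 3, 0)},
         {"winner": 5}),
    _row("KCTD1/SS18/ZNF521", 40, {"fugu": (21, 0, 0), "medaka": (19, 0, 0),
                                   "stickleback": (19, 0, 0),
                                   "tetraodon": (15, 0, 0),
                                   "zebrafish": (5, 0, 1)},
         {"winner": 5}),
]


def tally_row(row: PublishedRow) -> dict[str, int]:
    """Classification tally a row's triplets produce under the rule."""
    from .retention import classify_pattern

    out: dict[str, int] = {}
    for a, b, c in row.triplets.values():
        label = classify_pattern(a, b, c)
        out[label] = out.get(label, 0) + 1
    return out
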