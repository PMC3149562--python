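"""Curated site map for the nine human linker histone H1 subtypes.

Positions are met-cleaved (initiator-Met-removed) coordinates, i.e. one
below the database canonical position, compiled from published
experimental phosphosite annotations and public predictor outputs
(NetPhos-style phospho potentials, YinOYang-style O-GlcNAc potentials)
together with cross-species conservation classes.  These tables are
*inputs* to the pipeline: they drive the bundled fixtures and the
imported-score workflow; nothing in the package recomputes them.
"""

from __future__ import annotations

SUBTYPES = {
    "Q02539": "H1.1",
    "P16403": "H1.2",
    "P16402": "H1.3",
    "P10412": "H1.4",
    "P16401": "H1.5",
    "P07305": "H1.0",
    "P22492": "H1t",
    "Q81ZA3": "H1oo",
    "Q92522": "H1x",
}

#: canonical sequence lengths (raw, including the initiator Met)
SEQUENCE_LENGTHS = {
    "Q02539": 215,
    "P16403": 213,
    "P16402": 221,
    "P10412": 219,
    "P16401": 226,
    "P07305": 194,
    "P22492": 207,
    "Q81ZA3": 346,
    "Q92522": 213,
}

#: (S/T)PXK / (S/T)PXZ consensus motif starts (met-cleaved numbering)
MOTIF_POSITIONS = {
    "Q02539": {"S": [183], "T": [151]},
    "P16403": {"S": [172], "T": [30, 145, 153]},
    "P16402": {"S": [173, 188], "T": [18, 146, 154]},
    "P10412": {"S": [171, 186], "T": [17, 145, 153]},
    "P16401": {"S": [17, 172], "T": [10, 137, 154]},
    "P07305": {"S": [], "T": [118, 140, 152]},
    "P22492": {"S": [142, 180], "T": []},
    "Q81ZA3": {"S": [276], "T": []},
    "Q92522": {"S": [33], "T": []},
}

#: phospho-predictor-positive positions (NetPhos-style)
NETPHOS_POSITIONS = {
    "Q02539": {"S": [33, 41, 51, 52, 53, 91, 106, 114, 115, 123, 135, 145, 148, 164, 165],
               "T": [94, 151, 161, 173, 199, 203]},
    "P16403": {"S": [35, 50, 54, 104, 112, 149, 172, 187], "T": [30, 91, 145, 153, 166]},
    "P16402": {"S": [36, 51, 55, 104, 113, 150, 173, 188, 204], "T": [18, 92, 146, 154, 167, 179]},
    "P10412": {"S": [26, 35, 50, 54, 103, 112, 150, 171, 186], "T": [17, 91, 145, 153, 202]},
    "P16401": {"S": [17, 43, 53, 106, 115, 172, 188], "T": [10, 24, 38, 94, 137, 154]},
    "P07305": {"S": [6, 18, 21, 44, 48, 65, 70, 97, 103, 123, 130, 185],
               "T": [109, 118, 134, 140, 152, 161]},
    "P22492": {"S": [8, 42, 52, 54, 86, 107, 111, 118, 126, 128, 137, 140, 142, 165, 180, 187, 204],
               "T": [131, 148, 158, 159, 162, 203]},
    "Q81ZA3": {"S": [8, 11, 13, 14, 16, 20, 21, 23, 26, 32, 42, 73, 161, 211, 229, 230, 235,
                     243, 245, 246, 260, 262, 263, 276, 336, 337, 340, 341],
               "T": [72, 194, 256, 278, 319]},
    "Q92522": {"S": [31, 33, 39, 92, 113, 154, 171], "T": [55]},
}

#: experimentally verified phosphosites
EXPERIMENTAL_POSITIONS = {
    "Q02539": {"S": [1, 35, 103, 183], "T": [151]},
    "P16403": {"S": [1, 172], "T": [30]},
    "P16402": {"S": [188], "T": [18]},
    # Thr-145 carries direct mitotic-phosphorylation evidence alongside
    # Ser-171/186, although the per-subtype site-map table omits it
    "P10412": {"S": [35, 171, 186], "T": [17, 145]},
    "P16401": {"S": [17, 172, 188], "T": [137, 154]},
    "P07305": {"S": [123], "T": []},
    "P22492": {"S": [177], "T": [158, 159]},
    "Q81ZA3": {"S": [], "T": []},
    "Q92522": {"S": [31, 33], "T": []},
}

#: O-GlcNAc-predictor-positive positions (YinOYang-style)
YINYANG_POSITIONS = {
    "Q02539": {"S": [33, 52, 53, 114, 164, 165], "T": [161, 173, 199, 203]},
    "P16403": {"S": [30, 50, 187], "T": [145, 166]},
    "P16402": {"S": [35, 51, 188, 204], "T": [146]},
    "P10412": {"S": [35, 50, 186], "T": [17, 145, 202]},
    "P16401": {"S": [17, 43, 53], "T": [10, 38]},
    "P07305": {"S": [6, 21, 44, 97, 103, 123, 130], "T": [134, 161]},
    "P22492": {"S": [8, 54, 118, 180, 204], "T": [148, 158, 159, 162, 203]},
    "Q81ZA3": {"S": [8, 13, 14, 16, 26, 73, 229, 262, 336, 337, 340, 341], "T": [256, 319]},
    "Q92522": {"S": [33], "T": []},
}

#: strictly conserved S/T positions across the subtype's ortholog family
CONSERVED_POSITIONS = {
    "Q02539": {"S": [41, 43, 51, 53, 60, 106, 183], "T": [94]},
    "P16403": {"S": [1, 40, 58, 77, 102, 104, 172, 187], "T": [44, 91, 95, 98]},
    "P16402": {"S": [36, 41, 51, 58, 79, 89, 102, 104, 188], "T": [3, 45, 92, 96, 99]},
    "P10412": {"S": [1, 35, 40, 50, 54, 57, 78, 85, 88, 101, 103, 112, 150, 171, 186],
               "T": [3, 17, 91, 95, 98, 145]},
    "P16401": {"S": [1, 43, 60, 80, 104, 106, 115], "T": [38]},
    "P07305": {"S": [4, 6, 21, 28, 44, 45, 55, 65, 70, 89, 91, 103, 130, 170, 184, 185],
               "T": [1, 5, 22, 76, 77, 83, 109, 118, 123, 134, 140, 152]},
    "P22492": {"S": [1, 42, 44, 52, 54, 61, 81, 105, 107, 140, 142, 165, 180],
               "T": [3, 21, 99, 102, 148, 158]},
    "Q81ZA3": {"S": [5, 8, 12, 13, 20, 67, 110, 118, 221, 236], "T": [66, 81, 97, 116, 231]},
    "Q92522": {"S": [49, 65, 66, 92, 113], "T": [101]},
}

#: conserved-substituted (S<->T) positions
CONSERVED_SUB_POSITIONS = {
    "Q02539": {"S": [1, 48, 52, 91, 103], "T": [11, 101, 151, 164, 203]},
    "P16403": {"S": [35, 85, 88, 112], "T": [3, 153]},
    "P16402": {"S": [1, 86], "T": [154]},
    "P10412": {"S": [172, 188], "T": [141, 153, 202]},
    "P16401": {"S": [17, 53, 88, 91, 172], "T": [3, 8, 47, 98, 101, 154]},
    "P07305": {"S": [18, 97, 115], "T": [161]},
    "P22492": {"S": [8, 35, 126, 128, 137, 187, 189, 204], "T": [10, 48, 131, 145, 203]},
    "Q81ZA3": {"S": [7, 122, 219, 231, 241, 249], "T": [19, 209]},
    "Q92522": {"S": [27, 31, 133], "T": [12, 13, 55, 87]},
}

#: proposed Yin-Yang sites (conservation-anchored dual-modification calls)
PROPOSED_YINYANG = {
    "Q02539": {"S": [103, 183], "T": [203]},
    "P16403": {"S": [187], "T": []},
    "P16402": {"S": [188], "T": [146]},
    "P10412": {"S": [35, 186], "T": [17, 45, 202]},
    "P16401": {"S": [17], "T": []},
    "P07305": {"S": [21, 44, 97, 103, 123, 130], "T": [134, 161]},
    "P22492": {"S": [54, 180, 204], "T": [148, 158, 203]},
    "Q81ZA3": {"S": [8, 13], "T": []},
    "Q92522": {"S": [], "T": []},
}

#: proposed FN-Yin-Yang sites (glyco score just below threshold)
PROPOSED_FN_YINYANG = {
    "Q02539": {"S": [41, 51, 91, 104, 106, 182], "T": [94, 203]},
    "P16403": {"S": [], "T": []},
    "P16402": {"S": [104], "T": [92, 154]},
    "P10412": {"S": [54, 103, 112, 171], "T": [91, 153]},
    "P16401": {"S": [106, 115, 172], "T": []},
    "P07305": {"S": [], "T": []},
    "P22492": {"S": [42, 52, 107, 126, 128, 137, 140, 165, 187], "T": [31]},
    "Q81ZA3": {"S": [], "T": []},
    "Q92522": {"S": [], "T": []},
}

#: mitotic phosphosites with direct experimental support, per subtype
MITOTIC_PHOSPHOSITES = {
    "P16403": {"S": [172], "T": []},
    "P16402": {"S": [188], "T": []},
    "P10412": {"S": [171, 186], "T": [145]},
    "P16401": {"S": [17, 172], "T": [137, 154]},
}

#: experimentally phosphorylated residues that also score O-GlcNAc-positive
EXPERIMENTAL_DUAL_SITES = [
    ("P16402", "S", 188),
    ("P10412", "S", 186),
    ("P10412", "T", 145),
    ("P16401", "S", 17),
    ("P22492", "S", 177),
]
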