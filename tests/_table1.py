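"""Published reference peptides: sequence, PTM flags, printed [M+H]+ (3 dp).

Curated detected-neuropeptide tables for the two ant species, used as
the regression oracle for the mass engine.  ``pyroglu`` entries carry
the pre-cyclisation residue (Q) as the first residue of ``sequence``.
"""

# (name, species, sequence, amidated, pyroglu, printed_calc_mh)
LASIUS = [
    ("AST A1", "L. niger", "LPLYNFGI", True, False, 935.535),
    ("AST A2", "L. niger", "TRPFSFGI", True, False, 923.510),
    ("AST A3", "L. niger", "LRDYRFGI", True, False, 1038.584),
    ("AST A4", "L. niger", "GGKPFSFGI", True, False, 908.499),
    ("AST A5", "L. niger", "GWKLATGETAVS", True, False, 1218.648),
    ("CAPA1", "L. niger", "SAGLVPYPRI", True, False, 1071.631),
    ("CAPA2", "L. niger", "ALGIIHQPRI", True, False, 1116.700),
    ("CRZ", "L. niger", "QTFQYSRGWTN", True, True, 1369.629),
    ("ETH1", "L. niger", "DEVPAFFLKIAKIPTLPRV", True, False, 2153.284),
    ("IDLSRF-like", "L. niger", "IDLSRFYGHINT", False, False, 1435.733),
    ("ITG-like", "L. niger", "ITGQGNRLF", False, False, 1005.548),
    ("MS", "L. niger", "QDVDHVFLRF", True, True, 1257.638),
    ("NPLP1 2", "L. niger", "NVGTLARDFALPT", True, False, 1373.754),
    ("NPLP1 3", "L. niger", "HIASVARDHGLPN", True, False, 1385.740),
    ("NPLP1 4", "L. niger", "NIGSLARQSTLPSN", True, False, 1456.787),
    ("NPLP1 6", "L. niger", "NVAALARDSSLPY", True, False, 1375.733),
    ("OK3", "L. niger", "NFDEIDRVGWGGFV", False, False, 1610.760),
    ("PK1", "L. niger", "TTAQEITSGMWFGPRL", True, False, 1793.900),
    ("sNPF", "L. niger", "SPSLRLRF", True, False, 974.589),
    ("TK1", "L. niger", "APMGFQGMR", True, False, 993.476),
    ("TK3", "L. niger", "LLAMGFQGIR", True, False, 1104.635),
    ("TK4", "L. niger", "TVMGFQGMR", True, False, 1025.502),
    ("TK7", "L. niger", "AAMGFYGTR", True, False, 972.472),
]

ATTA = [
    ("AST A1", "A. sexdens", "LPLYTFGI", True, False, 922.540),
    ("AST A2", "A. sexdens", "TRQFSFGI", True, False, 954.516),
    ("AST A3", "A. sexdens", "LRNYDFGI", True, False, 996.526),
    ("AST A4", "A. sexdens", "GNHQFGFGI", True, False, 975.480),
    ("AST A5", "A. sexdens", "VWKLATGETAVS", True, False, 1260.695),
    ("CAPA1", "A. sexdens", "SAGLVAYPRI", True, False, 1045.615),
    ("CAPA2", "A. sexdens", "AFGIIHKPRIG", True, False, 1207.742),
    ("CRZ", "A. sexdens", "QTFQYSRGWTN", True, True, 1369.629),
    ("ETH1", "A. sexdens", "EEVPAFFLKIAKIPTLPRV", True, False, 2167.300),
    ("IDLSRF-like", "A. sexdens", "IDLSRFYGHFNT", False, False, 1469.717),
    ("ITG-like", "A. sexdens", "ITGQGNRLF", False, False, 1005.548),
    ("MS", "A. sexdens", "QDVDHVFLRF", True, True, 1257.638),
    ("NPLP1 2", "A. sexdens", "NVGALARDFALPT", True, False, 1343.743),
    ("NPLP1 3", "A. sexdens", "HIGSVLRDYSTMS", True, False, 1464.726),
    ("NPLP1 4", "A. sexdens", "NIGSLARQSMLPIS", True, False, 1485.821),
    ("NPLP1 6", "A. sexdens", "NVAALARDSSLPY", True, False, 1375.733),
    ("OK3", "A. sexdens", "NFDEIDRAGWGGFV", False, False, 1582.728),
    ("PK1", "A. sexdens", "TTQDITSGMWFGPRL", True, False, 1708.848),
    ("sNPF", "A. sexdens", "SPSLRLRF", True, False, 974.589),
    ("TK1", "A. sexdens", "APMGFQGMR", True, False, 993.476),
    ("TK2", "A. sexdens", "APKGFQGMR", True, False, 990.530),
    ("TK3", "A. sexdens", "ASMGFQGMR", True, False, 983.455),
    ("TK4", "A. sexdens", "TLMGFQGMR", True, False, 1039.518),
    ("TK7", "A. sexdens", "AALGFYGTR", True, False, 954.516),
]

TABLE1 = LASIUS + ATTA

#: Masses that reproduce the printed 3-dp values exactly with the proton
#: convention (the remainder agree within the +/-0.001 Da calculator band).
ROBUST_3DP = [
    ("APMGFQGMR", True, False, 993.476),
    ("ITGQGNRLF", False, False, 1005.548),
    ("LRDYRFGI", True, False, 1038.584),
    ("IDLSRFYGHINT", False, False, 1435.733),
    ("NVAALARDSSLPY", True, False, 1375.733),
    ("AALGFYGTR", True, False, 954.516),
    ("TRQFSFGI", True, False, 954.516),
    ("SPSLRLRF", True, False, 974.589),
]
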