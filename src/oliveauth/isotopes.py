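"""Monoisotopic masses and natural isotope abundances (CODATA/IUPAC 2021).

Pinned here so mass arithmetic and isotope-pattern simulation are
bit-stable across environments.  Masses in Da; abundances as mole
fractions.  Only the elements that occur in the deprotonated small
molecules this workflow annotates are included.
"""

from __future__ import annotations

# element -> list of (isotope mass, natural abundance), most abundant first
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.00782503207, 0.999885), (2.01410177785, 0.000115)],
    "C": [(12.0, 0.9893), (13.00335483507, 0.0107)],
    "N": [(14.0030740048, 0.99636), (15.0001088989, 0.00364)],
    "O": [
        (15.99491461956, 0.99757),
        (16.99913170, 0.00038),
        (17.99916104, 0.00205),
    ],
    "P": [(30.97376163, 1.0)],
    "S": [
        (31.97207100, 0.9499),
        (32.97145876, 0.0075),
        (33.96786690, 0.0425),
        (35.96708076, 0.0001),
    ],
    "Na": [(22.9897692809, 1.0)],
    "Cl": [(34.96885268, 0.7576), (36.96590259, 0.2424)],
    "K": [
        (38.96370668, 0.932581),
        (39.96399848, 0.000117),
        (40.96182576, 0.067302),
    ],
}

#: mass of the most abundant isotope, per element
MONOISOTOPIC_MASS: dict[str, float] = {el: iso[0][0] for el, iso in ISOTOPES.items()}

#: mass of a proton; subtracted from the neutral monoisotopic mass for [M-H]-
PROTON_MASS: float = 1.00727646
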