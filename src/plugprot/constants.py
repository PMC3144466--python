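"""Pinned physical constants: element isotope tables and residue formulas.

Everything downstream (masses, labeled-mass shifts, isotope envelopes)
derives from the tables in this file, so the whole package is reproducible
from a single place. Masses are monoisotopic, in Daltons. Isotope
abundances are the standard terrestrial values; the natural ``15N``
abundance is pinned explicitly because the labeling arithmetic depends
on it.
"""

from __future__ import annotations

ELEMENTS = ("C", "H", "N", "O", "S")

#: monoisotopic mass of the lightest isotope of each element
MONO_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

#: per-element isotope table: list of (neutron shift, mass offset from the
#: lightest isotope, natural abundance). Shifts are relative neutron counts,
#: offsets are exact mass differences.
ISOTOPES = {
    "C": [(0, 0.0, 0.9893), (1, 1.0033548378, 0.0107)],
    "H": [(0, 0.0, 0.999885), (1, 1.0062767, 0.000115)],
    "N": [(0, 0.0, 0.996337), (1, 0.9970349, 0.003663)],
    "O": [(0, 0.0, 0.99757), (1, 1.0042169, 0.00038), (2, 2.0042449, 0.00205)],
    "S": [(0, 0.0, 0.9493), (1, 0.9993878, 0.0076), (2, 1.9957959, 0.0429),
          (4, 3.9950096, 0.0002)],
}

#: natural abundance of 15N (fraction of nitrogen atoms)
N15_NATURAL_ABUNDANCE = 0.003663

#: exact 15N - 14N mass difference, Da
N15_N14_MASS_DIFF = 0.9970349

#: proton mass for the m/z convention mz = (M + z * PROTON_MASS) / z
PROTON_MASS = 1.00727646688

#: residue (not free amino acid) elemental formulas for the 20 standard
#: residues, as (C, H, N, O, S) counts; a peptide is the sum of its residues
#: plus one water.
RESIDUE_FORMULAS = {
    "G": (2, 3, 1, 1, 0),
    "A": (3, 5, 1, 1, 0),
    "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0),
    "V": (5, 9, 1, 1, 0),
    "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1),
    "L": (6, 11, 1, 1, 0),
    "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0),
    "D": (4, 5, 1, 3, 0),
    "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0),
    "E": (5, 7, 1, 3, 0),
    "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0),
    "F": (9, 9, 1, 1, 0),
    "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0),
    "W": (11, 10, 2, 1, 0),
}

STANDARD_RESIDUES = frozenset(RESIDUE_FORMULAS)

#: water, (C, H, N, O, S)
WATER_FORMULA = (0, 2, 0, 1, 0)
WATER_MASS = 2 * MONO_MASS["H"] + MONO_MASS["O"]
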