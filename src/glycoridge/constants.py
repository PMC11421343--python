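"""Physical constants and mass tables used throughout the package.

All masses are monoisotopic and in Daltons. Glycopeptide masses arriving
from deconvolution are singly protonated (MH+); neutral masses are obtained
by subtracting :data:`PROTON_MASS`.
"""

from __future__ import annotations

#: Mass of a proton (charge carrier), Da.
PROTON_MASS = 1.00727646688

#: Average spacing of adjacent isotope peaks (13C - 12C), Da.
ISOTOPE_SPACING = 1.0033548

#: Monoisotopic element masses, Da.
ELEMENT_MASSES = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

#: Natural isotope abundances per element as (extra neutrons, abundance).
ISOTOPE_ABUNDANCES = {
    "C": [(0, 0.9893), (1, 0.0107)],
    "H": [(0, 0.999885), (1, 0.000115)],
    "N": [(0, 0.99636), (1, 0.00364)],
    "O": [(0, 0.99757), (1, 0.00038), (2, 0.00205)],
    "S": [(0, 0.9499), (1, 0.0075), (2, 0.0425), (4, 0.0001)],
}

#: Averagine model: average amino-acid residue composition used to predict
#: peptide isotope envelopes as a function of mass alone.
AVERAGINE_COMPOSITION = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
AVERAGINE_MASS = 111.1254

#: Glycan residue (dehydrated monosaccharide) masses, Da.
#: Hex C6H10O5; HexNAc C8H13NO5; dHex C6H10O4; NeuAc C11H17NO8.
HEX = 162.052824
HEXNAC = 203.079373
DHEX = 146.057909
NEUAC = 291.095417
LACNAC = HEX + HEXNAC  # Hex+HexNAc motif, one N-acetyllactosamine repeat

RESIDUE_MASSES = {
    "Hex": HEX,
    "HexNAc": HEXNAC,
    "dHex": DHEX,
    "LacNAc": LACNAC,
    "NeuAc": NEUAC,
}

#: Mass shifts of non-proton adduct satellites relative to the MH+ species:
#: ammonium adduct replaces H+ with NH4+ (net +NH3); Fe(III) replaces three
#: protons with one Fe3+ (net +Fe - 3H).
ADDUCT_SHIFTS = {
    "NH4": 17.026549,
    "FeIII": 52.911461,
}

#: Default glycan oxonium (diagnostic) ions, singly charged m/z.
DIAGNOSTIC_IONS = {
    "HexNAc": HEXNAC + PROTON_MASS,          # 204.0866
    "HexNAc+Hex": HEX + HEXNAC + PROTON_MASS,  # 366.1395
}


def composition_mass(hex: int, hexnac: int, dhex: int, neuac: int) -> float:
    """Neutral mass of a glycan composition Hex(i)HexNAc(j)dHex(k)NeuAc(l)."""
    return hex * HEX + hexnac * HEXNAC + dhex * DHEX + neuac * NEUAC
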