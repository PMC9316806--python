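"""Fixed element -> atomic mass table (Da).

Centers of mass must be bit-for-bit reproducible across runs and machines,
so masses come from this frozen table rather than from any external
library whose values could drift between versions.  Values are IUPAC 2021
standard atomic weights rounded to 3 decimals, which is far beyond the
precision any distance computed here requires.
"""

from __future__ import annotations

from .errors import SelectionError

ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
    "NA": 22.990,
    "K": 39.098,
    "MG": 24.305,
    "CA": 40.078,
    "ZN": 65.38,
    "FE": 55.845,
    "MN": 54.938,
    "CU": 63.546,
}


def mass_of(element: str) -> float:
    """Mass of *element* in Da.

    Raises
    ------
    SelectionError
        If the element symbol is not in the internal table.  An unknown
        element would silently corrupt every mass-weighted center of mass,
        so it is a hard error, never a default.
    """
    key = element.strip().upper()
    try:
        return ELEMENT_MASSES[key]
    except KeyError:
        raise SelectionError(
            f"element {element!r} not in the internal mass table; "
            f"known elements: {sorted(ELEMENT_MASSES)}"
        ) from None
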