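"""Unit conversions for hydroponic solution chemistry.

Solution dosing is quoted interchangeably in molar (µmol/L) and mass
(mg/L, µg/L) concentration; these helpers convert between the two for the
elements handled by the pipeline.
"""

from __future__ import annotations

#: Standard atomic weights (g/mol), IUPAC 2021 abridged values.
MOLAR_MASS_G_PER_MOL: dict[str, float] = {
    "Cd": 112.414,
    "Zn": 65.38,
    "Fe": 55.845,
}


def _molar_mass(element: str) -> float:
    try:
        return MOLAR_MASS_G_PER_MOL[element]
    except KeyError:
        raise ValueError(f"no molar mass registered for element {element!r}") from None


def umol_per_l_to_mg_per_l(umol_per_l: float, element: str) -> float:
    """Convert a molar concentration (µmol/L) to a mass concentration (mg/L).

    E.g. a 20 µmol/L CdCl2 dose corresponds to 20 µmol/L of Cd, i.e.
    ~2.25 mg/L of Cd.
    """
    if umol_per_l < 0:
        raise ValueError("concentration must be non-negative")
    return umol_per_l * _molar_mass(element) / 1000.0


def ug_per_l_to_umol_per_l(ug_per_l: float, element: str) -> float:
    """Convert a mass concentration (µg/L) to a molar concentration (µmol/L)."""
    if ug_per_l < 0:
        raise ValueError("concentration must be non-negative")
    return ug_per_l / _molar_mass(element)


def mg_per_l_to_umol_per_l(mg_per_l: float, element: str) -> float:
    """Convert a mass concentration (mg/L) to a molar concentration (µmol/L)."""
    return ug_per_l_to_umol_per_l(mg_per_l * 1000.0, element)
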