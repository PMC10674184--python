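"""Default background (reference) concentrations.

Ratio indices need a background value CB per element.  Surveys normally
take these from a regional soil baseline or from an upper-continental-
crust (UCC) compilation; the package ships one documented UCC default set
(Rudnick & Gao-style averages, mg/kg) covering the 17 elements of the
default survey panel.  Users with a regional baseline should supply their
own ``element,background_mg_per_kg`` CSV instead — the choice of
background dominates every index magnitude.
"""

from __future__ import annotations

from .tables import BackgroundTable

# Upper continental crust averages, mg/kg.
UCC_BACKGROUND_MG_PER_KG: dict[str, float] = {
    "Cu": 28.0,
    "Ni": 47.0,
    "Pb": 17.0,
    "Zn": 67.0,
    "Co": 17.3,
    "Cr": 92.0,
    "Ba": 628.0,
    "Fe": 39200.0,
    "Mn": 775.0,
    "Mg": 15000.0,
    "Sr": 320.0,
    "Na": 24300.0,
    "Al": 81500.0,
    "Ca": 25700.0,
    "K": 23200.0,
    "As": 4.8,
    "Cd": 0.09,
}


def default_background() -> BackgroundTable:
    """The built-in UCC background table."""
    return BackgroundTable.from_mapping(UCC_BACKGROUND_MG_PER_KG)
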