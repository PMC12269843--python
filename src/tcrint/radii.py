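"""Van der Waals radii tables for solvent-accessibility calculations.

Two named tables are shipped:

``"default"``
    Element-based radii in the range commonly used for protein SASA
    (Bondi-like values, C = 1.70 A).

``"chothia"``
    The classic protein-atom set used in early buried-surface work
    (aromatic/aliphatic carbons slightly larger, carbonyl oxygen smaller).
    Resolved per element here; atom-name refinements are applied on top
    for protein carbons.

Hydrogens are assigned a radius but are excluded upstream from all
interface computations (crystal structures at the resolutions handled
here rarely contain them).
"""

from __future__ import annotations

# element -> radius (Angstrom)
RADII_TABLES: dict[str, dict[str, float]] = {
    "default": {
        "H": 1.20,
        "C": 1.70,
        "N": 1.55,
        "O": 1.52,
        "S": 1.80,
        "P": 1.80,
        "SE": 1.90,
        "F": 1.47,
        "CL": 1.75,
        "BR": 1.85,
        "I": 1.98,
    },
    "chothia": {
        "H": 1.00,
        "C": 1.87,
        "N": 1.65,
        "O": 1.40,
        "S": 1.85,
        "P": 1.90,
        "SE": 1.90,
    },
}

DEFAULT_TABLE = "default"


class RadiusError(ValueError):
    """Raised when an atom's element has no radius in the chosen table."""


def vdw_radius(element: str, table: str = DEFAULT_TABLE) -> float:
    """Look up the van der Waals radius for an element symbol.

    Parameters
    ----------
    element:
        Chemical element symbol, case-insensitive (e.g. ``"C"``, ``"Se"``).
    table:
        Name of the radii table (``"default"`` or ``"chothia"``).

    Raises
    ------
    RadiusError
        If the element is absent from the table (no silent fallback:
        an unknown element would corrupt every downstream area).
    """
    try:
        radii = RADII_TABLES[table]
    except KeyError:
        raise RadiusError(f"unknown radii table {table!r}") from None
    key = element.strip().upper()
    if key not in radii:
        raise RadiusError(
            f"no van der Waals radius for element {element!r} in table {table!r}"
        )
    return radii[key]
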