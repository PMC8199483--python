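"""Element table: atomic masses and van der Waals radii.

Masses in atomic mass units (IUPAC 2021 standard atomic weights, rounded);
radii in Å (Bondi 1964, with the common Rowland & Taylor value for H).
The table is deliberately small and strict: an element missing from it is an
error, never a guess, because SASA depends directly on the radii.  Callers
may pass overrides (``element_table=``) to every reader.
"""

from __future__ import annotations

#: symbol -> (mass / amu, vdW radius / Å)
ELEMENT_TABLE: dict[str, tuple[float, float]] = {
    "H": (1.008, 1.10),
    "C": (12.011, 1.70),
    "N": (14.007, 1.55),
    "O": (15.999, 1.52),
    "S": (32.06, 1.80),
    "P": (30.974, 1.80),
    "F": (18.998, 1.47),
    "CL": (35.45, 1.75),
    "BR": (79.904, 1.85),
    "I": (126.904, 1.98),
    "NA": (22.990, 2.27),
    "K": (39.098, 2.75),
    "MG": (24.305, 1.73),
    "CA": (40.078, 2.31),
    "ZN": (65.38, 1.39),
    "FE": (55.845, 1.94),
    "SE": (78.971, 1.90),
}


class UnknownElementError(ValueError):
    """Raised when an atom's element symbol is not in the element table."""


def lookup(symbol: str, overrides: dict[str, tuple[float, float]] | None = None,
           *, atom_label: str = "") -> tuple[float, float]:
    """Return ``(mass, vdw_radius)`` for an element symbol.

    Parameters
    ----------
    symbol
        Element symbol, case-insensitive ("C", "Cl", ...).
    overrides
        Optional extra/replacement entries, same shape as :data:`ELEMENT_TABLE`.
    atom_label
        Human-readable atom identification used in the error message.
    """
    key = symbol.strip().upper()
    if overrides:
        up = {k.upper(): v for k, v in overrides.items()}
        if key in up:
            return up[key]
    if key in ELEMENT_TABLE:
        return ELEMENT_TABLE[key]
    raise UnknownElementError(
        f"unknown element {symbol!r}" + (f" for atom {atom_label}" if atom_label else "")
    )
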