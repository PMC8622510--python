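"""Built-in per-element force-field-style parameters.

The steric probe interaction uses Lennard-Jones parameters combined with
arithmetic radii and geometric well depths. Radii are Bondi van der Waals
radii; well depths follow general-purpose Amber-style atom types rounded to
three figures. Hydrophobic weights are a coarse atom-typing scheme (apolar
atoms positive, polar heteroatoms negative) in the spirit of atom-based
logP increments. All values are user-overridable through a YAML config
(see :func:`load_parameter_overrides`).

Units: radii in Angstrom, well depths in kcal/mol, hydrophobic weight
unitless.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml


@dataclass(frozen=True)
class ElementParams:
    vdw_radius: float
    lj_epsilon: float
    hydrophobic_weight: float


#: Default parameter table keyed by element symbol.
ELEMENT_TABLE: dict[str, ElementParams] = {
    "H": ElementParams(1.20, 0.0157, 0.0),
    "C": ElementParams(1.70, 0.1094, 1.0),
    "N": ElementParams(1.55, 0.1700, -1.0),
    "O": ElementParams(1.52, 0.2100, -1.0),
    "F": ElementParams(1.47, 0.0610, 1.0),
    "P": ElementParams(1.80, 0.2000, 0.0),
    "S": ElementParams(1.80, 0.2500, 0.5),
    "Cl": ElementParams(1.75, 0.2650, 1.0),
    "Br": ElementParams(1.85, 0.3200, 1.0),
    "I": ElementParams(1.98, 0.4000, 1.0),
}

#: Conversion factor for Coulomb energies, kcal*Angstrom/(mol*e^2).
COULOMB_CONSTANT = 332.0636

#: Probe defaults: an sp3-carbon-like probe with the 1.52 A radius used for
#: grid field evaluation, charge +1.
DEFAULT_PROBE_RADIUS = 1.52
DEFAULT_PROBE_EPSILON = ELEMENT_TABLE["C"].lj_epsilon
DEFAULT_PROBE_CHARGE = 1.0


class UnknownElementError(KeyError):
    """Raised when an atom's element has no entry in the parameter table."""


def element_params(symbol: str, table: dict[str, ElementParams] | None = None) -> ElementParams:
    tab = table if table is not None else ELEMENT_TABLE
    try:
        return tab[symbol]
    except KeyError:
        raise UnknownElementError(
            f"no built-in parameters for element {symbol!r}; "
            "supply an override table via config"
        ) from None


def load_parameter_overrides(path: str) -> dict[str, ElementParams]:
    """Merge a YAML mapping ``element -> {vdw_radius, lj_epsilon, hydrophobic_weight}``
    over the built-in table and return the merged table."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    table = dict(ELEMENT_TABLE)
    for sym, vals in raw.items():
        base = table.get(sym, ElementParams(1.7, 0.1, 0.0))
        table[sym] = ElementParams(
            float(vals.get("vdw_radius", base.vdw_radius)),
            float(vals.get("lj_epsilon", base.lj_epsilon)),
            float(vals.get("hydrophobic_weight", base.hydrophobic_weight)),
        )
    return table
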