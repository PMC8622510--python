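"""Packaged reference tables.

``complex_energy_components.csv`` holds published per-complex MM-PB(GB)SA
component means (VDWAALS, E_EL, E_PB/GB, E_SURF; kcal/mol, final-window
averages) for a set of FLT3 inhibitor complexes. Only the components are
stored; the gas-phase, solvation and total terms are always recomposed by
:func:`gridqsar.endstate.mmpbsa_total`.
"""

from importlib import resources

import pandas as pd


def reference_energy_components() -> pd.DataFrame:
    with resources.files(__package__).joinpath(
        "complex_energy_components.csv"
    ).open() as fh:
        return pd.read_csv(fh)
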