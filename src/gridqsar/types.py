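"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FIELD_KINDS = ("S", "E", "H", "A", "D")


@dataclass
class MoleculeRecord:
    """An aligned small-molecule conformer with per-atom grid-field parameters.

    Molecules are consumed pre-aligned to a common template; no conformer
    generation or alignment happens downstream. ``core_atom_indices`` marks
    the atoms of the shared substructure (identical count across a dataset).
    """

    id: str
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3), Angstrom
    charges: np.ndarray  # elementary charge
    vdw_radius: np.ndarray  # Angstrom, > 0
    lj_epsilon: np.ndarray  # kcal/mol
    hydrophobic_weight: np.ndarray  # unitless
    donor_flag: np.ndarray  # bool
    acceptor_flag: np.ndarray  # bool
    core_atom_indices: list[int] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        for name in ("charges", "vdw_radius", "lj_epsilon", "hydrophobic_weight"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.donor_flag = np.asarray(self.donor_flag, dtype=bool)
        self.acceptor_flag = np.asarray(self.acceptor_flag, dtype=bool)
        self.validate()

    def validate(self) -> None:
        n = self.n_atoms
        if self.coords.shape != (n, 3):
            raise ValueError(f"{self.id}: coords shape {self.coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.id}: non-finite coordinates")
        for name in ("charges", "vdw_radius", "lj_epsilon", "hydrophobic_weight"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{self.id}: {name} has length {arr.shape}, expected {n}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{self.id}: non-finite {name}")
        if np.any(self.vdw_radius <= 0):
            raise ValueError(f"{self.id}: vdw_radius must be positive")
        if any(i < 0 or i >= n for i in self.core_atom_indices):
            raise ValueError(f"{self.id}: core_atom_indices out of range")

    def translated(self, shift) -> "MoleculeRecord":
        """Return a copy rigidly translated by ``shift`` (length-3 vector)."""
        out = MoleculeRecord(
            id=self.id,
            elements=list(self.elements),
            coords=self.coords + np.asarray(shift, dtype=float),
            charges=self.charges.copy(),
            vdw_radius=self.vdw_radius.copy(),
            lj_epsilon=self.lj_epsilon.copy(),
            hydrophobic_weight=self.hydrophobic_weight.copy(),
            donor_flag=self.donor_flag.copy(),
            acceptor_flag=self.acceptor_flag.copy(),
            core_atom_indices=list(self.core_atom_indices),
        )
        return out


@dataclass
class EnergyFrameSeries:
    """Per-frame interaction/solvation energy components for one complex.

    ``frames`` has columns ``frame, vdwaals, e_el, e_pbgb, e_surf``
    (kcal/mol), strictly increasing ``frame``. ``variant`` records whether
    the polar solvation column came from a PB or GB calculation.
    """

    frames: pd.DataFrame
    label: str = ""
    variant: str | None = None

    REQUIRED = ("frame", "vdwaals", "e_el", "e_pbgb", "e_surf")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frames.columns]
        if missing:
            raise ValueError(f"energy frame series missing columns: {missing}")
        if len(self.frames) == 0:
            raise ValueError("no frames")
        idx = self.frames["frame"].to_numpy()
        if not np.all(np.diff(idx) > 0):
            raise ValueError("frame indices must be strictly increasing")
        vals = self.frames[list(self.REQUIRED[1:])].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite energy components")

    def __len__(self) -> int:
        return len(self.frames)
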