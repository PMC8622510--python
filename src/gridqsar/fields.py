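"""Grid-based molecular interaction and similarity fields.

Two field families are computed on a shared rectangular lattice around the
aligned series:

* CoMFA-style interaction fields — a probe atom's Lennard-Jones (steric)
  and Coulomb (electrostatic) energies at every grid point, capped at
  +/-30 kcal/mol.
* CoMSIA-style similarity fields — Gaussian-attenuated sums of per-atom
  property weights (steric volume, partial charge, hydrophobicity, H-bond
  donor/acceptor flags), with no distance cutoff.

Grid points are ordered x-fastest: point ``k`` maps to
``(ix, iy, iz) = (k % nx, (k // nx) % ny, k // (nx * ny))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import (
    COULOMB_CONSTANT,
    DEFAULT_PROBE_CHARGE,
    DEFAULT_PROBE_EPSILON,
    DEFAULT_PROBE_RADIUS,
)
from .types import FIELD_KINDS, MoleculeRecord

#: Energy cap for CoMFA fields, kcal/mol.
DEFAULT_ENERGY_CAP = 30.0
#: CoMSIA Gaussian attenuation factor, 1/Angstrom^2.
DEFAULT_ALPHA = 0.3
#: Minimum column standard deviation retained by the column filter, kcal/mol.
DEFAULT_MIN_SIGMA = 2.0

COMFA_KINDS = ("S", "E")


@dataclass(frozen=True)
class GridSpec:
    """A rectangular lattice: ``origin`` (A), isotropic ``spacing`` (A),
    ``dims`` = number of points per axis."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dims must be >= 1")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All lattice coordinates, shape (n_points, 3), x-fastest order."""
        nx, ny, nz = self.dims
        ix = np.arange(nx)
        iy = np.arange(ny)
        iz = np.arange(nz)
        gz, gy, gx = np.meshgrid(iz, iy, ix, indexing="ij")
        idx = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        return np.asarray(self.origin) + idx * self.spacing


@dataclass(frozen=True)
class ProbeSpec:
    """The grid probe: sp3-carbon-like sphere, charge +1, unit property
    weight, after the conventional CoMFA probe."""

    vdw_radius: float = DEFAULT_PROBE_RADIUS
    lj_epsilon: float = DEFAULT_PROBE_EPSILON
    charge: float = DEFAULT_PROBE_CHARGE
    property_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError("probe vdw_radius must be positive")


@dataclass
class DescriptorBlock:
    """Molecules x (grid points x field kinds) descriptor matrix.

    ``column_meta`` has one row per column: ``kind`` in {S,E,H,A,D} and
    ``point`` (grid point index). ``kept_mask`` tracks column filtering;
    ``matrix`` always holds all columns and :meth:`filtered` selects the
    kept ones.
    """

    matrix: np.ndarray
    column_meta: pd.DataFrame
    grid: GridSpec
    scheme: str
    molecule_ids: list[str]
    kept_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    imputed_mask: np.ndarray | None = None  # entries replaced by column means

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.column_meta):
            raise ValueError("column_meta length does not match matrix width")
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.matrix.shape[1], dtype=bool)

    @property
    def n_molecules(self) -> int:
        return self.matrix.shape[0]

    def filtered(self) -> np.ndarray:
        return self.matrix[:, self.kept_mask]

    def kept_meta(self) -> pd.DataFrame:
        return self.column_meta[self.kept_mask].reset_index(drop=True)

    def kinds(self) -> list[str]:
        return list(dict.fromkeys(self.column_meta["kind"]))


# ---------------------------------------------------------------------------


def build_grid(
    molecules: list[MoleculeRecord], spacing: float = 2.0, margin: float = 4.0
) -> GridSpec:
    """Axis-aligned lattice covering the union of all atom coordinates,
    expanded by ``margin`` on every side and discretized at ``spacing``.

    Identical for any permutation of the molecule list.
    """
    if not molecules:
        raise ValueError("need at least one molecule to build a grid")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    coords = np.vstack([m.coords for m in molecules])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    dims = tuple(int(math.ceil(round((h - l) / spacing, 9))) + 1 for l, h in zip(lo, hi))
    return GridSpec(origin=tuple(float(v) for v in lo), spacing=float(spacing), dims=dims)


def _distances(molecule: MoleculeRecord, grid: GridSpec) -> np.ndarray:
    """Pairwise distances, shape (n_points, n_atoms)."""
    pts = grid.points()
    diff = pts[:, None, :] - molecule.coords[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=2))


def comfa_steric(
    molecule: MoleculeRecord,
    grid: GridSpec,
    probe: ProbeSpec | None = None,
    cap: float = DEFAULT_ENERGY_CAP,
) -> np.ndarray:
    """Lennard-Jones probe energy at every grid point, kcal/mol.

    Per atom pair: ``eps_ij * [(Rmin_ij/r)^12 - 2 (Rmin_ij/r)^6]`` with
    ``Rmin_ij = r_vdw,atom + r_vdw,probe`` and
    ``eps_ij = sqrt(eps_atom * eps_probe)``; the sum over atoms is clamped
    to ``[-cap, +cap]``. A point coincident with an atom center is clamped
    to ``+cap`` (no singularity propagated).
    """
    probe = probe or ProbeSpec()
    r = _distances(molecule, grid)
    rmin = molecule.vdw_radius + probe.vdw_radius
    eps = np.sqrt(molecule.lj_epsilon * probe.lj_epsilon)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        ratio6 = (rmin[None, :] / r) ** 6
        energy = eps[None, :] * (ratio6 * ratio6 - 2.0 * ratio6)
    energy = np.where(np.isfinite(energy), energy, np.inf)
    total = energy.sum(axis=1)
    total = np.where(np.isfinite(total), total, cap)
    return np.clip(total, -cap, cap)


def comfa_electrostatic(
    molecule: MoleculeRecord,
    grid: GridSpec,
    probe: ProbeSpec | None = None,
    cap: float = DEFAULT_ENERGY_CAP,
    dielectric: str = "distance",
) -> np.ndarray:
    """Coulomb probe energy at every grid point, kcal/mol.

    ``332.0636 * sum_i q_probe q_i / (eps(r_i) r_i)`` with the
    distance-dependent dielectric ``eps(r) = r`` by default (``dielectric=
    "constant"`` selects eps = 1); clamped to ``[-cap, +cap]``. Treatment
    of sterically excluded points (column-mean imputation) happens at
    matrix-assembly time, where all molecules are in view.
    """
    probe = probe or ProbeSpec()
    r = _distances(molecule, grid)
    if dielectric == "distance":
        denom = r * r
    elif dielectric == "constant":
        denom = r
    else:
        raise ValueError(f"unknown dielectric model {dielectric!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = COULOMB_CONSTANT * probe.charge * molecule.charges[None, :] / denom
    # a point on an atom center contributes the capped energy with the sign
    # of the pair charge product (zero for an uncharged atom)
    on_center = r == 0
    if on_center.any():
        signs = np.sign(molecule.charges[None, :] * probe.charge)
        terms = np.where(on_center, cap * np.broadcast_to(signs, terms.shape), terms)
    terms = np.nan_to_num(terms, nan=0.0, posinf=cap, neginf=-cap)
    return np.clip(terms.sum(axis=1), -cap, cap)


_COMSIA_WEIGHTS = {
    "S": lambda m: m.vdw_radius**3,
    "E": lambda m: m.charges,
    "H": lambda m: m.hydrophobic_weight,
    "D": lambda m: m.donor_flag.astype(float),
    "A": lambda m: m.acceptor_flag.astype(float),
}


def comsia_field(
    molecule: MoleculeRecord,
    grid: GridSpec,
    kind: str,
    alpha: float = DEFAULT_ALPHA,
    probe_weight: float = 1.0,
) -> np.ndarray:
    """Gaussian similarity field ``A_k(q) = -sum_i w_probe w_ik exp(-alpha r_iq^2)``.

    Property weights per kind: S — r_vdw^3 (steric volume); E — partial
    charge; H — hydrophobic weight from the atom table; D/A — donor/acceptor
    flags as 0/1. No distance cutoff; unitless.
    """
    if kind not in _COMSIA_WEIGHTS:
        raise ValueError(f"unknown CoMSIA field kind {kind!r}")
    w = _COMSIA_WEIGHTS[kind](molecule)
    r = _distances(molecule, grid)
    return -(probe_weight * np.exp(-alpha * r * r) @ w)


def assemble_descriptor_matrix(
    molecules: list[MoleculeRecord],
    grid: GridSpec,
    kinds: tuple[str, ...] | str = ("S", "E"),
    scheme: str = "comfa",
    probe: ProbeSpec | None = None,
    cap: float = DEFAULT_ENERGY_CAP,
    alpha: float = DEFAULT_ALPHA,
    excluded_policy: str = "column_mean",
) -> DescriptorBlock:
    """Stack per-molecule fields into the molecules x columns matrix.

    Rows follow molecule order; columns are grouped by kind (in the order
    given) then grid point index. For ``scheme="comfa"`` only S and E are
    allowed; electrostatic entries at sterically excluded points (steric
    value clamped at ``+cap``) are replaced by the column mean over the
    non-excluded molecules (``excluded_policy="column_mean"``, the classic
    convention) or left clamped (``"clamp"``); replaced entries are flagged
    in ``imputed_mask``.
    """
    kinds = tuple(kinds)
    if not kinds:
        raise ValueError("kinds must be non-empty")
    unknown = [k for k in kinds if k not in FIELD_KINDS]
    if unknown:
        raise ValueError(f"unknown field kinds: {unknown}")
    if scheme not in ("comfa", "comsia"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "comfa" and any(k not in COMFA_KINDS for k in kinds):
        raise ValueError("CoMFA supports only steric (S) and electrostatic (E) fields")
    if not molecules:
        raise ValueError("no molecules")

    npts = grid.n_points
    blocks: dict[str, np.ndarray] = {}
    if scheme == "comfa":
        steric = np.vstack([comfa_steric(m, grid, probe, cap) for m in molecules])
        if "S" in kinds:
            blocks["S"] = steric
        if "E" in kinds:
            ele = np.vstack(
                [comfa_electrostatic(m, grid, probe, cap) for m in molecules]
            )
            excluded = steric >= cap
            if excluded_policy == "column_mean":
                n_ok = (~excluded).sum(axis=0)
                col_sum = np.where(excluded, 0.0, ele).sum(axis=0)
                col_mean = np.where(n_ok > 0, col_sum / np.maximum(n_ok, 1), 0.0)
                ele = np.where(excluded, col_mean[None, :], ele)
            elif excluded_policy != "clamp":
                raise ValueError(f"unknown excluded_policy {excluded_policy!r}")
            blocks["E"] = ele
    else:
        for k in kinds:
            blocks[k] = np.vstack(
                [comsia_field(m, grid, k, alpha=alpha) for m in molecules]
            )
        excluded = None

    matrix = np.hstack([blocks[k] for k in kinds])
    meta = pd.DataFrame(
        {
            "kind": np.repeat(list(kinds), npts),
            "point": np.tile(np.arange(npts), len(kinds)),
        }
    )
    imputed = None
    if scheme == "comfa" and "E" in kinds and excluded_policy == "column_mean":
        imputed = np.zeros_like(matrix, dtype=bool)
        e_off = list(kinds).index("E") * npts
        imputed[:, e_off : e_off + npts] = excluded
    return DescriptorBlock(
        matrix=matrix,
        column_meta=meta,
        grid=grid,
        scheme=scheme,
        molecule_ids=[m.id for m in molecules],
        imputed_mask=imputed,
    )


def column_filter(
    block: DescriptorBlock,
    min_sigma: float = DEFAULT_MIN_SIGMA,
    drop_clamped: bool = True,
    clamp_limit: float = DEFAULT_ENERGY_CAP,
) -> DescriptorBlock:
    """Drop columns whose sample standard deviation across molecules falls
    below ``min_sigma`` (kcal/mol for CoMFA; the same numeric threshold is
    applied to unitless CoMSIA columns). Returns a new block with
    ``kept_mask`` updated; the raw matrix is shared, not copied.

    For CoMFA blocks, ``drop_clamped`` additionally removes columns whose
    value hits the energy cap for at least one molecule: such grid points
    sit partially inside the union molecular volume, and their variance is
    a discontinuous artifact of the clamp rather than a smooth field
    response.
    """
    if block.matrix.size == 0:
        raise ValueError("empty descriptor block")
    sd = block.matrix.std(axis=0, ddof=1)
    kept = sd >= min_sigma
    if drop_clamped and block.scheme == "comfa":
        tol = 1e-9 * max(clamp_limit, 1.0)
        kept &= ~(np.abs(block.matrix) >= clamp_limit - tol).any(axis=0)
    if not kept.any():
        raise ValueError(
            f"column filter at min_sigma={min_sigma} removed every column; "
            "lower the threshold"
        )
    return DescriptorBlock(
        matrix=block.matrix,
        column_meta=block.column_meta,
        grid=block.grid,
        scheme=block.scheme,
        molecule_ids=block.molecule_ids,
        kept_mask=kept,
        imputed_mask=block.imputed_mask,
    )
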