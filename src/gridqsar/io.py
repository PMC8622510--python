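"""Readers and writers for molecules, activity tables, energy tables and grids.

Structures arrive as SDF V2000 (read through RDKit) or Tripos MOL2.
Per-atom partial charges are taken from the file when present (the
``atom.dprop.PartialCharge`` SDF property list or the MOL2 charge column);
otherwise Gasteiger charges are assigned as a configurable default. Missing
per-atom field parameters (vdW radius, LJ well depth, hydrophobic weight,
donor/acceptor flags) are filled from the built-in element table.

All CSV tables are header-driven, UTF-8, with the Unicode minus sign
normalized to ASCII on read.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .params import ELEMENT_TABLE, ElementParams, element_params
from .types import EnergyFrameSeries, MoleculeRecord

SET_LABELS = ("train", "test", "unassigned")


class FormatError(ValueError):
    """Unparseable or malformed input file."""


class SchemaError(ValueError):
    """A required table column is absent."""


# ---------------------------------------------------------------------------
# molecules


def _donor_acceptor_flags(mol: Chem.Mol) -> tuple[np.ndarray, np.ndarray]:
    """Donor: N/O bearing at least one H. Acceptor: any N/O."""
    n = mol.GetNumAtoms()
    donor = np.zeros(n, dtype=bool)
    acceptor = np.zeros(n, dtype=bool)
    for atom in mol.GetAtoms():
        if atom.GetSymbol() in ("N", "O"):
            acceptor[atom.GetIdx()] = True
            if atom.GetTotalNumHs(includeNeighbors=True) > 0:
                donor[atom.GetIdx()] = True
    return donor, acceptor


def _record_from_rdkit(
    mol: Chem.Mol,
    mol_id: str,
    charge_method: str,
    table: dict[str, ElementParams],
) -> MoleculeRecord:
    if mol.GetNumConformers() == 0:
        raise FormatError(f"molecule {mol_id!r} has no coordinates block")
    conf = mol.GetConformer()
    coords = np.array(conf.GetPositions(), dtype=float)
    elements = [a.GetSymbol() for a in mol.GetAtoms()]

    if all(a.HasProp("PartialCharge") for a in mol.GetAtoms()):
        charges = np.array([a.GetDoubleProp("PartialCharge") for a in mol.GetAtoms()])
    elif charge_method == "gasteiger":
        AllChem.ComputeGasteigerCharges(mol)
        charges = np.array(
            [float(a.GetProp("_GasteigerCharge")) for a in mol.GetAtoms()], dtype=float
        )
        charges = np.nan_to_num(charges, nan=0.0)
    else:
        raise FormatError(
            f"molecule {mol_id!r} carries no partial charges and charge method "
            f"{charge_method!r} is not available"
        )

    params = [element_params(sym, table) for sym in elements]
    donor, acceptor = _donor_acceptor_flags(mol)

    def per_atom(prop: str, default: np.ndarray) -> np.ndarray:
        atoms = list(mol.GetAtoms())
        if all(a.HasProp(prop) for a in atoms):
            return np.array([float(a.GetProp(prop)) for a in atoms])
        return default

    vdw = per_atom("VdwRadius", np.array([p.vdw_radius for p in params]))
    eps = per_atom("LJEpsilon", np.array([p.lj_epsilon for p in params]))
    hydro = per_atom(
        "HydrophobicWeight", np.array([p.hydrophobic_weight for p in params])
    )
    donor = per_atom("DonorFlag", donor.astype(float)).astype(bool)
    acceptor = per_atom("AcceptorFlag", acceptor.astype(float)).astype(bool)
    core: list[int] = []
    if mol.HasProp("core_atom_indices"):
        txt = mol.GetProp("core_atom_indices").strip()
        core = [int(t) for t in txt.split()] if txt else []
    return MoleculeRecord(
        id=mol_id,
        elements=elements,
        coords=coords,
        charges=charges,
        vdw_radius=vdw,
        lj_epsilon=eps,
        hydrophobic_weight=hydro,
        donor_flag=donor,
        acceptor_flag=acceptor,
        core_atom_indices=core,
    )


def _read_sdf(path: Path, charge_method: str, table) -> list[MoleculeRecord]:
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    records: list[MoleculeRecord] = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise FormatError(f"{path}: molecule entry {i + 1} failed to parse")
        mol_id = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        mol_id = mol_id or f"mol{i + 1}"
        records.append(_record_from_rdkit(mol, mol_id, charge_method, table))
    if not records:
        raise FormatError(f"{path}: no molecule entries found")
    return records


_MOL2_SECTION = re.compile(r"^@<TRIPOS>(\w+)")


def _read_mol2(path: Path, charge_method: str, table) -> list[MoleculeRecord]:
    """Minimal Tripos MOL2 reader: MOLECULE + ATOM records with the charge
    column. Element symbols are derived from the SYBYL atom type (text before
    the first dot)."""
    records: list[MoleculeRecord] = []
    name = None
    atoms: list[tuple[str, float, float, float, float | None]] = []
    section = None

    def flush() -> None:
        nonlocal atoms, name
        if name is None and not atoms:
            return
        if not atoms:
            raise FormatError(f"{path}: molecule {name!r} has no ATOM records")
        elements = [a[0] for a in atoms]
        coords = np.array([a[1:4] for a in atoms], dtype=float)
        raw_charges = [a[4] for a in atoms]
        if all(c is not None for c in raw_charges):
            charges = np.array(raw_charges, dtype=float)
        elif charge_method == "gasteiger":
            charges = np.zeros(len(atoms))
        else:
            raise FormatError(f"{path}: molecule {name!r} lacks a charge column")
        params = [element_params(sym, table) for sym in elements]
        records.append(
            MoleculeRecord(
                id=name or f"mol{len(records) + 1}",
                elements=elements,
                coords=coords,
                charges=charges,
                vdw_radius=np.array([p.vdw_radius for p in params]),
                lj_epsilon=np.array([p.lj_epsilon for p in params]),
                hydrophobic_weight=np.array([p.hydrophobic_weight for p in params]),
                # MOL2 carries no explicit H counts per heavy atom here; use the
                # element rule (N/O acceptors, donors resolved elsewhere).
                donor_flag=np.zeros(len(atoms), dtype=bool),
                acceptor_flag=np.array([s in ("N", "O") for s in elements]),
            )
        )
        atoms = []
        name = None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            m = _MOL2_SECTION.match(line)
            if m:
                sec = m.group(1)
                if sec == "MOLECULE":
                    flush()
                section = sec
                if section == "MOLECULE":
                    name = "PENDING"
                continue
            if section == "MOLECULE" and name == "PENDING" and line.strip():
                name = line.strip()
                continue
            if section == "ATOM" and line.strip():
                parts = line.split()
                if len(parts) < 6:
                    raise FormatError(f"{path}: malformed ATOM record at line {lineno}")
                sym = parts[5].split(".")[0].capitalize()
                try:
                    x, y, z = float(parts[2]), float(parts[3]), float(parts[4])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: bad coordinates at line {lineno}"
                    ) from exc
                charge = float(parts[8]) if len(parts) >= 9 else None
                atoms.append((sym, x, y, z, charge))
    flush()
    if not records:
        raise FormatError(f"{path}: no molecule entries found")
    return records


def read_molecules(
    path: str | Path,
    format: str | None = None,
    charge_method: str = "gasteiger",
    parameter_table: dict[str, ElementParams] | None = None,
) -> list[MoleculeRecord]:
    """Read aligned molecules from SDF V2000 or Tripos MOL2.

    ``format`` defaults to the file extension. Charges present in the file
    win; otherwise ``charge_method`` ("gasteiger" or "none") applies.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    table = parameter_table if parameter_table is not None else ELEMENT_TABLE
    if fmt == "sdf":
        return _read_sdf(path, charge_method, table)
    if fmt == "mol2":
        return _read_mol2(path, charge_method, table)
    raise FormatError(f"unsupported molecule format {fmt!r}")


def write_molecules(records: list[MoleculeRecord], path: str | Path) -> None:
    """Write records as SDF V2000 with per-atom charges in an
    ``atom.dprop.PartialCharge`` property list."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for rec in records:
            mol = Chem.RWMol()
            conf = Chem.Conformer(rec.n_atoms)
            for i, sym in enumerate(rec.elements):
                atom = Chem.Atom(sym)
                atom.SetNoImplicit(True)
                mol.AddAtom(atom)
                conf.SetAtomPosition(i, rec.coords[i].tolist())
            mol.AddConformer(conf)
            out = mol.GetMol()
            out.SetProp("_Name", rec.id)
            per_atom_double = {
                "PartialCharge": rec.charges,
                "VdwRadius": rec.vdw_radius,
                "LJEpsilon": rec.lj_epsilon,
                "HydrophobicWeight": rec.hydrophobic_weight,
            }
            for prop, values in per_atom_double.items():
                for atom, v in zip(out.GetAtoms(), values):
                    atom.SetDoubleProp(prop, float(v))
                Chem.CreateAtomDoublePropertyList(out, prop)
            for prop, values in (
                ("DonorFlag", rec.donor_flag),
                ("AcceptorFlag", rec.acceptor_flag),
            ):
                for atom, v in zip(out.GetAtoms(), values):
                    atom.SetIntProp(prop, int(v))
                Chem.CreateAtomIntPropertyList(out, prop)
            if rec.core_atom_indices:
                out.SetProp(
                    "core_atom_indices", " ".join(str(i) for i in rec.core_atom_indices)
                )
            writer.write(out)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# activities


def ic50_to_pic50(ic50_nm) -> float | np.ndarray:
    """Convert IC50 in nM to pIC50 = -log10(IC50 in molar) = 9 - log10(nM)."""
    arr = np.asarray(ic50_nm, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("IC50 must be positive")
    out = 9.0 - np.log10(arr)
    return float(out) if np.isscalar(ic50_nm) else out


def pic50_to_ic50(pic50) -> float | np.ndarray:
    """Inverse of :func:`ic50_to_pic50` (returns nM)."""
    arr = np.asarray(pic50, dtype=float)
    out = np.power(10.0, 9.0 - arr)
    return float(out) if np.isscalar(pic50) else out


def _normalize_minus(text: str) -> str:
    return text.replace("−", "-").replace("–", "-")


def _read_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        buf = _io.StringIO(_normalize_minus(fh.read()))
    return pd.read_csv(buf, **kwargs)


def load_activity_table(path: str | Path) -> pd.DataFrame:
    """Load a compound activity CSV into the canonical schema
    ``compound_id, ic50, pic50, set_label``.

    Either ``ic50`` (nM) or ``pic50`` may be absent per row; the other is
    derived. When both are present they must agree within 1e-6.
    """
    df = _read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "compound_id" not in df.columns:
        raise SchemaError("activity table must have a 'compound_id' column")
    if "ic50" not in df.columns and "pic50" not in df.columns:
        raise SchemaError("activity table needs an 'ic50' or 'pic50' column")
    out = pd.DataFrame({"compound_id": df["compound_id"].astype(str)})
    ic50 = pd.to_numeric(df["ic50"], errors="coerce") if "ic50" in df.columns else pd.Series(np.nan, index=df.index)
    pic50 = pd.to_numeric(df["pic50"], errors="coerce") if "pic50" in df.columns else pd.Series(np.nan, index=df.index)
    both = ic50.notna() & pic50.notna()
    if both.any():
        derived = 9.0 - np.log10(ic50[both])
        if np.max(np.abs(derived - pic50[both])) > 1e-6:
            bad = df.loc[both].loc[np.abs(derived - pic50[both]) > 1e-6, "compound_id"]
            raise ValueError(f"ic50/pic50 inconsistent for compounds: {list(bad)}")
    neither = ic50.isna() & pic50.isna()
    if neither.any():
        raise ValueError(
            f"rows without ic50 or pic50: {list(out.loc[neither, 'compound_id'])}"
        )
    pic50 = pic50.where(pic50.notna(), 9.0 - np.log10(ic50))
    ic50 = ic50.where(ic50.notna(), np.power(10.0, 9.0 - pic50))
    out["ic50"] = ic50.astype(float)
    out["pic50"] = pic50.astype(float)
    if "set_label" in df.columns:
        labels = df["set_label"].fillna("unassigned").astype(str)
        bad = ~labels.isin(SET_LABELS)
        if bad.any():
            raise ValueError(f"unknown set labels: {sorted(labels[bad].unique())}")
        out["set_label"] = labels
    else:
        out["set_label"] = "unassigned"
    return out


def split_dataset(table: pd.DataFrame, n_test: int, seed: int) -> pd.DataFrame:
    """Assign train/test labels by activity-stratified random sampling.

    Rows are ranked by pIC50 and cut into three equal-as-possible tertiles
    (high/medium/low activity); test compounds are drawn from each tertile
    proportionally, uniformly at random under ``seed``. Reproducible
    bit-exactly for a fixed seed.
    """
    if n_test >= len(table):
        raise ValueError("n_test must be smaller than the number of compounds")
    if table["pic50"].isna().any():
        raise ValueError("all rows need a pic50 for stratified splitting")
    out = table.copy()
    out["set_label"] = "train"
    if n_test == 0:
        return out
    order = np.argsort(-out["pic50"].to_numpy(), kind="stable")
    n = len(out)
    bounds = [round(i * n / 3) for i in range(4)]
    tertiles = [order[bounds[i] : bounds[i + 1]] for i in range(3)]
    # proportional allocation, largest-remainder on the fractional parts
    quotas = np.array([len(t) * n_test / n for t in tertiles])
    take = np.floor(quotas).astype(int)
    rem = n_test - take.sum()
    for idx in np.argsort(-(quotas - take), kind="stable")[:rem]:
        take[idx] += 1
    rng = np.random.default_rng(seed)
    test_rows: list[int] = []
    for t, k in zip(tertiles, take):
        if len(t) - k < 1:
            raise ValueError(
                "n_test would leave an activity tertile without training compounds"
            )
        test_rows.extend(rng.choice(t, size=k, replace=False).tolist())
    out.iloc[test_rows, out.columns.get_loc("set_label")] = "test"
    return out


# ---------------------------------------------------------------------------
# energy tables


_ENERGY_ALIASES = {
    "frame": "frame",
    "vdwaals": "vdwaals",
    "eel": "e_el",
    "e_el": "e_el",
    "epb": "e_pbgb",
    "e_pb": "e_pbgb",
    "egb": "e_pbgb",
    "e_gb": "e_pbgb",
    "esurf": "e_surf",
    "e_surf": "e_surf",
}


def read_energy_components(path: str | Path, label: str = "") -> EnergyFrameSeries:
    """Read a per-frame MM-PB(GB)SA component CSV.

    Header must contain frame, VDWAALS, EEL, EPB or EGB, and ESURF columns
    (case-insensitive, order-free). Both EPB and EGB map to the polar
    solvation component with the variant recorded.
    """
    df = _read_csv(path)
    rename: dict[str, str] = {}
    variant = None
    for col in df.columns:
        key = col.strip().lower().replace(" ", "")
        if key in _ENERGY_ALIASES:
            rename[col] = _ENERGY_ALIASES[key]
            if key in ("epb", "e_pb"):
                variant = "PB"
            elif key in ("egb", "e_gb"):
                variant = "GB"
    df = df.rename(columns=rename)
    missing = [c for c in EnergyFrameSeries.REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing energy column(s): {missing}")
    if len(df) == 0:
        raise FormatError(f"{path}: no frames")
    frames = df[list(EnergyFrameSeries.REQUIRED)].astype(float)
    frames["frame"] = frames["frame"].astype(int)
    return EnergyFrameSeries(
        frames=frames.reset_index(drop=True),
        label=label or Path(path).stem,
        variant=variant,
    )


# ---------------------------------------------------------------------------
# OpenDX scalar grids


def write_field_grid(values, grid, path: str | Path, name: str = "field") -> None:
    """Write grid-point scalar values as an OpenDX regular scalar field.

    ``values`` are in the package's x-fastest point order; OpenDX stores
    z-fastest, so the data block is re-ordered on write. Round-trips origin,
    spacing, dims exactly.
    """
    vals = np.asarray(values, dtype=float)
    nx, ny, nz = grid.dims
    if vals.size != nx * ny * nz:
        raise ValueError(
            f"value count {vals.size} does not match grid point count {nx * ny * nz}"
        )
    # x-fastest (C-order over (iz, iy, ix)) -> z-fastest (C-order over (ix, iy, iz))
    cube = vals.reshape(nz, ny, nx).transpose(2, 1, 0)
    flat = cube.reshape(-1)
    ox, oy, oz = grid.origin
    s = grid.spacing
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.6g} {oy:.6g} {oz:.6g}\n")
        fh.write(f"delta {s:.6g} 0 0\ndelta 0 {s:.6g} 0\ndelta 0 0 {s:.6g}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {flat.size} data follows\n"
        )
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write(f'object "{name}" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def read_field_grid(path: str | Path):
    """Read an OpenDX file written by :func:`write_field_grid`.

    Returns ``(values, grid)`` with values in x-fastest order.
    """
    from .fields import GridSpec

    dims = None
    origin = None
    deltas: list[float] = []
    data: list[float] = []
    n_items = None
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "object" and "gridpositions" in line:
                dims = (int(tok[-3]), int(tok[-2]), int(tok[-1]))
            elif tok[0] == "origin":
                origin = (float(tok[1]), float(tok[2]), float(tok[3]))
            elif tok[0] == "delta":
                deltas.append(max(float(t) for t in tok[1:4]))
            elif tok[0] == "object" and "data follows" in line:
                n_items = int(tok[tok.index("items") + 1])
            elif n_items is not None and len(data) < n_items:
                try:
                    data.extend(float(t) for t in tok)
                except ValueError:
                    continue
    if dims is None or origin is None or n_items is None:
        raise FormatError(f"{path}: not a recognizable OpenDX scalar grid")
    if len(data) != n_items:
        raise FormatError(f"{path}: expected {n_items} values, found {len(data)}")
    nx, ny, nz = dims
    cube = np.array(data).reshape(nx, ny, nz)
    vals = cube.transpose(2, 1, 0).reshape(-1)  # back to x-fastest
    grid = GridSpec(origin=origin, spacing=deltas[0], dims=dims)
    return vals, grid
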