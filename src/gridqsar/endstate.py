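"""End-state binding free energy aggregation.

This is the arithmetic/reporting layer over per-frame solver output (e.g.
gmx_MMPBSA component tables): it averages the final window of an MD
trajectory's interaction/solvation components, composes the gas-phase,
solvation and total binding energies, evaluates linear interaction energy
(LIE) estimates, and applies the distance/negligibility filter to
per-residue decomposition tables. No PB/GB solver and no trajectory
processing live here.

The composition follows the standard end-state identities

    dG_gas  = dE_vdW + dE_ele
    dG_solv = dG_PB|GB + dG_SA
    dTOTAL  = dG_gas + dG_solv

with the entropy term (-T dS) structurally excluded: a breakdown has no
entropy field, and an optional user-supplied adjustment is applied only on
request. LIE uses

    dG_bind = alpha * (<V_vdW>_bound - <V_vdW>_unbound)
            + beta  * (<V_ele>_bound - <V_ele>_unbound)

with the literature scaling factors alpha = 0.181 and beta = 0.43 for
neutral ligands as defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import EnergyFrameSeries

LIE_ALPHA = 0.181
LIE_BETA = 0.43

COMPONENTS = ("vdwaals", "e_el", "e_pbgb", "e_surf")


@dataclass
class EnergyBreakdown:
    """Mean MM-PB(GB)SA components and their composed totals, kcal/mol."""

    vdwaals: float
    e_el: float
    e_pbgb: float
    e_surf: float
    dg_gas: float
    dg_solv: float
    dtotal: float
    n_frames: int
    variant: str = "GB"
    label: str = ""

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Table-style view rounded for report parity; full precision stays
        in the dataclass fields."""
        return {
            "VDWAALS": round(self.vdwaals, ndigits),
            "E_EL": round(self.e_el, ndigits),
            f"E_{self.variant}": round(self.e_pbgb, ndigits),
            "E_SURF": round(self.e_surf, ndigits),
            "dG_gas": round(self.dg_gas, ndigits),
            "dG_solv": round(self.dg_solv, ndigits),
            "dTOTAL": round(self.dtotal, ndigits),
        }

    def with_entropy(self, minus_t_delta_s: float) -> float:
        """Total with a user-supplied -T*dS adjustment (applied on request
        only; never stored)."""
        return self.dtotal + minus_t_delta_s


@dataclass
class LieResult:
    bound_vdw_mean: float
    unbound_vdw_mean: float
    bound_ele_mean: float
    unbound_ele_mean: float
    alpha: float
    beta: float
    dg_bind: float


def average_components(series: EnergyFrameSeries, last_n: int = 200) -> dict[str, float]:
    """Arithmetic mean of each component over the final ``last_n`` frames."""
    if last_n < 1:
        raise ValueError("last_n must be >= 1")
    if len(series) < last_n:
        raise ValueError(
            f"series has {len(series)} frames, fewer than the requested {last_n}"
        )
    tail = series.frames.iloc[-last_n:]
    out = {c: float(tail[c].mean()) for c in COMPONENTS}
    out["n_frames"] = last_n
    return out


def mmpbsa_total(
    means: dict[str, float], variant: str = "GB", label: str = ""
) -> EnergyBreakdown:
    """Compose component means into the gas/solvation/total breakdown."""
    missing = [c for c in COMPONENTS if c not in means]
    if missing:
        raise ValueError(f"missing energy components: {missing}")
    vdw, eel = float(means["vdwaals"]), float(means["e_el"])
    pbgb, surf = float(means["e_pbgb"]), float(means["e_surf"])
    dg_gas = vdw + eel
    dg_solv = pbgb + surf
    return EnergyBreakdown(
        vdwaals=vdw,
        e_el=eel,
        e_pbgb=pbgb,
        e_surf=surf,
        dg_gas=dg_gas,
        dg_solv=dg_solv,
        dtotal=dg_gas + dg_solv,
        n_frames=int(means.get("n_frames", 0)),
        variant=variant,
        label=label,
    )


def aggregate_series(
    series: EnergyFrameSeries, last_n: int = 200, label: str = ""
) -> EnergyBreakdown:
    """Average the final window of a frame series and compose the totals."""
    means = average_components(series, last_n)
    return mmpbsa_total(
        means, variant=series.variant or "GB", label=label or series.label
    )


def lie_binding(
    bound: pd.DataFrame | dict,
    unbound: pd.DataFrame | dict,
    alpha: float = LIE_ALPHA,
    beta: float = LIE_BETA,
) -> LieResult:
    """LIE binding free energy from bound/unbound ligand-surroundings
    ensembles.

    Each ensemble is a table (or mapping of arrays) with ``vdw`` and ``ele``
    columns of per-frame energies, kcal/mol.
    """

    def _means(ens, name: str) -> tuple[float, float]:
        df = pd.DataFrame(ens)
        for col in ("vdw", "ele"):
            if col not in df.columns:
                raise ValueError(f"{name} ensemble lacks a {col!r} column")
        if len(df) == 0:
            raise ValueError(f"{name} ensemble is empty")
        return float(df["vdw"].mean()), float(df["ele"].mean())

    b_vdw, b_ele = _means(bound, "bound")
    u_vdw, u_ele = _means(unbound, "unbound")
    dg = alpha * (b_vdw - u_vdw) + beta * (b_ele - u_ele)
    return LieResult(
        bound_vdw_mean=b_vdw,
        unbound_vdw_mean=u_vdw,
        bound_ele_mean=b_ele,
        unbound_ele_mean=u_ele,
        alpha=alpha,
        beta=beta,
        dg_bind=dg,
    )


# ---------------------------------------------------------------------------
# per-residue decomposition


def _residue_sort_key(residue_id: str):
    digits = "".join(ch for ch in str(residue_id) if ch.isdigit())
    return (int(digits) if digits else 10**9, str(residue_id))


def per_residue_filter(
    decomp: pd.DataFrame, cutoff: float = 4.0, negligible: float = 0.05
) -> pd.DataFrame:
    """Apply the distance and negligibility rules to a decomposition table.

    Expects columns ``residue_id``, ``contribution`` (kcal/mol) and an
    optional ``min_distance`` (A). Rows farther than ``cutoff`` from the
    ligand, or with |contribution| below ``negligible``, get NA
    contributions; remaining rows are unchanged. Output is sorted by
    residue number.
    """
    df = decomp.copy()
    if "residue_id" not in df.columns or "contribution" not in df.columns:
        raise ValueError("decomposition needs residue_id and contribution columns")
    if len(df) == 0:
        return df
    contrib = pd.to_numeric(df["contribution"], errors="coerce")
    mask = contrib.abs() < negligible
    if "min_distance" in df.columns:
        dist = pd.to_numeric(df["min_distance"], errors="coerce")
        mask |= dist > cutoff
    df["contribution"] = contrib.where(~mask)
    df = df.sort_values(
        by="residue_id", key=lambda s: s.map(lambda r: _residue_sort_key(r))
    ).reset_index(drop=True)
    return df


def compare_breakdowns(a, b):
    """Term-wise difference ``a - b`` (NA-aware for decomposition tables).

    Accepts two :class:`EnergyBreakdown` objects (returns a dict of per-term
    differences) or two residue-decomposition tables with identical residue
    sets (returns a table; NA minus anything is NA).
    """
    if isinstance(a, EnergyBreakdown) and isinstance(b, EnergyBreakdown):
        return {
            name: getattr(a, name) - getattr(b, name)
            for name in ("vdwaals", "e_el", "e_pbgb", "e_surf", "dg_gas", "dg_solv", "dtotal")
        }
    if isinstance(a, pd.DataFrame) and isinstance(b, pd.DataFrame):
        if set(a.columns) != set(b.columns):
            raise ValueError("decomposition tables have different schemas")
        left = a.set_index("residue_id")
        right = b.set_index("residue_id")
        if set(left.index) != set(right.index):
            raise ValueError("decomposition tables cover different residues")
        diff = pd.DataFrame(index=left.index)
        diff["contribution"] = pd.to_numeric(
            left["contribution"], errors="coerce"
        ) - pd.to_numeric(right.loc[left.index, "contribution"], errors="coerce")
        return diff.reset_index()
    raise TypeError("compare_breakdowns expects two breakdowns or two tables")
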