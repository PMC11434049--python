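"""Paired expiration/inspiration dynamics of the gas-exchange unit.

Over a tidal cycle, geometric similarity is diagnosed by the
dimensionless shape factor k = S / V^(2/3) of the gas-exchange unit and
its ratio across the cycle, q = k_insp / k_exp: q = 1 means the unit
inflates like a balloon, q > 1 means the alveoli expand more than their
duct, q < 1 the reverse.  Tissue stretch is quantified by the membrane
area strain ΔS = (S_insp − S_exp)/S_exp, its linear-equivalent
ε = (1 + ΔS)^(1/2) − 1, the entrance-ring strain ε_ER computed directly
from ring perimeters, and the change in inter-alveolar angle
Δθ = θ_insp − θ_exp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, PairingError, SchemaError
from .morphometry import MorphometryRecord

__all__ = [
    "PairedDynamics",
    "shape_factor",
    "q_statistic",
    "area_strain",
    "linear_strain",
    "ring_strain",
    "delta_theta",
    "pair_structures",
    "compute_dynamics",
    "pair_angles",
]


def shape_factor(S: float, V: float) -> float:
    """k = S / V^(2/3); scale-invariant, minimal (≈4.8360) for a sphere."""
    if S <= 0 or V <= 0:
        raise DomainError("S and V must be positive")
    return float(S / V ** (2.0 / 3.0))


def q_statistic(
    unit_exp: MorphometryRecord, unit_insp: MorphometryRecord
) -> float:
    """Shape-change statistic q = k_insp / k_exp of the gas-exchange unit."""
    for rec, state in ((unit_exp, "expiration"), (unit_insp, "inspiration")):
        if rec.role != "unit_AAD":
            raise PairingError(
                f"{state} record has role {rec.role!r}, expected 'unit_AAD'"
            )
    if unit_exp.structure_id != unit_insp.structure_id:
        raise PairingError("unit records belong to different structures")
    return shape_factor(unit_insp.S, unit_insp.V) / shape_factor(
        unit_exp.S, unit_exp.V
    )


def area_strain(S_exp: float, S_insp: float) -> float:
    """ΔS = (S_insp − S_exp) / S_exp; negative values are allowed."""
    if S_exp <= 0:
        raise DomainError("S_exp must be positive")
    return float((S_insp - S_exp) / S_exp)


def linear_strain(dS: float) -> float:
    """ε = (1 + ΔS)^(1/2) − 1, the length-scale strain equivalent to ΔS."""
    if dS <= -1.0:
        raise DomainError("area strain must exceed -1")
    return float(np.sqrt(1.0 + dS) - 1.0)


def ring_strain(P_exp: float, P_insp: float) -> float:
    """ε_ER = (P_insp − P_exp) / P_exp from ring perimeters (already a length)."""
    if P_exp <= 0:
        raise DomainError("P_exp must be positive")
    return float((P_insp - P_exp) / P_exp)


def delta_theta(theta_exp: float, theta_insp: float) -> float:
    """Signed angle change Δθ = θ_insp − θ_exp in degrees."""
    for t in (theta_exp, theta_insp):
        if not 0.0 <= t <= 180.0:
            raise DomainError("angles must lie in [0, 180] degrees")
    return float(theta_insp - theta_exp)


@dataclass(frozen=True)
class PairedDynamics:
    """Unit-level dynamic quantities for one expiration/inspiration pair."""

    structure_id: int
    condition: dict
    k_exp: float
    k_insp: float
    q: float
    dS: float
    eps_A: float


_REQUIRED = {"structure_id", "role", "state", "V_um3", "S_um2"}


def _check_schema(df: pd.DataFrame):
    missing = _REQUIRED - set(df.columns)
    if missing:
        raise SchemaError(f"morphometry table lacks columns {sorted(missing)}")


def pair_structures(
    exp: pd.DataFrame,
    insp: pd.DataFrame,
    *,
    by: str = "structure_id",
    max_displacement_um: float = 30.0,
) -> pd.DataFrame:
    """Pair per-structure rows across the two states.

    With ``by="structure_id"`` (phantoms and tracked data) rows join on
    the persistent id; with ``by="centroid"`` alveoli are matched to the
    nearest centroid within ``max_displacement_um``.  Structures left
    unmatched are reported in the ``matched`` column, never dropped
    silently.
    """
    _check_schema(exp)
    _check_schema(insp)
    if by == "structure_id":
        merged = exp.merge(
            insp, on=["structure_id", "role"], suffixes=("_exp", "_insp"),
            how="outer", indicator="matched",
        )
        merged["matched"] = merged["matched"] == "both"
        return merged
    if by != "centroid":
        raise ValueError("by must be 'structure_id' or 'centroid'")
    from scipy.optimize import linear_sum_assignment

    rows = []
    for role in exp.role.unique():
        e = exp[exp.role == role].reset_index(drop=True)
        i = insp[insp.role == role].reset_index(drop=True)
        if e.empty or i.empty:
            continue
        ce = e[["cz", "cy", "cx"]].to_numpy()
        ci = i[["cz", "cy", "cx"]].to_numpy()
        d = np.linalg.norm(ce[:, None, :] - ci[None, :, :], axis=2)
        r_idx, c_idx = linear_sum_assignment(d)
        for a, b in zip(r_idx, c_idx):
            if d[a, b] <= max_displacement_um:
                row = pd.concat(
                    [e.loc[a].add_suffix("_exp"), i.loc[b].add_suffix("_insp")]
                )
                row["matched"] = True
                rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True)


def compute_dynamics(
    exp: pd.DataFrame,
    insp: pd.DataFrame,
    *,
    by: str = "structure_id",
) -> pd.DataFrame:
    """Per-structure dynamic quantities from two morphometry tables.

    Every matched structure gets its area strain ΔS (from the
    aperture-excluded surface ``S_um2``), the linear strain ε_A, the
    entrance-ring strain ε_ER where ring perimeters exist, and — for the
    unit row — k_exp, k_insp and q.
    """
    paired = pair_structures(exp, insp, by=by)
    out = []
    for _, row in paired.iterrows():
        if not row.get("matched", True):
            continue
        dS = area_strain(row["S_um2_exp"], row["S_um2_insp"])
        rec = {
            "structure_id": row["structure_id"],
            "role": row["role"],
            "PEEP": row.get("PEEP_exp", np.nan),
            "IPP": row.get("IPP_exp", np.nan),
            "dS": dS,
            "eps_A": linear_strain(dS),
            "dV_frac": (row["V_um3_insp"] - row["V_um3_exp"])
            / row["V_um3_exp"],
            "D_A_exp_um": row.get("D_A_um_exp", np.nan),
            "D_A_insp_um": row.get("D_A_um_insp", np.nan),
        }
        pe = row.get("ring_perimeter_um_exp", np.nan)
        pi = row.get("ring_perimeter_um_insp", np.nan)
        rec["eps_ER"] = (
            ring_strain(pe, pi)
            if np.isfinite(pe) and np.isfinite(pi)
            else np.nan
        )
        rec["k_exp"] = shape_factor(row["S_um2_exp"], row["V_um3_exp"])
        rec["k_insp"] = shape_factor(row["S_um2_insp"], row["V_um3_insp"])
        rec["q"] = rec["k_insp"] / rec["k_exp"]
        out.append(rec)
    return pd.DataFrame(out)


def pair_angles(
    angles_exp: pd.DataFrame, angles_insp: pd.DataFrame
) -> pd.DataFrame:
    """Join per-pair θ tables across states and add Δθ = θ_insp − θ_exp."""
    merged = angles_exp.merge(
        angles_insp, on=["id_a", "id_b"], suffixes=("_exp", "_insp")
    )
    merged["dtheta_deg"] = [
        delta_theta(te, ti)
        for te, ti in zip(merged["theta_deg_exp"], merged["theta_deg_insp"])
    ]
    return merged.rename(
        columns={
            "theta_deg_exp": "theta_exp_deg",
            "theta_deg_insp": "theta_insp_deg",
        }
    )
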