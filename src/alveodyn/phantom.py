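"""Synthetic gas-exchange-unit phantoms with exact ground truth.

A phantom unit is an alveolar duct — a cylinder of radius R and length L
with hemispherical end caps — carrying ``n_alveoli`` cup-shaped alveoli.
Each alveolus is the major spherical cap of a sphere of radius r cut by a
mouth plane held a short distance (``mouth_neck_um``) above the duct
surface; the circular cut of radius ``a = mouth_fraction * r`` is the
alveolar mouth (entrance ring).  The neck channel between the duct
surface and the mouth plane, inside the mouth cylinder, belongs to the
duct lumen, so the air spaces communicate through the mouth exactly as
the closed-form bookkeeping assumes, and the peri-mouth septum stays
resolvable at the working voxel size (the neck plays the role of the
fibrous entrance-ring rim of real alveoli).

All ground-truth morphometry (volumes, membrane areas, ring perimeters,
centroids, the unit shape factor k = S/V^(2/3) and shape-change statistic
q = k_insp/k_exp, and inter-alveolar angles θ) is computed from the
generating parameters — spherical-cap closed forms plus 1D quadratures
for the mouth-channel terms — never from meshes or voxels.

The inspiration state is derived from the expiration state by one of
three deformation modes:

``isotropic``
    every length scales by ``volume_ratio**(1/3)``; shape is preserved,
    so q = 1 and every θ is unchanged.
``alveolus_dominant``
    the duct (and with it every mouth) takes only a small share of the
    linear expansion while the alveolar radii scale more, deepening the
    cups: q > 1 and θ decreases.
``duct_dominant``
    the converse: the duct and mouths widen while alveoli barely grow,
    flattening the cups into the duct: q < 1 and θ increases.

In either anisotropic mode the free scale factor is solved so that the
whole-unit volume ratio V_insp/V_exp hits ``volume_ratio`` exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from .errors import DegenerateResolutionError, DomainError, PlacementError
from .labels import LabeledVolume
from .morphometry import SurfaceMesh, equivalent_diameter

__all__ = [
    "PhantomSpec",
    "PhantomState",
    "PhantomGroundTruth",
    "generate_unit",
    "voxelize",
    "render_grayscale",
    "MODE_CONDITIONS",
]

#: ventilation conditions (cm H2O) each deformation mode emulates:
#: duct-dominant expansion is the low-lung-volume regime, alveolus-
#: dominant the medium, isotropic the high.
MODE_CONDITIONS = {
    "duct_dominant": {"PEEP": 0.0, "IPP": 12.0},
    "alveolus_dominant": {"PEEP": 3.0, "IPP": 13.0},
    "isotropic": {"PEEP": 10.0, "IPP": 36.0},
}

_MODES = ("isotropic", "alveolus_dominant", "duct_dominant")


# ---------------------------------------------------------------------------
# closed forms and quadratures


def cap_volume(r: float, a: float) -> float:
    """Volume of the major spherical cap of radius ``r`` with mouth radius ``a``."""
    c = np.sqrt(r * r - a * a)
    h = r - c  # height of the discarded minor cap
    return 4.0 / 3.0 * np.pi * r**3 - np.pi * h * h * (3 * r - h) / 3.0


def cap_area(r: float, a: float) -> float:
    """Curved (membrane) area of the major cap, mouth disk excluded."""
    c = np.sqrt(r * r - a * a)
    return 4.0 * np.pi * r * r - 2.0 * np.pi * r * (r - c)


def cap_centroid_height(r: float, a: float) -> float:
    """Distance of the cap centroid from the sphere center, toward the pole."""
    c = np.sqrt(r * r - a * a)
    # centroid of a cap of height H = r + c, measured from the center
    return 3.0 * (r - c) ** 2 / (4.0 * (2.0 * r - c))


def _channel_volume(R: float, a: float, lift: float) -> float:
    """Air volume of the mouth channel between the duct cylinder surface
    and the mouth plane at radial distance R + lift."""
    f = lambda y: 2.0 * np.sqrt(max(a * a - y * y, 0.0)) * (
        R + lift - np.sqrt(R * R - y * y)
    )
    return quad(f, -a, a, limit=200)[0]


def _channel_wall_area(R: float, a: float, lift: float) -> float:
    """Lateral (tissue-facing) wall area of the mouth channel."""
    f = lambda phi: a * (
        R + lift - np.sqrt(max(R * R - (a * np.cos(phi)) ** 2, 0.0))
    )
    return quad(f, 0.0, 2.0 * np.pi, limit=200)[0]


def _duct_patch_area(R: float, a: float) -> float:
    """Area of the duct-cylinder surface patch opened by one mouth channel."""
    f = lambda y: 2.0 * np.sqrt(max(a * a - y * y, 0.0)) / np.sqrt(
        max(1.0 - (y / R) ** 2, 1e-300)
    )
    return quad(f, -a, a, limit=200)[0]


# ---------------------------------------------------------------------------
# spec


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic gas-exchange unit.

    Lengths in µm.  ``mouth_fraction`` is aperture radius over alveolar
    radius; ``volume_ratio`` the target whole-unit V_insp/V_exp;
    ``deformation_split`` the share of the isotropic linear scale given
    to the weaker-scaling compartment in the anisotropic modes;
    ``septum_gap`` the minimum tissue gap enforced between alveolar
    spheres (and toward the duct end caps) in both states.
    """

    duct_radius: float = 35.0
    duct_length: float = 160.0
    n_alveoli: int = 6
    alveolar_radius: float = 30.0
    alveolar_dispersion: float = 0.08
    mouth_fraction: float = 0.45
    placement_seed: int = 0
    deformation_mode: str = "isotropic"
    volume_ratio: float = 1.5
    voxel_spacing: float = 0.65
    noise_sd: float = 0.0
    deformation_split: float = 0.15
    septum_gap: float = 2.0
    mouth_neck_um: float = 1.5
    max_attempts: int = 10_000

    def __post_init__(self):
        if self.duct_radius <= 0 or self.duct_length <= 0:
            raise DomainError("duct dimensions must be positive")
        if self.alveolar_radius <= 0:
            raise DomainError("alveolar radius must be positive")
        if not 0.0 < self.mouth_fraction < 1.0:
            raise DomainError("mouth_fraction must lie in (0, 1)")
        if self.n_alveoli < 1:
            raise DomainError("n_alveoli must be >= 1")
        if self.volume_ratio <= 1.0:
            raise DomainError("volume_ratio must exceed 1")
        if self.deformation_mode not in _MODES:
            raise DomainError(
                f"deformation_mode must be one of {_MODES}"
            )
        if self.voxel_spacing <= 0:
            raise DomainError("voxel_spacing must be positive")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if not 0.0 <= self.deformation_split < 1.0:
            raise DomainError("deformation_split must lie in [0, 1)")
        if self.mouth_neck_um < 0:
            raise DomainError("mouth_neck_um must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls(**d)


@dataclass(frozen=True)
class _Alveolus:
    """One alveolus in one state: sphere radius, mouth radius, mouth
    azimuth (rad) and axial position of the mouth center."""

    r: float
    a: float
    phi: float
    z0: float

    @property
    def c(self) -> float:
        """Distance from sphere center to the mouth plane."""
        return float(np.sqrt(self.r**2 - self.a**2))


def _radial(phi: float) -> np.ndarray:
    """Outward unit vector of the mouth axis, (z, y, x) components."""
    return np.array([0.0, np.sin(phi), np.cos(phi)])


@dataclass(frozen=True)
class PhantomState:
    """Geometry of the unit in one respiratory state."""

    duct_radius: float
    duct_length: float
    alveoli: tuple[_Alveolus, ...]
    state: str
    mouth_lift: float = 1.5
    condition: dict = field(default_factory=dict)

    @property
    def mouth_plane_radius(self) -> float:
        """Radial distance of every mouth plane from the duct axis.

        The mouth plane floats ``mouth_lift`` above the duct surface: the
        aperture has a short neck, mimicking the fibrous entrance-ring
        rim and keeping the peri-mouth septum resolvable at the working
        voxel size.
        """
        return self.duct_radius + self.mouth_lift

    # -- analytic per-structure quantities ---------------------------------

    def mouth_center(self, i: int) -> np.ndarray:
        al = self.alveoli[i]
        return self.mouth_plane_radius * _radial(al.phi) + np.array(
            [al.z0, 0.0, 0.0]
        )

    def sphere_center(self, i: int) -> np.ndarray:
        al = self.alveoli[i]
        return (self.mouth_plane_radius + al.c) * _radial(al.phi) + np.array(
            [al.z0, 0.0, 0.0]
        )

    def alveolus_centroid(self, i: int) -> np.ndarray:
        al = self.alveoli[i]
        d = self.mouth_plane_radius + al.c + cap_centroid_height(al.r, al.a)
        return d * _radial(al.phi) + np.array([al.z0, 0.0, 0.0])

    def duct_volume(self) -> float:
        R, L = self.duct_radius, self.duct_length
        v = np.pi * R * R * L + 4.0 / 3.0 * np.pi * R**3
        v += sum(
            _channel_volume(R, al.a, self.mouth_lift)
            for al in self.alveoli
        )
        return v

    def duct_external_area(self) -> float:
        R, L = self.duct_radius, self.duct_length
        s = 2.0 * np.pi * R * L + 4.0 * np.pi * R * R
        for al in self.alveoli:
            s -= _duct_patch_area(R, al.a)
            s += _channel_wall_area(R, al.a, self.mouth_lift)
        return s

    def duct_centroid(self) -> np.ndarray:
        return np.zeros(3)

    def unit_volume(self) -> float:
        return self.duct_volume() + sum(
            cap_volume(al.r, al.a) for al in self.alveoli
        )

    def unit_area(self) -> float:
        return self.duct_external_area() + sum(
            cap_area(al.r, al.a) for al in self.alveoli
        )

    def shape_factor(self) -> float:
        return self.unit_area() / self.unit_volume() ** (2.0 / 3.0)

    def theta(self, i: int, j: int) -> float:
        """Inter-alveolar angle (deg) from the analytic geometry."""
        vertex = 0.5 * (self.mouth_center(i) + self.mouth_center(j))
        va = self.alveolus_centroid(i) - vertex
        vb = self.alveolus_centroid(j) - vertex
        cosang = np.clip(
            va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)), -1.0, 1.0
        )
        return float(np.degrees(np.arccos(cosang)))

    def septum(self, i: int) -> float:
        """Thinnest inter-alveolar tissue gap of alveolus ``i`` (µm)."""
        ci = self.sphere_center(i)
        gaps = [
            np.linalg.norm(ci - self.sphere_center(j))
            - self.alveoli[i].r
            - self.alveoli[j].r
            for j in range(len(self.alveoli))
            if j != i
        ]
        return float(min(gaps)) if gaps else np.nan

    # -- solids and meshes --------------------------------------------------

    def solids(self) -> dict[int, "Solid"]:
        """Implicit solids keyed by instance label (1 = duct lumen)."""
        out: dict[int, Solid] = {
            1: _DuctSolid(
                self.duct_radius, self.duct_length, self.alveoli,
                self.mouth_lift,
            )
        }
        for k, al in enumerate(self.alveoli):
            out[k + 2] = _CapSolid(self.mouth_plane_radius, al)
        return out

    def meshes(self, refinement: int = 4) -> dict[int, SurfaceMesh]:
        """Closed analytic triangle meshes keyed by instance label."""
        out = {
            1: _capsule_mesh(
                self.duct_radius, self.duct_length, refinement
            )
        }
        for k, al in enumerate(self.alveoli):
            out[k + 2] = _cap_mesh(self.mouth_plane_radius, al, refinement)
        return out


# ---------------------------------------------------------------------------
# implicit solids


class Solid:
    """Implicit solid: point-membership test plus an axis-aligned bound."""

    def contains(self, pts: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:  # pragma: no cover
        raise NotImplementedError


class _DuctSolid(Solid):
    """Capped cylinder plus the mouth-neck channels of its alveoli."""

    def __init__(self, R, L, alveoli, lift=0.0):
        self.R, self.L = R, L
        self.alveoli = alveoli
        self.lift = lift

    def contains(self, pts):
        z, y, x = pts[:, 0], pts[:, 1], pts[:, 2]
        rho2 = y * y + x * x
        R, L = self.R, self.L
        inside = (rho2 <= R * R) & (np.abs(z) <= L / 2)
        inside |= rho2 + (np.abs(z) - L / 2) ** 2 <= R * R
        for al in self.alveoli:
            u = _radial(al.phi)
            t = y * u[1] + x * u[2]
            p = -y * u[2] + x * u[1]
            w = z - al.z0
            inside |= (
                (p * p + w * w <= al.a * al.a)
                & (t < R + self.lift)
                & (t > 0)
            )
        return inside

    @property
    def bounds(self):
        R, L = self.R, self.L
        m = R + self.lift
        half = np.array([L / 2 + R, m, m])
        return -half, half


class _CapSolid(Solid):
    """Major spherical cap outside its mouth plane.

    ``D`` is the radial distance of the mouth plane from the duct axis
    (duct radius plus the mouth lift).
    """

    def __init__(self, D, alveolus):
        self.D = D
        self.al = alveolus

    def contains(self, pts):
        al = self.al
        u = _radial(al.phi)
        z, y, x = pts[:, 0], pts[:, 1], pts[:, 2]
        t = y * u[1] + x * u[2]
        p = -y * u[2] + x * u[1]
        w = z - al.z0
        d = self.D + al.c
        return ((t - d) ** 2 + p * p + w * w <= al.r * al.r) & (t >= self.D)

    @property
    def bounds(self):
        al = self.al
        center = self.sphere_center()
        lo = center - al.r
        hi = center + al.r
        return lo, hi

    def sphere_center(self):
        al = self.al
        return (self.D + al.c) * _radial(al.phi) + np.array(
            [al.z0, 0.0, 0.0]
        )


# ---------------------------------------------------------------------------
# analytic meshes


def _orient(mesh: SurfaceMesh) -> SurfaceMesh:
    return mesh.oriented_outward()


def _capsule_mesh(R: float, L: float, refinement: int) -> SurfaceMesh:
    """Cylinder with hemispherical end caps, axis along z, centered."""
    n_az = 8 * 2**refinement
    n_pol = max(4, n_az // 4)
    phi = np.linspace(0, 2 * np.pi, n_az, endpoint=False)
    rows = []
    # bottom pole cap (z from -L/2-R up to -L/2), then cylinder, then top
    # cap; the pole points and the cylinder-junction rings are not repeated
    pol = np.linspace(0, np.pi / 2, n_pol + 1)
    for th in pol[1:-1]:
        z = -L / 2 - R * np.cos(th)
        rr = R * np.sin(th)
        rows.append(np.column_stack(
            [np.full(n_az, z), rr * np.sin(phi), rr * np.cos(phi)]
        ))
    n_len = max(2, int(np.ceil(L / (2 * np.pi * R / n_az))))
    for z in np.linspace(-L / 2, L / 2, n_len + 1):
        rows.append(np.column_stack(
            [np.full(n_az, z), R * np.sin(phi), R * np.cos(phi)]
        ))
    for th in pol[1:-1][::-1]:
        z = L / 2 + R * np.cos(th)
        rr = R * np.sin(th)
        rows.append(np.column_stack(
            [np.full(n_az, z), rr * np.sin(phi), rr * np.cos(phi)]
        ))
    return _orient(_lathe_mesh(rows, n_az,
                               pole_lo=[-L / 2 - R, 0, 0],
                               pole_hi=[L / 2 + R, 0, 0]))


def _cap_mesh(R: float, alveolus: _Alveolus, refinement: int) -> SurfaceMesh:
    """Closed mesh of one alveolus: spherical cap plus flat mouth disk."""
    al = alveolus
    n_az = 8 * 2**refinement
    psi_max = np.arccos(-al.c / al.r)  # polar angle of the cut circle
    n_pol = max(4, int(np.ceil(n_az * psi_max / (2 * np.pi))) * 2)
    u = _radial(al.phi)
    e1 = np.array([1.0, 0.0, 0.0])  # duct axis direction
    e2 = np.cross(u, e1)
    e2 /= np.linalg.norm(e2)
    center = (R + al.c) * u + np.array([al.z0, 0.0, 0.0])
    phi = np.linspace(0, 2 * np.pi, n_az, endpoint=False)
    rows = []
    for psi in np.linspace(0, psi_max, n_pol + 1)[1:]:
        axial = al.r * np.cos(psi)
        rr = al.r * np.sin(psi)
        ring = (
            center[None, :]
            + axial * u[None, :]
            + rr * (np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2))
        )
        rows.append(ring)
    # the last ring lies on the mouth plane; close it with a fan disk
    pole = center + al.r * u
    mouth_center = center - al.c * u
    return _orient(_lathe_mesh(rows, n_az, pole_lo=pole, pole_hi=mouth_center))


def _lathe_mesh(rows, n_az, pole_lo, pole_hi) -> SurfaceMesh:
    """Stitch stacked vertex rings plus two pole points into a closed mesh."""
    verts = [np.asarray(pole_lo, float)[None, :]]
    verts.extend(rows)
    verts.append(np.asarray(pole_hi, float)[None, :])
    offsets = np.cumsum([0] + [len(v) for v in verts])
    V = np.vstack(verts)
    faces = []
    first = offsets[1]
    for j in range(n_az):
        faces.append([0, first + j, first + (j + 1) % n_az])
    for k in range(1, len(verts) - 2):
        a0, b0 = offsets[k], offsets[k + 1]
        for j in range(n_az):
            j1 = (j + 1) % n_az
            faces.append([a0 + j, b0 + j, b0 + j1])
            faces.append([a0 + j, b0 + j1, a0 + j1])
    last = offsets[-3]
    pole = offsets[-2]
    for j in range(n_az):
        faces.append([pole, last + (j + 1) % n_az, last + j])
    return SurfaceMesh(V, np.asarray(faces))


# ---------------------------------------------------------------------------
# ground truth


@dataclass(frozen=True)
class PhantomGroundTruth:
    """Analytic morphometry of a phantom unit in both states.

    ``structures`` has one row per structure per state with the same
    columns the measurement pipeline produces; ``units`` carries the
    whole-unit V, S and k per state; ``pairs`` every inter-alveolar angle
    in both states with its change Δθ.
    """

    structures: pd.DataFrame
    units: pd.DataFrame
    pairs: pd.DataFrame
    q_true: float
    scales: dict

    def unit_row(self, state: str) -> pd.Series:
        return self.units.set_index("state").loc[state]


def _state_truth_rows(st: PhantomState) -> list[dict]:
    rows = []
    rows.append(
        {
            "structure_id": 1,
            "role": "duct",
            "state": st.state,
            "V_um3": st.duct_volume(),
            "S_um2": st.duct_external_area(),
            "D_A_um": equivalent_diameter(st.duct_volume()),
            "T_A_um": np.nan,
            "ring_perimeter_um": np.nan,
            "cz": 0.0,
            "cy": 0.0,
            "cx": 0.0,
        }
    )
    for i, al in enumerate(st.alveoli):
        V = cap_volume(al.r, al.a)
        cz, cy, cx = st.alveolus_centroid(i)
        rows.append(
            {
                "structure_id": i + 2,
                "role": "alveolus",
                "state": st.state,
                "V_um3": V,
                "S_um2": cap_area(al.r, al.a),
                "D_A_um": equivalent_diameter(V),
                "T_A_um": st.septum(i),
                "ring_perimeter_um": 2.0 * np.pi * al.a,
                "cz": cz,
                "cy": cy,
                "cx": cx,
            }
        )
    return rows


def _compute_truth(
    exp: PhantomState, insp: PhantomState, scales: dict
) -> PhantomGroundTruth:
    structures = pd.DataFrame(
        _state_truth_rows(exp) + _state_truth_rows(insp)
    )
    units = pd.DataFrame(
        [
            {
                "state": st.state,
                "V_AAD_um3": st.unit_volume(),
                "S_AAD_um2": st.unit_area(),
                "k": st.shape_factor(),
            }
            for st in (exp, insp)
        ]
    )
    q_true = float(
        units.loc[units.state == "inspiration", "k"].iloc[0]
        / units.loc[units.state == "expiration", "k"].iloc[0]
    )
    pair_rows = []
    n = len(exp.alveoli)
    for i in range(n):
        for j in range(i + 1, n):
            te, ti = exp.theta(i, j), insp.theta(i, j)
            pair_rows.append(
                {
                    "id_a": i + 2,
                    "id_b": j + 2,
                    "theta_exp_deg": te,
                    "theta_insp_deg": ti,
                    "dtheta_deg": ti - te,
                }
            )
    pairs = pd.DataFrame(
        pair_rows,
        columns=[
            "id_a", "id_b", "theta_exp_deg", "theta_insp_deg", "dtheta_deg"
        ],
    )
    return PhantomGroundTruth(structures, units, pairs, q_true, scales)


# ---------------------------------------------------------------------------
# deformation


def _deformation_scales(spec: PhantomSpec, alveoli) -> tuple[float, float]:
    """Linear scale factors (duct, alveoli) realizing the volume ratio.

    The mouth radius always follows the duct scale (the aperture lives on
    the duct wall), so the anisotropic modes change how deep each cup is.
    """
    s_iso = spec.volume_ratio ** (1.0 / 3.0)
    if spec.deformation_mode == "isotropic":
        return s_iso, s_iso

    R, L = spec.duct_radius, spec.duct_length

    def total(s_d, s_a):
        st = PhantomState(
            s_d * R,
            s_d * L,
            tuple(
                replace(al, r=s_a * al.r, a=s_d * al.a, z0=s_d * al.z0)
                for al in alveoli
            ),
            state="x",
            mouth_lift=s_d * spec.mouth_neck_um,
        )
        return st.unit_volume()

    v_target = spec.volume_ratio * total(1.0, 1.0)
    lock = 1.0 + spec.deformation_split * (s_iso - 1.0)
    # mouths scale with the duct, so the duct scale must never push a
    # mouth radius past its (scaled) alveolar radius
    ratio_floor = min(al.r / al.a for al in alveoli)
    if spec.deformation_mode == "alveolus_dominant":
        s_d = lock
        s_a = brentq(lambda s: total(s_d, s) - v_target, 1.0, 4.0)
        if s_d / s_a >= ratio_floor:
            raise DomainError(
                "alveolus_dominant deformation is infeasible: a mouth "
                "would outgrow its alveolus; lower mouth_fraction"
            )
    else:  # duct_dominant
        s_a = lock
        hi = 0.999 * s_a * ratio_floor
        if total(hi, s_a) < v_target:
            raise DomainError(
                "duct_dominant deformation cannot reach volume_ratio "
                "before a mouth outgrows its alveolus; lower "
                "mouth_fraction or volume_ratio, or raise "
                "deformation_split"
            )
        s_d = brentq(lambda s: total(s, s_a) - v_target, 1.0, hi)
    return float(s_d), float(s_a)


def _scaled_state(
    spec: PhantomSpec, alveoli, s_d: float, s_a: float, state: str, condition
) -> PhantomState:
    scaled = []
    for al in alveoli:
        r, a = s_a * al.r, s_d * al.a
        if a >= r:
            raise DomainError(
                "deformation drove a mouth radius past its alveolar "
                "radius; lower mouth_fraction or deformation_split"
            )
        scaled.append(replace(al, r=r, a=a, z0=s_d * al.z0))
    return PhantomState(
        s_d * spec.duct_radius,
        s_d * spec.duct_length,
        tuple(scaled),
        state=state,
        mouth_lift=s_d * spec.mouth_neck_um,
        condition=dict(condition),
    )


# ---------------------------------------------------------------------------
# placement and generation


def _feasible(states: list[PhantomState], gap: float) -> bool:
    for st in states:
        n = len(st.alveoli)
        centers = [st.sphere_center(i) for i in range(n)]
        for i in range(n):
            ai = st.alveoli[i]
            # clearance from the hemispherical duct end caps
            for ze in (-st.duct_length / 2, st.duct_length / 2):
                d = np.linalg.norm(centers[i] - np.array([ze, 0, 0]))
                if d < ai.r + st.duct_radius + gap:
                    return False
            for j in range(i):
                aj = st.alveoli[j]
                if (
                    np.linalg.norm(centers[i] - centers[j])
                    < ai.r + aj.r + gap
                ):
                    return False
                # mouths must not overlap on the duct surface
                mi, mj = st.mouth_center(i), st.mouth_center(j)
                if np.linalg.norm(mi - mj) < ai.a + aj.a + 1.0:
                    return False
    return True


def generate_unit(
    spec: PhantomSpec,
) -> tuple[PhantomState, PhantomState, PhantomGroundTruth]:
    """Generate a two-state phantom unit with analytic ground truth.

    Alveolar radii are drawn once (normal, clipped at ±2 SD); mouths are
    placed by rejection sampling on the duct surface, requiring the
    tissue gap ``spec.septum_gap`` between alveolar spheres and clearance
    from the duct end caps *in both states*.  Deterministic for a fixed
    ``placement_seed``.

    Raises :class:`PlacementError` after ``spec.max_attempts`` rejected
    proposals — never a silent reduction of ``n_alveoli``.
    """
    rng = np.random.default_rng(spec.placement_seed)
    disp = np.clip(
        rng.standard_normal(spec.n_alveoli), -2.0, 2.0
    )
    radii = spec.alveolar_radius * (1.0 + spec.alveolar_dispersion * disp)
    if np.any(radii <= 0):
        raise DomainError("alveolar_dispersion produced nonpositive radii")

    proto = [
        _Alveolus(r=float(r), a=float(spec.mouth_fraction * r),
                  phi=0.0, z0=0.0)
        for r in radii
    ]
    if max(al.a for al in proto) >= spec.duct_radius:
        raise DomainError(
            "a mouth radius reaches the duct radius; shrink "
            "mouth_fraction or alveolar_radius, or widen the duct"
        )
    s_d, s_a = _deformation_scales(spec, tuple(proto))
    condition = MODE_CONDITIONS[spec.deformation_mode]

    placed: list[_Alveolus] = []
    attempts = 0
    zmax = spec.duct_length / 2
    while len(placed) < spec.n_alveoli:
        if attempts >= spec.max_attempts:
            raise PlacementError(
                spec.placement_seed, spec.n_alveoli, attempts
            )
        attempts += 1
        cand = replace(
            proto[len(placed)],
            phi=float(rng.uniform(0.0, 2.0 * np.pi)),
            z0=float(rng.uniform(-zmax, zmax)),
        )
        trial = placed + [cand]
        exp_try = PhantomState(
            spec.duct_radius, spec.duct_length, tuple(trial), "expiration",
            mouth_lift=spec.mouth_neck_um,
        )
        insp_try = _scaled_state(
            spec, tuple(trial), s_d, s_a, "inspiration", condition
        )
        if _feasible([exp_try, insp_try], spec.septum_gap):
            placed.append(cand)

    exp = PhantomState(
        spec.duct_radius,
        spec.duct_length,
        tuple(placed),
        state="expiration",
        mouth_lift=spec.mouth_neck_um,
        condition=dict(condition),
    )
    insp = _scaled_state(
        spec, tuple(placed), s_d, s_a, "inspiration", condition
    )
    truth = _compute_truth(
        exp, insp, {"s_duct": s_d, "s_alveoli": s_a}
    )
    return exp, insp, truth


# ---------------------------------------------------------------------------
# voxelization and rendering


def voxelize(
    structures: "PhantomState | dict[int, object]",
    spacing: float | tuple[float, float, float],
    *,
    margin_um: float = 2.0,
    min_voxels: int = 10,
    state: str | None = None,
    condition: dict | None = None,
) -> LabeledVolume:
    """Rasterize structures onto a voxel grid of the given spacing (µm).

    ``structures`` is a :class:`PhantomState` or a mapping from instance
    label to an implicit :class:`Solid`, a :class:`SurfaceMesh`, or a
    ``trimesh.Trimesh``.  Each voxel takes the label of the structure
    whose interior contains its center (structures are assumed
    interior-disjoint); the complement is tissue (label 0).  Voxel
    centers sit at ``origin + (index + 0.5) * spacing``.

    Raises :class:`DegenerateResolutionError` when any structure covers
    fewer than ``min_voxels`` voxels.
    """
    if isinstance(structures, PhantomState):
        if state is None:
            state = structures.state
        if condition is None:
            condition = structures.condition
        structures = structures.solids()
    state = state or "expiration"
    condition = condition or {}
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise DomainError("spacing must be positive")

    solids = {int(k): _as_solid(v) for k, v in structures.items()}
    if not solids:
        vol = np.zeros((1, 1, 1), dtype=np.int32)
        return LabeledVolume(vol, spacing, state=state, condition=condition)

    los, his = zip(*(s.bounds for s in solids.values()))
    lo = np.min(np.vstack(los), axis=0) - margin_um
    hi = np.max(np.vstack(his), axis=0) + margin_um
    sp = np.asarray(spacing)
    shape = np.ceil((hi - lo) / sp).astype(int)
    out = np.zeros(shape, dtype=np.int32)

    zc = lo[0] + (np.arange(shape[0]) + 0.5) * sp[0]
    yc = lo[1] + (np.arange(shape[1]) + 0.5) * sp[1]
    xc = lo[2] + (np.arange(shape[2]) + 0.5) * sp[2]
    Y, X = np.meshgrid(yc, xc, indexing="ij")
    plane = np.column_stack(
        [np.zeros(Y.size), Y.ravel(), X.ravel()]
    )
    for iz, z in enumerate(zc):  # slab-wise to bound memory
        plane[:, 0] = z
        slab = out[iz].ravel()
        for label, solid in solids.items():
            blo, bhi = solid.bounds
            if z < blo[0] - sp[0] or z > bhi[0] + sp[0]:
                continue
            inside = solid.contains(plane)
            slab[inside & (slab == 0)] = label
        out[iz] = slab.reshape(shape[1], shape[2])

    for label in solids:
        n = int((out == label).sum())
        if n < min_voxels:
            raise DegenerateResolutionError(
                f"structure {label} occupies {n} voxels (< {min_voxels}) "
                f"at spacing {spacing}"
            )
    return LabeledVolume(
        out,
        spacing,
        state=state,
        condition=condition,
        origin=tuple(float(v) for v in lo),
    )


def _as_solid(obj) -> Solid:
    if isinstance(obj, Solid):
        return obj
    if isinstance(obj, SurfaceMesh):
        return _MeshSolid(obj.to_trimesh())
    import trimesh as _tm

    if isinstance(obj, _tm.Trimesh):
        return _MeshSolid(obj)
    raise TypeError(f"cannot voxelize object of type {type(obj)!r}")


class _MeshSolid(Solid):
    """Point-membership for a closed mesh via per-slice cross-sections."""

    def __init__(self, mesh):
        self.mesh = mesh
        self._sections: dict[float, object] = {}

    @property
    def bounds(self):
        b = np.asarray(self.mesh.bounds)
        return b[0], b[1]

    def contains(self, pts):
        import shapely
        from shapely.ops import polygonize, unary_union
        import trimesh.intersections as tin

        pts = np.asarray(pts)
        z = pts[0, 0]  # slab-wise calls share one z
        key = round(float(z), 9)
        if key not in self._sections:
            segs = tin.mesh_plane(
                self.mesh,
                plane_normal=[1.0, 0.0, 0.0],
                plane_origin=[z, 0.0, 0.0],
            )
            if len(segs) == 0:
                self._sections[key] = None
            else:
                # snap endpoints so shared segment ends node exactly
                lines = [
                    shapely.LineString(np.round(s[:, 1:], 6))
                    for s in segs
                ]
                polys = list(polygonize(unary_union(lines)))
                self._sections[key] = (
                    unary_union(polys) if polys else None
                )
        region = self._sections[key]
        if region is None:
            return np.zeros(len(pts), dtype=bool)
        return shapely.contains_xy(region, pts[:, 1], pts[:, 2])


def render_grayscale(
    volume: LabeledVolume,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    air_value: float = 60.0,
    tissue_value: float = 200.0,
) -> np.ndarray:
    """Two-material grayscale rendering of a label volume.

    Air (any nonzero lumen label) maps to ``air_value``, tissue to
    ``tissue_value``; independent Gaussian noise of standard deviation
    ``noise_sd`` is added with the given seed (deterministic).
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    img = np.where(
        volume.voxels > 0, float(air_value), float(tissue_value)
    ).astype(np.float32)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(
            0.0, noise_sd, size=img.shape
        ).astype(np.float32)
    return img
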