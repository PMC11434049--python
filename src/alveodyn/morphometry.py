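"""Single-state 3D morphometry of alveoli and alveolar ducts.

All measures live in physical micrometres with axes ordered (z, y, x) and
voxel centers at ``(index + 0.5) * spacing``.

The volume of a closed triangulated surface is the sum of signed
tetrahedra spanned by the origin and each triangle (exact for polyhedra);
the surface area is the sum of triangle areas.  From the volume the
apparent (volume-equivalent sphere) diameter is D_A = (6V/π)^(1/3).
The thinnest septal wall thickness T_A comes from the Euclidean distance
transform of the tissue mask, sampled on the tissue ridge between an
alveolar lumen and any other air region.  The aperture of an alveolus —
its entrance ring — is the ordered boundary loop between the alveolar
membrane and the shared mouth with the duct; its polyline length is the
ring perimeter.  The inter-alveolar angle θ is measured at the midpoint
of two mouth centers, between the rays to the two lumen centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage
from skimage import measure as skmeasure

from .errors import (
    ClosednessError,
    DegenerateAngleError,
    DegenerateResolutionError,
    DomainError,
    ManifoldFailureError,
    NotAttachedError,
    UndefinedThicknessError,
    UnknownLabelError,
)
from .labels import DUCT_LABEL, LabeledVolume

__all__ = [
    "SurfaceMesh",
    "EntranceRing",
    "MorphometryRecord",
    "mesh_volume",
    "mesh_area",
    "equivalent_diameter",
    "extract_mesh",
    "detect_entrance_ring",
    "wall_thickness",
    "angle_between_alveoli",
    "assemble_unit",
    "measure_labels",
    "alveolar_angles",
    "records_to_frame",
]


# ---------------------------------------------------------------------------
# meshes


@dataclass(frozen=True)
class SurfaceMesh:
    """Closed, outward-oriented triangle mesh of one lumen structure.

    ``vertices`` are (n, 3) physical coordinates in µm, axis order
    (z, y, x); ``faces`` are (m, 3) vertex-index triples.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=float))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def closed(self) -> bool:
        """True when every edge is shared by exactly two faces."""
        e = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool((counts == 2).all())

    def oriented_outward(self) -> "SurfaceMesh":
        """Return a copy whose signed volume is positive."""
        if _signed_volume(self.vertices, self.faces) < 0:
            return SurfaceMesh(self.vertices, self.faces[:, ::-1])
        return self

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh) -> "SurfaceMesh":
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces))


def _signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    v0 = vertices[faces[:, 0]]
    v1 = vertices[faces[:, 1]]
    v2 = vertices[faces[:, 2]]
    return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


def mesh_volume(mesh: SurfaceMesh) -> float:
    """Volume (µm³) of a closed oriented mesh by signed tetrahedra.

    Each triangle spans a tetrahedron with the origin; the signed volumes
    sum to the enclosed volume, exactly for polyhedra and independent of
    the origin (translation invariance follows from closedness).
    """
    if not mesh.closed:
        raise ClosednessError("mesh_volume requires a closed mesh")
    return abs(_signed_volume(mesh.vertices, mesh.faces))


def mesh_area(mesh: SurfaceMesh) -> float:
    """Total triangle area (µm²)."""
    return _face_areas(mesh.vertices, mesh.faces).sum()


def _face_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v0 = vertices[faces[:, 0]]
    cross = np.cross(vertices[faces[:, 1]] - v0, vertices[faces[:, 2]] - v0)
    return 0.5 * np.linalg.norm(cross, axis=1)


def equivalent_diameter(volume_um3: float) -> float:
    """Apparent diameter D_A = (6V/π)^(1/3) of the volume-equivalent sphere."""
    if volume_um3 <= 0:
        raise DomainError("volume must be positive")
    return float((6.0 * volume_um3 / np.pi) ** (1.0 / 3.0))


def shape_factor_mesh(mesh: SurfaceMesh) -> float:
    """Dimensionless k = S / V^(2/3) of a closed mesh."""
    return mesh_area(mesh) / mesh_volume(mesh) ** (2.0 / 3.0)


# ---------------------------------------------------------------------------
# surface extraction from labels


def extract_mesh(
    labels: LabeledVolume,
    label: int | None = None,
    *,
    mask: np.ndarray | None = None,
    min_voxels: int = 10,
    smooth_iterations: int = 0,
) -> SurfaceMesh:
    """Marching-cubes isosurface (level 0.5) of one labeled structure.

    Either a ``label`` or an explicit boolean ``mask`` on the same grid
    may be given.  The indicator is padded with background so the surface
    is always closed; no smoothing is applied by default, so surface
    area carries the well-known staircase bias of binary marching cubes
    (volume does not, to first order).  ``smooth_iterations`` > 0 runs
    that many Taubin smoothing passes — this changes areas
    systematically and is therefore opt-in.  Vertices are returned in
    physical µm in the volume frame.  If the surface splits into several
    components the largest (by face count) is returned.
    """
    if mask is None:
        if label is None:
            raise ValueError("give either label or mask")
        if label not in labels.labels():
            raise UnknownLabelError(label)
        mask = labels.mask(label)
    mask = np.asarray(mask, bool)
    n_vox = int(mask.sum())
    if n_vox < min_voxels:
        raise DegenerateResolutionError(
            f"structure occupies {n_vox} voxels (< {min_voxels}); "
            "spacing is too coarse for surface extraction"
        )
    # crop to the bounding box (marching cubes cost scales with the grid)
    sl = ndimage.find_objects(mask.astype(np.int8))[0]
    lo = np.array([s.start for s in sl])
    sub = np.pad(mask[sl], 1).astype(np.float32)
    spacing = np.asarray(labels.spacing)
    verts, faces, _, _ = skmeasure.marching_cubes(sub, 0.5, spacing=tuple(spacing))
    # undo pad (-1 voxel), voxel-center convention (+0.5), crop offset, origin
    origin = np.asarray(getattr(labels, "origin", (0.0, 0.0, 0.0)))
    verts = verts + (lo - 0.5) * spacing + origin
    mesh = SurfaceMesh(verts, faces)
    if not mesh.closed:
        comp = _largest_component(mesh)
        if not comp.closed:
            raise ManifoldFailureError(
                "marching cubes produced an open surface"
            )
        mesh = comp
    else:
        mesh = _largest_component(mesh)
    if smooth_iterations > 0:
        from trimesh import smoothing

        tm = mesh.to_trimesh()
        smoothing.filter_taubin(tm, iterations=smooth_iterations)
        mesh = SurfaceMesh.from_trimesh(tm)
    return mesh.oriented_outward()


def _largest_component(mesh: SurfaceMesh) -> SurfaceMesh:
    tm = mesh.to_trimesh()
    parts = tm.split(only_watertight=False)
    if len(parts) <= 1:
        return mesh
    best = max(parts, key=lambda p: len(p.faces))
    return SurfaceMesh.from_trimesh(best)


# ---------------------------------------------------------------------------
# entrance ring


@dataclass(frozen=True)
class EntranceRing:
    """Ordered aperture boundary loop of one alveolus.

    ``loop`` is a closed polyline (first vertex repeated last) in µm;
    ``perimeter`` its length; ``mouth_center``/``mouth_normal`` the fitted
    aperture plane (normal pointing from the alveolus toward the duct);
    ``planarity_rms`` the RMS out-of-plane residual of the loop.
    """

    loop: np.ndarray
    perimeter: float
    mouth_center: np.ndarray
    mouth_normal: np.ndarray
    alveolus_id: int
    planarity_rms: float = 0.0
    membrane_area: float = field(default=np.nan)
    mouth_area: float = field(default=np.nan)


def detect_entrance_ring(
    labels: LabeledVolume,
    alveolus_id: int,
    duct_id: int = DUCT_LABEL,
    *,
    mesh: SurfaceMesh | None = None,
) -> EntranceRing:
    """Locate the aperture between an alveolus and the duct lumen.

    Mouth voxels are alveolar voxels 26-adjacent to duct voxels.  The
    closed marching-cubes surface of the alveolus is partitioned into
    mouth faces (those bordering duct air) and membrane faces; the ring
    is the ordered boundary loop between the two partitions, and its
    polyline length is the perimeter.  The membrane submesh area (the
    alveolar surface with the aperture cap excluded) is reported on the
    ring as ``membrane_area``.

    Raises ``NotAttachedError`` when the alveolus shares no aperture with
    the duct; emits a warning and keeps the largest loop when the
    aperture splits into several.
    """
    alv = labels.mask(alveolus_id)
    if not alv.any():
        raise UnknownLabelError(alveolus_id)
    duct = labels.mask(duct_id)
    near_duct = ndimage.binary_dilation(duct, np.ones((3, 3, 3), bool))
    if not (alv & near_duct).any():
        raise NotAttachedError(
            f"alveolus {alveolus_id} shares no aperture with duct {duct_id}"
        )
    if mesh is None:
        mesh = extract_mesh(labels, alveolus_id)

    is_mouth = _mouth_faces(mesh, labels, alveolus_id, duct_id)
    is_mouth = _clean_partition(mesh.faces, is_mouth)
    if not is_mouth.any():
        raise NotAttachedError(
            f"no mouth faces found for alveolus {alveolus_id}"
        )
    membrane_faces = mesh.faces[~is_mouth]
    mouth_faces = mesh.faces[is_mouth]

    loop_idx = _boundary_loops(membrane_faces)
    if len(loop_idx) == 0:
        raise NotAttachedError(
            f"aperture boundary of alveolus {alveolus_id} is degenerate"
        )
    loops = [mesh.vertices[np.asarray(li)] for li in loop_idx]
    lengths = [_polyline_length(lp, closed=True) for lp in loops]
    if len(loops) > 1:
        warnings.warn(
            f"alveolus {alveolus_id}: {len(loops)} disjoint aperture loops;"
            " keeping the largest",
            stacklevel=2,
        )
    best = int(np.argmax(lengths))
    pts = loops[best]
    closed_loop = np.vstack([pts, pts[:1]])

    center = pts.mean(axis=0)
    # plane fit: smallest principal direction of the loop cloud
    u, s, vt = np.linalg.svd(pts - center, full_matrices=False)
    normal = vt[-1]
    rms = float(np.sqrt(np.mean(((pts - center) @ normal) ** 2)))
    # the raw voxel-scale loop zigzags; the aperture perimeter is taken
    # from the convex hull of the loop projected into the mouth plane,
    # which is stable to staircase jitter and exact for convex apertures
    perimeter = _projected_hull_perimeter(pts, center, normal)
    if not np.isfinite(perimeter) or perimeter <= 0:
        perimeter = float(lengths[best])
    # orient the normal from alveolar centroid toward the duct side
    alv_centroid = _voxel_centroid(labels, alveolus_id)
    if np.dot(center - alv_centroid, normal) < 0:
        normal = -normal
    return EntranceRing(
        loop=closed_loop,
        perimeter=perimeter,
        mouth_center=center,
        mouth_normal=normal,
        alveolus_id=int(alveolus_id),
        planarity_rms=rms,
        membrane_area=float(_face_areas(mesh.vertices, membrane_faces).sum()),
        mouth_area=float(_face_areas(mesh.vertices, mouth_faces).sum()),
    )


def _mouth_faces(
    mesh: SurfaceMesh,
    labels: LabeledVolume,
    alveolus_id: int,
    duct_id: int,
) -> np.ndarray:
    """Boolean mask over faces: True where the face borders duct air.

    Each marching-cubes face separates a structure voxel from one
    complement voxel along its outward normal; the face is a mouth face
    when the voxel just outside it carries the duct label.
    """
    spacing = np.asarray(labels.spacing)
    origin = np.asarray(getattr(labels, "origin", (0.0, 0.0, 0.0)))
    tri = mesh.vertices[mesh.faces]
    cent = tri.mean(axis=1)
    normal = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(normal, axis=1, keepdims=True)
    normal = np.where(norm > 0, normal / np.maximum(norm, 1e-300), 0.0)
    shape = np.asarray(labels.voxels.shape)
    out = np.zeros(len(cent), dtype=bool)
    # probe a little outside the face (mesh is outward-oriented); two
    # probe depths make the lookup robust to centroid-rounding ties
    for step in (0.5, 1.0):
        probe = cent + step * spacing * normal
        idx = np.round((probe - origin) / spacing - 0.5).astype(int)
        np.clip(idx, 0, shape - 1, out=idx)
        lab = labels.voxels[idx[:, 0], idx[:, 1], idx[:, 2]]
        out |= lab == duct_id
    return out


def _projected_hull_perimeter(
    pts: np.ndarray, center: np.ndarray, normal: np.ndarray
) -> float:
    from scipy.spatial import ConvexHull, QhullError

    d = (pts - center) @ normal
    proj = pts - np.outer(d, normal)
    e1 = np.cross(normal, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-9:
        e1 = np.cross(normal, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    uv = np.column_stack([(proj - center) @ e1, (proj - center) @ e2])
    try:
        return float(ConvexHull(uv).area)  # 2D hull "area" is perimeter
    except (QhullError, ValueError):
        return np.nan


def _face_adjacency(faces: np.ndarray) -> list[list[int]]:
    """Edge-sharing neighbor faces of each face."""
    edges = np.sort(faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    owner = np.repeat(np.arange(len(faces)), 3)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges, owner = edges[order], owner[order]
    nbrs: list[list[int]] = [[] for _ in range(len(faces))]
    same = (np.diff(edges, axis=0) == 0).all(axis=1)
    for k in np.nonzero(same)[0]:
        a, b = int(owner[k]), int(owner[k + 1])
        nbrs[a].append(b)
        nbrs[b].append(a)
    return nbrs


def _clean_partition(faces: np.ndarray, is_mouth: np.ndarray) -> np.ndarray:
    """Regularize a mouth/membrane face labeling.

    Voxel-lookup speckle is removed by a few majority-vote passes over
    edge-adjacent faces, after which only the largest connected mouth
    patch is kept (an aperture is a single disk of faces).
    """
    nbrs = _face_adjacency(faces)
    lab = is_mouth.copy()
    for _ in range(3):
        votes = np.array(
            [lab[f] + sum(lab[n] for n in nbrs[f]) for f in range(len(lab))]
        )
        degree = np.array([1 + len(nbrs[f]) for f in range(len(lab))])
        lab = votes * 2 > degree
    if not lab.any():
        return lab
    # connected components of the mouth patch; keep the largest
    seen = np.zeros(len(lab), bool)
    best: list[int] = []
    for f0 in np.nonzero(lab)[0]:
        if seen[f0]:
            continue
        stack, comp = [int(f0)], []
        seen[f0] = True
        while stack:
            f = stack.pop()
            comp.append(f)
            for n in nbrs[f]:
                if lab[n] and not seen[n]:
                    seen[n] = True
                    stack.append(n)
        if len(comp) > len(best):
            best = comp
    out = np.zeros(len(lab), bool)
    out[best] = True
    return out


def _boundary_loops(faces: np.ndarray) -> list[list[int]]:
    """Ordered vertex loops bounding an open triangle-face subset."""
    edges = np.sort(faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    if len(boundary) == 0:
        return []
    nbr: dict[int, list[int]] = {}
    for a, b in boundary:
        nbr.setdefault(int(a), []).append(int(b))
        nbr.setdefault(int(b), []).append(int(a))
    seen: set[int] = set()
    loops = []
    for start in nbr:
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        prev, cur = None, start
        while True:
            nxt = [v for v in nbr[cur] if v != prev and v not in seen]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            loop.append(cur)
            seen.add(cur)
        if len(loop) >= 3:
            loops.append(loop)
    return loops


def _polyline_length(points: np.ndarray, closed: bool = False) -> float:
    d = np.diff(points, axis=0)
    total = np.linalg.norm(d, axis=1).sum()
    if closed:
        total += np.linalg.norm(points[0] - points[-1])
    return float(total)


def _voxel_centroid(labels: LabeledVolume, label: int) -> np.ndarray:
    idx = np.argwhere(labels.voxels == label)
    spacing = np.asarray(labels.spacing)
    origin = np.asarray(getattr(labels, "origin", (0.0, 0.0, 0.0)))
    return (idx.mean(axis=0) + 0.5) * spacing + origin


# ---------------------------------------------------------------------------
# wall thickness


def wall_thickness(
    labels: LabeledVolume,
    alveolus_id: int,
    *,
    ring_exclusion_um: float = 5.0,
) -> float:
    """Thinnest septal wall thickness T_A (µm) bordering one alveolus.

    The tissue mask is distance-transformed; every tissue voxel is
    attributed to its nearest air region.  Where the alveolus' tissue
    territory meets another air region's territory, each adjacent voxel
    pair spans the septum: the two distances to air sum to the local
    wall thickness, and T_A is the minimum of that sum over the ridge.
    Ridge voxels within ``ring_exclusion_um`` of the alveolar mouth are
    excluded: the tissue wedge at the aperture rim thins toward zero by
    construction and belongs to the entrance ring, not to a septum.
    """
    if alveolus_id not in labels.labels():
        raise UnknownLabelError(alveolus_id)
    tissue = labels.voxels == 0
    spacing = np.asarray(labels.spacing)
    edt, (iz, iy, ix) = ndimage.distance_transform_edt(
        tissue, sampling=spacing, return_indices=True
    )
    owner = labels.voxels[iz, iy, ix]  # nearest air label for tissue voxels
    own = tissue & (owner == alveolus_id)
    if not own.any():
        raise UndefinedThicknessError(
            f"alveolus {alveolus_id} has no adjacent tissue"
        )
    other = tissue & (owner != alveolus_id) & (owner > 0)
    # ridge: own-territory tissue voxels 26-adjacent to other-territory ones
    ridge = own & ndimage.binary_dilation(other, np.ones((3, 3, 3), bool))
    if ring_exclusion_um > 0:
        mouth = labels.mask(alveolus_id) & ndimage.binary_dilation(
            labels.mask(DUCT_LABEL), np.ones((3, 3, 3), bool)
        )
        if mouth.any():
            d_mouth = ndimage.distance_transform_edt(
                ~mouth, sampling=spacing
            )
            ridge &= d_mouth > ring_exclusion_um
    if not ridge.any():
        raise UndefinedThicknessError(
            f"alveolus {alveolus_id} has no septal ridge toward another "
            "air region"
        )
    # thickness across the ridge = own distance + facing territory's
    # distance, minimized over face-adjacent (6-connected) pairs; the
    # diagonal pairs of the 26-neighborhood would undercut the septum
    other_edt = np.where(other, edt, np.inf)
    cross = ndimage.generate_binary_structure(3, 1)
    facing = ndimage.minimum_filter(other_edt, footprint=cross)
    pair = edt[ridge] + facing[ridge]
    pair = pair[np.isfinite(pair)]
    if pair.size == 0:
        raise UndefinedThicknessError(
            f"alveolus {alveolus_id} has no face-adjacent septal pair"
        )
    return float(pair.min())


# ---------------------------------------------------------------------------
# records, angles, unit assembly


@dataclass
class MorphometryRecord:
    """Per-structure measures at one respiratory state."""

    structure_id: int
    role: str  # "alveolus" | "duct" | "unit_AAD"
    V: float  # µm³ (aperture-capped interior for alveoli)
    S: float  # µm² external/membrane area, shared apertures excluded
    D_A: float  # µm
    centroid: np.ndarray  # (z, y, x) µm
    state: str = "expiration"
    condition: dict = field(default_factory=dict)
    T_A: float = np.nan  # µm, alveoli only
    ring_perimeter: float = np.nan  # µm, alveoli only
    S_total: float = np.nan  # µm² closed-mesh area including apertures

    def __post_init__(self):
        if self.V <= 0 or self.S <= 0:
            raise DomainError("V and S must be positive")
        self.centroid = np.asarray(self.centroid, dtype=float)


def records_to_frame(records: list[MorphometryRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "structure_id": r.structure_id,
                "role": r.role,
                "state": r.state,
                "PEEP": r.condition.get("PEEP", np.nan),
                "IPP": r.condition.get("IPP", np.nan),
                "V_um3": r.V,
                "S_um2": r.S,
                "S_total_um2": r.S_total,
                "D_A_um": r.D_A,
                "T_A_um": r.T_A,
                "ring_perimeter_um": r.ring_perimeter,
                "cz": r.centroid[0],
                "cy": r.centroid[1],
                "cx": r.centroid[2],
            }
        )
    return pd.DataFrame(rows)


def angle_between_alveoli(
    a: MorphometryRecord,
    b: MorphometryRecord,
    ring_a: EntranceRing,
    ring_b: EntranceRing,
    *,
    method: str = "centroid",
) -> float:
    """Inter-alveolar angle θ in degrees, in [0, 180].

    With ``method="centroid"`` (default) the vertex is the midpoint of
    the two mouth centers and θ the angle between the rays from the
    vertex to the two lumen centroids; ``method="normals"`` instead
    measures the angle between the two mouth-plane normals.  Either way
    θ is invariant under rigid motion and uniform scaling.
    """
    if method == "normals":
        cosang = np.clip(
            float(ring_a.mouth_normal @ ring_b.mouth_normal), -1.0, 1.0
        )
        return float(np.degrees(np.arccos(cosang)))
    if method != "centroid":
        raise ValueError("method must be 'centroid' or 'normals'")
    vertex = 0.5 * (ring_a.mouth_center + ring_b.mouth_center)
    va = np.asarray(a.centroid) - vertex
    vb = np.asarray(b.centroid) - vertex
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0 or np.allclose(a.centroid, b.centroid):
        raise DegenerateAngleError("coincident centroids or vertex")
    cosang = np.clip(va @ vb / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def assemble_unit(
    alveoli: list[MorphometryRecord],
    duct: MorphometryRecord,
) -> MorphometryRecord:
    """Combine duct and attached alveoli into a gas-exchange-unit record.

    Volumes are additive (the aperture caps cancel between an alveolus
    and the duct), and because every record's ``S`` already excludes the
    shared aperture faces, the external surface of the union is the plain
    sum of the parts' ``S``.
    """
    V = duct.V + sum(a.V for a in alveoli)
    S = duct.S + sum(a.S for a in alveoli)
    w = np.array([duct.V] + [a.V for a in alveoli])
    cents = np.vstack([duct.centroid] + [a.centroid for a in alveoli])
    centroid = (w[:, None] * cents).sum(axis=0) / w.sum()
    return MorphometryRecord(
        structure_id=duct.structure_id,
        role="unit_AAD",
        V=V,
        S=S,
        D_A=equivalent_diameter(V),
        centroid=centroid,
        state=duct.state,
        condition=duct.condition,
    )


def measure_labels(
    labels: LabeledVolume,
    *,
    duct_id: int = DUCT_LABEL,
    ring_exclusion_um: float = 5.0,
    measure_thickness: bool = True,
) -> tuple[list[MorphometryRecord], dict[int, EntranceRing]]:
    """Measure every labeled structure and the whole gas-exchange unit.

    Returns the per-structure records (duct first, then alveoli by label,
    then the assembled ``unit_AAD`` record measured directly on the union
    air mask) and the entrance ring of every attached alveolus.

    The duct's ``S`` excludes its aperture interfaces with alveoli so
    that unit surface assembly stays additive; each alveolar ``S`` is the
    membrane area from its ring partition.
    """
    ids = [int(i) for i in labels.labels()]
    if duct_id not in ids:
        raise UnknownLabelError(duct_id)
    records: list[MorphometryRecord] = []
    rings: dict[int, EntranceRing] = {}

    duct_mesh = extract_mesh(labels, duct_id)
    duct_V = mesh_volume(duct_mesh)
    duct_S_total = mesh_area(duct_mesh)
    # duct aperture interfaces: faces of the duct surface bordering alveoli
    is_aperture = np.zeros(len(duct_mesh.faces), bool)
    for aid in ids:
        if aid == duct_id:
            continue
        is_aperture |= _mouth_faces(duct_mesh, labels, duct_id, aid)
    duct_S_ext = float(
        _face_areas(duct_mesh.vertices, duct_mesh.faces[~is_aperture]).sum()
    )
    duct_rec = MorphometryRecord(
        structure_id=duct_id,
        role="duct",
        V=duct_V,
        S=duct_S_ext,
        S_total=duct_S_total,
        D_A=equivalent_diameter(duct_V),
        centroid=_voxel_centroid(labels, duct_id),
        state=labels.state,
        condition=labels.condition,
    )
    records.append(duct_rec)

    alv_records = []
    for aid in ids:
        if aid == duct_id:
            continue
        mesh = extract_mesh(labels, aid)
        V = mesh_volume(mesh)
        S_total = mesh_area(mesh)
        try:
            ring = detect_entrance_ring(labels, aid, duct_id, mesh=mesh)
            rings[aid] = ring
            S = ring.membrane_area
            perim = ring.perimeter
        except NotAttachedError:
            S = S_total
            perim = np.nan
        T = np.nan
        if measure_thickness:
            try:
                T = wall_thickness(
                    labels, aid, ring_exclusion_um=ring_exclusion_um
                )
            except UndefinedThicknessError:
                T = np.nan
        rec = MorphometryRecord(
            structure_id=aid,
            role="alveolus",
            V=V,
            S=S,
            S_total=S_total,
            D_A=equivalent_diameter(V),
            T_A=T,
            ring_perimeter=perim,
            centroid=_voxel_centroid(labels, aid),
            state=labels.state,
            condition=labels.condition,
        )
        records.append(rec)
        alv_records.append(rec)

    # unit measured directly on the union air mask
    union_mesh = extract_mesh(labels, mask=labels.air_mask())
    unit = MorphometryRecord(
        structure_id=0,
        role="unit_AAD",
        V=mesh_volume(union_mesh),
        S=mesh_area(union_mesh),
        D_A=equivalent_diameter(mesh_volume(union_mesh)),
        centroid=_voxel_centroid_mask(labels),
        state=labels.state,
        condition=labels.condition,
    )
    records.append(unit)
    return records, rings


def _voxel_centroid_mask(labels: LabeledVolume) -> np.ndarray:
    idx = np.argwhere(labels.voxels > 0)
    spacing = np.asarray(labels.spacing)
    origin = np.asarray(getattr(labels, "origin", (0.0, 0.0, 0.0)))
    return (idx.mean(axis=0) + 0.5) * spacing + origin


def alveolar_angles(
    records: list[MorphometryRecord],
    rings: dict[int, EntranceRing],
) -> pd.DataFrame:
    """θ for every pair of ring-attached alveoli, as a tidy table."""
    alv = {r.structure_id: r for r in records if r.role == "alveolus"}
    rows = []
    ids = sorted(set(alv) & set(rings))
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            theta = angle_between_alveoli(
                alv[a], alv[b], rings[a], rings[b]
            )
            rows.append({"id_a": a, "id_b": b, "theta_deg": theta})
    return pd.DataFrame(rows, columns=["id_a", "id_b", "theta_deg"])
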