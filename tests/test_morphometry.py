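"""Mesh integration, surface extraction, rings, wall thickness, angles."""

import numpy as np
import pytest
import trimesh

from alveodyn import phantom as ph
from alveodyn.errors import (
    ClosednessError,
    DegenerateResolutionError,
    DomainError,
    NotAttachedError,
    UnknownLabelError,
)
from alveodyn.morphometry import (
    SurfaceMesh,
    assemble_unit,
    angle_between_alveoli,
    detect_entrance_ring,
    equivalent_diameter,
    extract_mesh,
    measure_labels,
    mesh_area,
    mesh_volume,
    MorphometryRecord,
    records_to_frame,
    wall_thickness,
)

from conftest import ball_mask, desk_spec, make_volume

SPHERE_K = (36.0 * np.pi) ** (1.0 / 3.0)  # 6^(2/3) π^(1/3)


def cube_mesh(side=10.0):
    tm = trimesh.creation.box(extents=(side, side, side))
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def icosphere(radius, subdivisions=4):
    tm = trimesh.creation.icosphere(
        subdivisions=subdivisions, radius=radius
    )
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


class TestMeshIntegrals:
    def test_cube_exact(self):
        m = cube_mesh(10.0)
        assert mesh_volume(m) == pytest.approx(1000.0, rel=1e-12)
        assert mesh_area(m) == pytest.approx(600.0, rel=1e-12)

    def test_unit_tetrahedron(self):
        verts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float
        )
        faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
        m = SurfaceMesh(verts, faces).oriented_outward()
        assert mesh_volume(m) == pytest.approx(1 / 6, rel=1e-12)

    def test_single_triangle_area(self):
        m = SurfaceMesh(
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float),
            np.array([[0, 1, 2]]),
        )
        assert mesh_area(m) == pytest.approx(0.5, rel=1e-12)

    def test_icosphere_within_half_percent(self):
        m = icosphere(25.0, subdivisions=4)
        assert mesh_volume(m) == pytest.approx(65449.85, rel=5e-3)
        assert mesh_area(m) == pytest.approx(7853.98, rel=5e-3)

    def test_translation_and_rotation_invariance(self):
        m = icosphere(5.0, subdivisions=2)
        v0 = mesh_volume(m)
        shifted = SurfaceMesh(m.vertices + [113.0, -40.0, 7.5], m.faces)
        assert mesh_volume(shifted) == pytest.approx(v0, rel=1e-12)
        th = 0.7
        rot = np.array(
            [
                [1, 0, 0],
                [0, np.cos(th), -np.sin(th)],
                [0, np.sin(th), np.cos(th)],
            ]
        )
        rotated = SurfaceMesh(m.vertices @ rot.T, m.faces)
        assert mesh_volume(rotated) == pytest.approx(v0, rel=1e-10)

    def test_scaling_laws(self):
        m = icosphere(5.0, subdivisions=2)
        s = 1.7
        scaled = SurfaceMesh(m.vertices * s, m.faces)
        assert mesh_volume(scaled) == pytest.approx(
            s**3 * mesh_volume(m), rel=1e-12
        )
        assert mesh_area(scaled) == pytest.approx(
            s**2 * mesh_area(m), rel=1e-12
        )

    def test_open_mesh_rejected(self):
        m = cube_mesh()
        open_mesh = SurfaceMesh(m.vertices, m.faces[:-1])
        with pytest.raises(ClosednessError):
            mesh_volume(open_mesh)

    def test_agrees_with_trimesh_oracle(self):
        """Cross-check the signed-tetrahedron sum against trimesh."""
        tm = trimesh.creation.capsule(radius=4.0, height=12.0)
        m = SurfaceMesh(
            np.asarray(tm.vertices), np.asarray(tm.faces)
        ).oriented_outward()
        assert mesh_volume(m) == pytest.approx(tm.volume, rel=1e-10)
        assert mesh_area(m) == pytest.approx(tm.area, rel=1e-10)


class TestEquivalentDiameter:
    @pytest.mark.parametrize("d", [50.0, 100.0])
    def test_inverts_sphere_volume(self, d):
        assert equivalent_diameter(np.pi / 6 * d**3) == pytest.approx(d)

    def test_unit_volume(self):
        d = equivalent_diameter(1.0)
        assert d == pytest.approx(1.2407, abs=1e-4)
        assert np.pi / 6 * d**3 == pytest.approx(1.0, rel=1e-12)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            equivalent_diameter(0.0)


class TestExtractMesh:
    def test_voxel_sphere_volume(self):
        from conftest import SphereSolid

        vol = ph.voxelize({1: SphereSolid(25.0)}, 0.65)
        m = extract_mesh(vol, 1)
        assert m.closed
        assert mesh_volume(m) == pytest.approx(65449.85, rel=0.015)

    def test_voxel_box_volume(self):
        v = np.zeros((26, 26, 26), np.int32)
        v[3:23, 3:23, 3:23] = 1
        m = extract_mesh(make_volume(v, 1.0), 1)
        assert mesh_volume(m) == pytest.approx(8000.0, rel=0.02)

    def test_one_voxel_structure_rejected(self):
        v = np.zeros((5, 5, 5), np.int32)
        v[2, 2, 2] = 1
        with pytest.raises(DegenerateResolutionError):
            extract_mesh(make_volume(v), 1)

    def test_unknown_label(self, desk_labels):
        with pytest.raises(UnknownLabelError):
            extract_mesh(desk_labels[0], 99)

    def test_taubin_smoothing_reduces_area_bias(self):
        from conftest import SphereSolid

        vol = ph.voxelize({1: SphereSolid(10.0)}, 0.65)
        S_true = 4 * np.pi * 100.0
        raw = abs(mesh_area(extract_mesh(vol, 1)) - S_true)
        smoothed = abs(
            mesh_area(extract_mesh(vol, 1, smooth_iterations=10)) - S_true
        )
        assert smoothed < raw

    def test_volume_matches_voxel_count(self, desk_labels):
        lab = desk_labels[0]
        for lbl in lab.labels():
            vox = (lab.voxels == lbl).sum() * lab.voxel_volume
            assert mesh_volume(extract_mesh(lab, lbl)) == pytest.approx(
                vox, rel=0.02
            )


class TestEntranceRing:
    def test_circular_mouth_perimeter(self):
        """Single alveolus with 15 µm mouth: perimeter ≈ 2π·15 = 94.248."""
        spec = desk_spec(
            n_alveoli=1,
            duct_radius=18.0,
            duct_length=50.0,
            alveolar_radius=20.0,
            mouth_fraction=0.75,
            alveolar_dispersion=0.0,
            voxel_spacing=0.8,
        )
        exp, _, truth = ph.generate_unit(spec)
        assert exp.alveoli[0].a == pytest.approx(15.0)
        lab = ph.voxelize(exp, spec.voxel_spacing)
        ring = detect_entrance_ring(lab, 2)
        assert ring.perimeter == pytest.approx(94.248, rel=0.02)
        assert ring.planarity_rms < 2 * spec.voxel_spacing

    def test_square_aperture_on_box_phantom(self):
        """10 µm square window between two boxes gives perimeter ≈ 40."""
        v = np.zeros((40, 30, 30), np.int32)
        v[4:18, 5:25, 5:25] = 1  # duct box
        v[21:36, 8:22, 8:22] = 2  # alveolus box
        v[18:21, 10:20, 10:20] = 2  # 10x10 neck connecting the two
        ring = detect_entrance_ring(make_volume(v, 1.0), 2)
        assert ring.perimeter == pytest.approx(40.0, rel=0.05)

    def test_phantom_ring_matches_truth(self, desk_unit, desk_labels):
        _, exp, _, truth = desk_unit
        lab = desk_labels[0]
        for i, al in enumerate(exp.alveoli):
            ring = detect_entrance_ring(lab, i + 2)
            assert ring.perimeter == pytest.approx(
                2 * np.pi * al.a, rel=0.04
            )
            # mouth center sits on the mouth plane
            assert np.linalg.norm(
                ring.mouth_center - exp.mouth_center(i)
            ) < 2.0

    def test_detached_alveolus_raises(self):
        v = np.zeros((20, 20, 20), np.int32)
        v[2:6, 2:6, 2:6] = 1
        v[12:18, 12:18, 12:18] = 2  # not touching the duct
        with pytest.raises(NotAttachedError):
            detect_entrance_ring(make_volume(v), 2)


class TestWallThickness:
    def test_parallel_slabs(self):
        """5-voxel tissue slab at 0.65 µm: T = 3.25 µm ± 1 voxel."""
        v = np.zeros((30, 12, 12), np.int32)
        v[2:12] = 1
        v[17:28] = 2
        lab = make_volume(v, 0.65)
        t = wall_thickness(lab, 2, ring_exclusion_um=0)
        assert t == pytest.approx(5 * 0.65, abs=0.65)

    def test_concentric_shell(self):
        """Air shell around an air core separated by 4 µm of tissue."""
        shape = (42, 42, 42)
        inner = ball_mask(shape, (21, 21, 21), 8)
        outer = ball_mask(shape, (21, 21, 21), 12)
        beyond = ball_mask(shape, (21, 21, 21), 17)
        v = np.zeros(shape, np.int32)
        v[inner] = 2
        v[beyond & ~outer] = 1
        lab = make_volume(v, 1.0)
        t = wall_thickness(lab, 2, ring_exclusion_um=0)
        assert t == pytest.approx(4.0, abs=1.0)

    def test_phantom_septum_matches_truth(self):
        """Close alveolus pair: measured T_A hits the known sphere gap."""
        spec = desk_spec(
            n_alveoli=2,
            placement_seed=5,
            septum_gap=2.6,
            alveolar_dispersion=0.0,
        )
        exp, _, truth = ph.generate_unit(spec)
        gap = exp.septum(0)
        lab = ph.voxelize(exp, spec.voxel_spacing)
        t = wall_thickness(lab, 2, ring_exclusion_um=5.0)
        assert t <= gap + 2 * spec.voxel_spacing

    def test_unknown_label(self, desk_labels):
        with pytest.raises(UnknownLabelError):
            wall_thickness(desk_labels[0], 99)


class TestAngles:
    @staticmethod
    def _measured_theta(phi_sep):
        al = ph._Alveolus(r=8.0, a=3.6, phi=0.0, z0=0.0)
        state = ph.PhantomState(
            duct_radius=10.0,
            duct_length=40.0,
            alveoli=(
                al,
                ph._Alveolus(r=8.0, a=3.6, phi=phi_sep, z0=0.0),
            ),
            state="expiration",
            mouth_lift=1.5,
        )
        lab = ph.voxelize(state, 0.8)
        records, rings = measure_labels(lab, measure_thickness=False)
        alv = {r.structure_id: r for r in records if r.role == "alveolus"}
        return angle_between_alveoli(
            alv[2], alv[3], rings[2], rings[3]
        ), state.theta(0, 1)

    def test_right_angle_placement(self):
        measured, analytic = self._measured_theta(np.pi / 2)
        assert measured == pytest.approx(analytic, abs=2.0)

    def test_antipodal_placement(self):
        measured, analytic = self._measured_theta(np.pi)
        assert analytic == pytest.approx(180.0, abs=1e-9)
        assert measured == pytest.approx(180.0, abs=2.0)

    def test_scale_invariance_exact(self):
        rec = lambda i, c: MorphometryRecord(
            structure_id=i, role="alveolus", V=1.0, S=1.0, D_A=1.0,
            centroid=c,
        )
        from alveodyn.morphometry import EntranceRing

        ring = lambda c: EntranceRing(
            loop=np.zeros((4, 3)), perimeter=1.0, mouth_center=np.array(c),
            mouth_normal=np.array([0.0, 0.0, 1.0]), alveolus_id=1,
        )
        a, b = rec(1, [0, 0, 5.0]), rec(2, [0, 5.0, 0])
        ra, rb = ring([0, 0, 1.0]), ring([0, 1.0, 0])
        th1 = angle_between_alveoli(a, b, ra, rb)
        s = 3.7
        a2 = rec(1, [0, 0, 5.0 * s])
        b2 = rec(2, [0, 5.0 * s, 0])
        th2 = angle_between_alveoli(
            a2, b2, ring([0, 0, s]), ring([0, s, 0])
        )
        assert th1 == pytest.approx(th2, rel=1e-12)

    def test_mouth_normal_variant(self):
        from alveodyn.morphometry import EntranceRing

        mk = lambda n: EntranceRing(
            loop=np.zeros((4, 3)), perimeter=1.0,
            mouth_center=np.zeros(3),
            mouth_normal=np.asarray(n, float), alveolus_id=1,
        )
        rec = MorphometryRecord(
            structure_id=1, role="alveolus", V=1.0, S=1.0, D_A=1.0,
            centroid=np.ones(3),
        )
        th = angle_between_alveoli(
            rec, rec, mk([0, 0, 1.0]), mk([0, 1.0, 0]), method="normals"
        )
        assert th == pytest.approx(90.0, abs=1e-9)


class TestAssembleUnit:
    def _mesh_records(self, state):
        meshes = state.meshes(refinement=4)
        recs = []
        duct = None
        for label, m in meshes.items():
            V, S = mesh_volume(m), mesh_area(m)
            if label == 1:
                duct = MorphometryRecord(
                    structure_id=1, role="duct", V=V, S=S,
                    D_A=equivalent_diameter(V), centroid=np.zeros(3),
                )
            else:
                al = state.alveoli[label - 2]
                recs.append(
                    MorphometryRecord(
                        structure_id=label, role="alveolus", V=V,
                        S=S - np.pi * al.a**2,  # membrane only
                        D_A=equivalent_diameter(V),
                        centroid=state.alveolus_centroid(label - 2),
                    )
                )
        return recs, duct

    def test_zero_alveoli_equals_duct(self):
        duct = MorphometryRecord(
            structure_id=1, role="duct", V=100.0, S=120.0,
            D_A=equivalent_diameter(100.0), centroid=np.zeros(3),
        )
        unit = assemble_unit([], duct)
        assert unit.V == duct.V and unit.S == duct.S
        assert unit.role == "unit_AAD"

    def test_volume_additivity_exact(self, desk_unit):
        _, exp, _, _ = desk_unit
        recs, duct = self._mesh_records(exp)
        unit = assemble_unit(recs, duct)
        assert unit.V == pytest.approx(
            duct.V + sum(r.V for r in recs), rel=1e-12
        )

    def test_assembled_unit_agrees_with_union_mesh(
        self, desk_unit, desk_labels
    ):
        """Summing aperture-excluded parts reproduces the surface of the
        union mesh, and the part volumes the union volume."""
        _, _, _, truth = desk_unit
        records, _ = measure_labels(
            desk_labels[0], measure_thickness=False
        )
        duct = next(r for r in records if r.role == "duct")
        alveoli = [r for r in records if r.role == "alveolus"]
        union = next(r for r in records if r.role == "unit_AAD")
        unit = assemble_unit(alveoli, duct)
        assert unit.V == pytest.approx(union.V, rel=0.01)
        assert unit.S == pytest.approx(union.S, rel=0.02)
        # and the measured unit volume matches the closed-form truth
        assert unit.V == pytest.approx(
            truth.unit_row("expiration")["V_AAD_um3"], rel=0.01
        )


class TestMeasureLabels:
    def test_full_record_set(self, desk_unit, desk_labels):
        spec, _, _, truth = desk_unit
        records, rings = measure_labels(
            desk_labels[0], measure_thickness=False
        )
        df = records_to_frame(records)
        assert (df.role == "alveolus").sum() == spec.n_alveoli
        assert (df.role == "duct").sum() == 1
        assert (df.role == "unit_AAD").sum() == 1
        assert len(rings) == spec.n_alveoli
        # unit V within 1% of truth
        unit = df[df.role == "unit_AAD"].iloc[0]
        assert unit.V_um3 == pytest.approx(
            truth.unit_row("expiration")["V_AAD_um3"], rel=0.01
        )
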