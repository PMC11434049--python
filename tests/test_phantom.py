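"""Phantom generator: determinism, analytic truth, voxelization, rendering."""

import numpy as np
import pandas as pd
import pytest

from alveodyn import phantom as ph
from alveodyn.errors import (
    DegenerateResolutionError,
    DomainError,
    PlacementError,
)
from alveodyn.morphometry import SurfaceMesh, mesh_area, mesh_volume

from conftest import SphereSolid, desk_spec


class TestGenerateUnit:
    def test_isotropic_truth_is_similarity(self, desk_unit):
        spec, exp, insp, truth = desk_unit
        assert truth.q_true == pytest.approx(1.0, abs=1e-12)
        ratio = insp.unit_volume() / exp.unit_volume()
        assert ratio == pytest.approx(spec.volume_ratio, rel=1e-10)
        assert np.allclose(truth.pairs["dtheta_deg"], 0.0, atol=1e-9)

    def test_determinism_bitwise(self):
        spec = desk_spec(deformation_mode="alveolus_dominant")
        a = ph.generate_unit(spec)
        b = ph.generate_unit(spec)
        for ma, mb in zip(a[0].meshes(2).values(), b[0].meshes(2).values()):
            assert np.array_equal(ma.vertices, mb.vertices)
            assert np.array_equal(ma.faces, mb.faces)
        pd.testing.assert_frame_equal(a[2].structures, b[2].structures)
        assert a[2].q_true == b[2].q_true

    def test_single_alveolus_tiny_mouth_is_nearly_spherical(self):
        spec = desk_spec(n_alveoli=1, mouth_fraction=0.05)
        exp, _, truth = ph.generate_unit(spec)
        r = exp.alveoli[0].r
        S = truth.structures.query(
            "role == 'alveolus' and state == 'expiration'"
        )["S_um2"].iloc[0]
        assert S == pytest.approx(4 * np.pi * r**2, rel=0.01)

    def test_placement_failure_names_seed_and_count(self):
        spec = desk_spec(n_alveoli=12, max_attempts=200)
        with pytest.raises(PlacementError) as err:
            ph.generate_unit(spec)
        assert "12" in str(err.value)
        assert str(spec.placement_seed) in str(err.value)

    @pytest.mark.parametrize(
        "mode,q_side,dth_side",
        [
            ("alveolus_dominant", 1, -1),
            ("duct_dominant", -1, 1),
        ],
    )
    def test_anisotropic_mode_signatures(self, mode, q_side, dth_side):
        """q and Δθ regimes are built into the deformation modes."""
        for seed in (0, 1, 2):
            spec = desk_spec(deformation_mode=mode, placement_seed=seed)
            exp, insp, truth = ph.generate_unit(spec)
            assert np.sign(truth.q_true - 1.0) == q_side
            assert np.sign(truth.pairs["dtheta_deg"].mean()) == dth_side
            # volume ratio still exact
            assert insp.unit_volume() / exp.unit_volume() == pytest.approx(
                spec.volume_ratio, rel=1e-9
            )
            # compartment strain ordering matches the mode
            dv_alv = [
                ph.cap_volume(ai.r, ai.a) / ph.cap_volume(ae.r, ae.a) - 1
                for ae, ai in zip(exp.alveoli, insp.alveoli)
            ]
            dv_duct = insp.duct_volume() / exp.duct_volume() - 1
            if mode == "alveolus_dominant":
                assert min(dv_alv) > dv_duct
            else:
                assert max(dv_alv) < dv_duct

    def test_mouths_disjoint_in_both_states(self, desk_unit):
        _, exp, insp, _ = desk_unit
        for st in (exp, insp):
            n = len(st.alveoli)
            for i in range(n):
                for j in range(i + 1, n):
                    d = np.linalg.norm(
                        st.mouth_center(i) - st.mouth_center(j)
                    )
                    assert d > st.alveoli[i].a + st.alveoli[j].a

    def test_invalid_specs_rejected(self):
        with pytest.raises(DomainError):
            desk_spec(mouth_fraction=1.2)
        with pytest.raises(DomainError):
            desk_spec(volume_ratio=0.8)
        with pytest.raises(DomainError):
            desk_spec(n_alveoli=0)
        with pytest.raises(DomainError):
            desk_spec(deformation_mode="sideways")


class TestAnalyticMeshes:
    def test_primitive_meshes_match_closed_forms(self, desk_unit):
        """Refinement-4 meshes integrate to the analytic S and V ≤ 0.5%."""
        _, exp, _, _ = desk_unit
        meshes = exp.meshes(refinement=4)
        R, L = exp.duct_radius, exp.duct_length
        V_caps = np.pi * R * R * L + 4 / 3 * np.pi * R**3
        S_caps = 2 * np.pi * R * L + 4 * np.pi * R * R
        assert mesh_volume(meshes[1]) == pytest.approx(V_caps, rel=5e-3)
        assert mesh_area(meshes[1]) == pytest.approx(S_caps, rel=5e-3)
        for k, al in enumerate(exp.alveoli):
            m = meshes[k + 2]
            assert m.closed
            assert mesh_volume(m) == pytest.approx(
                ph.cap_volume(al.r, al.a), rel=5e-3
            )
            # mesh includes the flat mouth disk; truth S excludes it
            assert mesh_area(m) - np.pi * al.a**2 == pytest.approx(
                ph.cap_area(al.r, al.a), rel=5e-3
            )

    def test_cap_centroid_against_numerical_integration(self):
        # oracle: brute-force centroid of the major cap by midpoint sums
        r, a = 10.0, 4.5
        c = np.sqrt(r * r - a * a)
        x = np.linspace(-c, r, 4000)  # axial coordinate from sphere center
        w = np.pi * (r * r - x * x)  # disk area at each height
        num = np.trapezoid(w * x, x) / np.trapezoid(w, x)
        assert ph.cap_centroid_height(r, a) == pytest.approx(num, abs=1e-3)


class TestVoxelize:
    def test_sphere_volume_within_one_percent(self):
        vol = ph.voxelize({1: SphereSolid(25.0)}, 0.65)
        measured = (vol.voxels == 1).sum() * vol.voxel_volume
        assert measured == pytest.approx(65449.85, rel=0.01)

    def test_convergence_with_finer_spacing(self):
        truth = 4 / 3 * np.pi * 10.0**3
        errs = []
        for sp in (2.0, 1.0):
            vol = ph.voxelize({1: SphereSolid(10.0)}, sp)
            v = (vol.voxels == 1).sum() * vol.voxel_volume
            errs.append(abs(v - truth) / truth)
        assert errs[1] < errs[0]

    def test_empty_structure_set_gives_zero_volume(self):
        vol = ph.voxelize({}, 1.0)
        assert vol.voxels.sum() == 0

    def test_degenerate_resolution_raises(self):
        with pytest.raises(DegenerateResolutionError):
            ph.voxelize({1: SphereSolid(1.0)}, 2.0)

    def test_mesh_voxelization_agrees_with_solid(self):
        """Slice-rasterized closed meshes match the implicit-solid route."""
        import trimesh

        r = 8.0
        tm = trimesh.creation.icosphere(subdivisions=3, radius=r)
        mesh = SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
        vol = ph.voxelize({1: mesh}, 1.0)
        v = (vol.voxels == 1).sum() * vol.voxel_volume
        assert v == pytest.approx(4 / 3 * np.pi * r**3, rel=0.02)

    def test_voxel_labels_match_truth_volumes(self, desk_unit, desk_labels):
        _, _, _, truth = desk_unit
        lab = desk_labels[0]
        t = truth.structures.query("state == 'expiration'")
        for _, row in t.iterrows():
            v = (lab.voxels == row.structure_id).sum() * lab.voxel_volume
            assert v == pytest.approx(row.V_um3, rel=0.01)


class TestRenderGrayscale:
    def test_noise_free_is_two_level(self, desk_labels):
        img = ph.render_grayscale(desk_labels[0], 0.0, seed=0)
        assert set(np.unique(img)) == {60.0, 200.0}

    def test_seed_determinism(self, desk_labels):
        a = ph.render_grayscale(desk_labels[0], 10.0, seed=42)
        b = ph.render_grayscale(desk_labels[0], 10.0, seed=42)
        assert np.array_equal(a, b)
        c = ph.render_grayscale(desk_labels[0], 10.0, seed=43)
        assert not np.array_equal(a, c)

    def test_noise_sd_calibration(self, desk_labels):
        """Sample SD inside a pure-air region recovers noise_sd within 5%."""
        lab = desk_labels[0]
        img = ph.render_grayscale(lab, 10.0, seed=7)
        air_sd = img[lab.voxels == 1].std(ddof=1)
        assert air_sd == pytest.approx(10.0, rel=0.05)
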