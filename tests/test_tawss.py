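"""TAWSS computation, adverse-area classification and group statistics."""

import numpy as np
import pytest
import trimesh

from vesselwarp import (
    Dissection,
    PhantomSpec,
    TaggedMesh,
    WSSTimeSeries,
    adverse_areas,
    build_waveform,
    clip_and_extend,
    compute_tawss,
    group_summary,
    label_to_surface,
    make_phantom,
    poiseuille_field,
    poiseuille_wss,
    smooth_surface,
    surface_areas,
    waveform_to_flow,
)
from vesselwarp.hemodynamics import Waveform
from vesselwarp.meshing import TAG_FALSE_LUMEN, TAG_WALL

# Per-model lumen surface areas (cm^2) by treatment stage, used as the
# reference inputs for the group statistics
TOTAL_AREAS_CM2 = {
    "pre_pta": [4.44, 6.11, 6.53, 10.94],
    "post_pta": [7.97, 9.02, 9.85, 11.34, 7.75, 8.32, 7.70],
    "post_stent": [10.33, 9.47, 9.99, 11.87],
}


def flat_patch_mesh(n_faces=10):
    """Strip of unit right triangles in the z=0 plane, all wall-tagged."""
    verts, faces = [], []
    for i in range(n_faces):
        base = len(verts)
        verts.extend([[i, 0, 0], [i + 1, 0, 0], [i, 1, 0]])
        faces.append([base, base + 1, base + 2])
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    return TaggedMesh(mesh=mesh, face_tags=np.full(n_faces, TAG_WALL, dtype=object))


class TestComputeTawss:
    def test_constant_field(self):
        mesh = flat_patch_mesh(4)
        t = np.linspace(0, 1, 50)
        series = WSSTimeSeries(mesh=mesh, times=t, wss=np.ones((50, 4)))
        assert compute_tawss(series) == pytest.approx(np.ones(4))

    def test_square_wave_averages_to_half(self):
        mesh = flat_patch_mesh(1)
        t = np.linspace(0, 1, 2001)
        wss = np.where(t[:, None] < 0.5, 0.0, 2.0)
        series = WSSTimeSeries(mesh=mesh, times=t, wss=wss)
        assert compute_tawss(series)[0] == pytest.approx(1.0, rel=1e-3)

    def test_rectified_sine_closed_form(self):
        # mean of |sin(2 pi t / T)| over a period is 2/pi
        mesh = flat_patch_mesh(1)
        t = np.linspace(0, 1, 500)
        wss = np.abs(np.sin(2 * np.pi * t))[:, None]
        series = WSSTimeSeries(mesh=mesh, times=t, wss=wss)
        assert compute_tawss(series)[0] == pytest.approx(2 / np.pi, rel=1e-3)

    def test_single_sample_rejected(self):
        mesh = flat_patch_mesh(1)
        series = WSSTimeSeries(mesh=mesh, times=np.array([0.0, 1.0]), wss=np.ones((2, 1)))
        series.times = np.array([0.0])
        series.wss = np.ones((1, 1))
        with pytest.raises(ValueError, match="two time samples"):
            compute_tawss(series)

    def test_linearity_and_monotonicity(self):
        mesh = flat_patch_mesh(3)
        t = np.linspace(0, 1, 100)
        rng = np.random.default_rng(0)
        w1 = rng.uniform(0, 5, (100, 3))
        w2 = rng.uniform(0, 5, (100, 3))
        s = lambda w: compute_tawss(WSSTimeSeries(mesh=mesh, times=t, wss=w))
        assert np.allclose(s(w1 + w2), s(w1) + s(w2))
        assert np.all(s(w1 + w2) >= s(w1))


class TestAdverseAreas:
    def test_uniform_normal_field(self):
        mesh = flat_patch_mesh(6)
        report = adverse_areas(np.ones(6), mesh)
        assert report.low_area_cm2 == 0.0
        assert report.high_area_cm2 == 0.0
        assert report.normal_area_cm2 == pytest.approx(mesh.mesh.area / 100.0)

    def test_boundary_value_is_normal_strict_inequality(self):
        mesh = flat_patch_mesh(3)
        report = adverse_areas(np.array([0.5, 7.0, 1.0]), mesh)
        assert report.low_area_cm2 == 0.0
        assert report.high_area_cm2 == 0.0

    def test_partition_conserves_wall_area(self):
        mesh = flat_patch_mesh(20)
        rng = np.random.default_rng(1)
        report = adverse_areas(rng.uniform(0, 10, 20), mesh)
        total = report.low_area_cm2 + report.high_area_cm2 + report.normal_area_cm2
        assert total == pytest.approx(report.wall_area_cm2, abs=1e-12)

    def test_false_lumen_fully_low_when_forced(self):
        mesh = flat_patch_mesh(10)
        mesh.face_tags[:4] = TAG_FALSE_LUMEN
        tawss = np.ones(10)
        tawss[:4] = 0.1  # false-lumen faces forced below threshold
        report = adverse_areas(tawss, mesh)
        assert report.false_lumen_low_coverage == pytest.approx(1.0)
        assert report.low_area_in_false_lumen_cm2 == report.low_area_cm2

    def test_missing_values_rejected(self):
        mesh = flat_patch_mesh(3)
        with pytest.raises(ValueError, match="non-finite"):
            adverse_areas(np.array([1.0, np.nan, 2.0]), mesh)


class TestGroupSummary:
    def test_reported_group_statistics(self):
        summary = group_summary(TOTAL_AREAS_CM2)
        g = summary["groups"]
        assert g["pre_pta"]["mean"] == pytest.approx(7.00, abs=0.005 + 1e-9)
        assert g["pre_pta"]["sd"] == pytest.approx(2.77, abs=0.005)
        assert g["post_pta"]["mean"] == pytest.approx(8.85, abs=0.005)
        assert g["post_pta"]["sd"] == pytest.approx(1.34, abs=0.005)
        assert g["post_stent"]["mean"] == pytest.approx(10.41, abs=0.005)
        assert g["post_stent"]["sd"] == pytest.approx(1.03, abs=0.005)

    def test_identical_groups_t_zero_p_one(self):
        summary = group_summary({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        test = summary["tests"][("a", "b")]
        assert test["t"] == pytest.approx(0.0)
        assert test["p"] == pytest.approx(1.0)
        assert not test["significant"]

    def test_hand_computed_pooled_t(self):
        # {1,2,3} vs {4,5,6}: pooled variance 1, se = sqrt(2/3),
        # t = -3 / 0.8165 = -3.674, df = 4, p = 0.0214
        summary = group_summary({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        test = summary["tests"][("a", "b")]
        assert test["t"] == pytest.approx(-3.674, abs=1e-3)
        assert test["p"] == pytest.approx(0.0214, abs=5e-4)
        assert test["significant"]

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            group_summary({"a": [1.0], "b": [1.0, 2.0]})

    def test_cross_check_against_textbook_formulas(self):
        # independent oracle: mean, (n-1) SD and pooled two-sample t from
        # first principles on seeded random group pairs
        from scipy import stats as sps

        for seed in range(50):
            rng = np.random.default_rng(seed)
            na, nb = rng.integers(3, 12, 2)
            a, b = rng.normal(5, 2, na), rng.normal(6, 2.5, nb)
            summary = group_summary({"a": a, "b": b})
            mean_a = a.sum() / na
            sd_a = np.sqrt(((a - mean_a) ** 2).sum() / (na - 1))
            assert summary["groups"]["a"]["mean"] == pytest.approx(mean_a, abs=1e-9)
            assert summary["groups"]["a"]["sd"] == pytest.approx(sd_a, abs=1e-9)
            sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
            t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
            p_hand = 2 * sps.t.sf(abs(t_hand), na + nb - 2)
            assert summary["tests"][("a", "b")]["t"] == pytest.approx(t_hand, abs=1e-9)
            assert summary["tests"][("a", "b")]["p"] == pytest.approx(p_hand, abs=1e-9)


@pytest.fixture(scope="module")
def clipped_cylinder():
    spec = PhantomSpec(centerline_kind="straight", length=20.0, radius=2.0, seed=3)
    truth = make_phantom(spec, voxel_size=(0.075, 0.075, 0.075))
    surf = smooth_surface(label_to_surface(truth.label_volume), 20, 0.5)
    return truth, clip_and_extend(surf, truth.centerline, 2.0, 18.0)


@pytest.fixture(scope="module")
def clipped_stenotic():
    from vesselwarp import Stenosis

    spec = PhantomSpec(
        centerline_kind="straight", length=20.0, radius=2.0, seed=3,
        stenosis=Stenosis(position=0.5, severity=0.5, length=8.0),
    )
    truth = make_phantom(spec, voxel_size=(0.075, 0.075, 0.075))
    surf = smooth_surface(label_to_surface(truth.label_volume), 20, 0.5)
    return truth, clip_and_extend(surf, truth.centerline, 2.0, 18.0)


class TestPoiseuilleField:
    def test_uniform_cylinder_matches_scalar_oracle(self, clipped_cylinder):
        truth, mesh = clipped_cylinder
        t = np.linspace(0, 1, 100, endpoint=False)
        q = Waveform(period=1.0, times=t, values=np.full(100, 500.0), kind="flow")
        series = poiseuille_field(mesh, truth.centerline, q)
        tawss = compute_tawss(series)
        wall = np.isin(mesh.face_tags, [TAG_WALL])
        expected = poiseuille_wss(500.0, 2.0)
        assert np.median(tawss[wall]) == pytest.approx(expected, rel=0.05)

    def test_stenosis_amplifies_wss_by_radius_cubed(self, clipped_stenotic):
        truth, mesh = clipped_stenotic
        t = np.linspace(0, 1, 100, endpoint=False)
        q = Waveform(period=1.0, times=t, values=np.full(100, 500.0), kind="flow")
        tawss = compute_tawss(poiseuille_field(mesh, truth.centerline, q, n_bins=40))
        wall = np.isin(mesh.face_tags, [TAG_WALL])
        centroids = mesh.mesh.triangles_center[wall]
        throat = np.abs(centroids[:, 2] - 10.0) < 0.5
        far = np.abs(centroids[:, 2] - 4.0) < 0.5
        ratio = np.median(tawss[wall][throat]) / np.median(tawss[wall][far])
        # radius halves at the throat: tau scales by 2^3 = 8
        assert ratio == pytest.approx(8.0, rel=0.2)

    def test_attenuated_false_lumen_falls_below_low_threshold(self):
        spec = PhantomSpec(
            centerline_kind="straight", length=20.0, radius=2.0, seed=3,
            dissection=Dissection(start_mm=5.0, end_mm=15.0, angular_extent_deg=90.0, gap_mm=0.4),
        )
        truth = make_phantom(spec, voxel_size=(0.075, 0.075, 0.075))
        surf = smooth_surface(label_to_surface(truth.label_volume), 10, 0.5)
        mesh = clip_and_extend(surf, truth.centerline, 2.0, 18.0)
        w = build_waveform("triphasic", 88.30, -14.90)
        q = waveform_to_flow(w, surface_areas(mesh)["inlet_mm2"])
        series = poiseuille_field(mesh, truth.centerline, q, attenuation=0.05)
        tawss = compute_tawss(series)
        report = adverse_areas(tawss, mesh)
        wall = np.isin(mesh.face_tags, [TAG_WALL, TAG_FALSE_LUMEN])
        main = tawss[wall][~(mesh.face_tags == TAG_FALSE_LUMEN)[wall]]
        # attenuation 0.05: whenever the main lumen sits below 10 Pa, every
        # false-lumen face lands below the 0.5 Pa low threshold
        assert np.median(main) < 10.0
        assert report.false_lumen_low_coverage == pytest.approx(1.0)

    def test_dissection_strictly_increases_low_tawss_area(self, clipped_cylinder):
        truth_plain, mesh_plain = clipped_cylinder
        spec = PhantomSpec(
            centerline_kind="straight", length=20.0, radius=2.0, seed=3,
            dissection=Dissection(start_mm=5.0, end_mm=15.0, angular_extent_deg=90.0, gap_mm=0.4),
        )
        truth_d = make_phantom(spec, voxel_size=(0.075, 0.075, 0.075))
        surf_d = smooth_surface(label_to_surface(truth_d.label_volume), 10, 0.5)
        mesh_d = clip_and_extend(surf_d, truth_d.centerline, 2.0, 18.0)
        w = build_waveform("triphasic", 88.30, -14.90)
        reports = []
        for truth, mesh in ((truth_plain, mesh_plain), (truth_d, mesh_d)):
            q = waveform_to_flow(w, surface_areas(mesh)["inlet_mm2"])
            tawss = compute_tawss(poiseuille_field(mesh, truth.centerline, q))
            reports.append(adverse_areas(tawss, mesh))
        assert reports[1].low_area_cm2 > reports[0].low_area_cm2
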