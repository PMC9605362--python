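import numpy as np
import pytest

from outflowfe.material import ViscoelasticParams, stress_update_coefficients
from outflowfe.meshing import fit_circle_diameter
from outflowfe.synth import (
    JCT_THICKNESS_UM,
    SC_WALL_THICKNESS_UM,
    LoadProtocol,
    SyntheticScene,
    generate_boundary_trajectory,
    generate_scene,
    generate_sc_lumen_stack,
    generate_specimen_curve,
    scene_from_yaml,
    scene_to_yaml,
    trajectory_from_csv,
    trajectory_to_csv,
)
from outflowfe.tables import ground_truth_set


class TestGenerateScene:
    def test_zero_waviness_straight_lines(self):
        scene = generate_scene(1, width_um=400, waviness=0.0)
        for label, poly in scene.boundaries.items():
            assert np.ptp(poly[:, 1]) < 1e-12, label
        ant = scene.boundaries["TM_posterior"][:, 1]
        jct = scene.boundaries["JCT_band"][:, 1]
        assert jct[0] - ant[0] == pytest.approx(JCT_THICKNESS_UM)

    def test_determinism(self):
        a = generate_scene(1, width_um=400, waviness=0.15)
        b = generate_scene(1, width_um=400, waviness=0.15)
        for label in a.boundaries:
            np.testing.assert_array_equal(a.boundaries[label], b.boundaries[label])

    def test_different_seeds_differ(self):
        a = generate_scene(1, width_um=400, waviness=0.15)
        b = generate_scene(2, width_um=400, waviness=0.15)
        dev = max(
            np.abs(a.boundaries[k] - b.boundaries[k]).max() for k in a.boundaries
        )
        assert dev > 0

    def test_depth_ordering_monotone(self):
        scene = generate_scene(3, width_um=300, waviness=0.25)
        order = ["TM_anterior", "TM_posterior", "JCT_band", "SC_inner_wall",
                 "SC_outer_wall"]
        for lo, hi in zip(order, order[1:]):
            assert np.all(
                scene.boundaries[hi][:, 1] > scene.boundaries[lo][:, 1]
            )

    def test_band_thicknesses(self):
        scene = generate_scene(4, width_um=300, waviness=0.2)
        jct = scene.boundaries["JCT_band"][:, 1] - scene.boundaries["TM_posterior"][:, 1]
        scw = scene.boundaries["SC_inner_wall"][:, 1] - scene.boundaries["JCT_band"][:, 1]
        np.testing.assert_allclose(jct, JCT_THICKNESS_UM, rtol=0.1)
        np.testing.assert_allclose(scw, SC_WALL_THICKNESS_UM, rtol=0.1)
        depth = scene.boundaries["TM_posterior"][:, 1] - scene.boundaries["TM_anterior"][:, 1]
        assert np.all((depth >= 60.0) & (depth <= 120.0))

    def test_waviness_out_of_range(self):
        with pytest.raises(ValueError):
            generate_scene(1, width_um=400, waviness=0.5)
        with pytest.raises(ValueError):
            generate_scene(1, width_um=50, waviness=0.1)

    def test_default_ground_truth_is_115lf(self):
        scene = generate_scene(1)
        assert scene.ground_truth["TM"].g0 == pytest.approx(5.10)
        assert scene.ground_truth["TM_beam"].beta == pytest.approx(450.0)

    def test_yaml_roundtrip(self, tmp_path):
        scene = generate_scene(6, width_um=150, waviness=0.1)
        path = tmp_path / "scene.yaml"
        scene_to_yaml(scene, path)
        back = scene_from_yaml(path)
        assert back.seed == scene.seed
        np.testing.assert_allclose(
            back.boundaries["TM_anterior"], scene.boundaries["TM_anterior"]
        )
        assert back.ground_truth["JCT"].ginf == scene.ground_truth["JCT"].ginf


class TestLoadProtocol:
    def test_invalid_kind(self):
        with pytest.raises(ValueError):
            LoadProtocol(kind="squeeze")

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            LoadProtocol(duration=0.0)

    def test_table_monotone_with_hold(self):
        p = LoadProtocol(p_start=0, p_end=30, duration=0.5, hold=0.5)
        t, v = p.table()
        assert np.all(np.diff(t) > 0)
        assert np.all(np.diff(v) >= 0)


class TestLumenStack:
    def test_exact_circle_diameter(self):
        stack = generate_sc_lumen_stack(63.0, n_sections=4, jitter_sd=0.0)
        for sec in stack:
            assert fit_circle_diameter(sec) == pytest.approx(126.0, abs=1e-9)

    def test_jittered_sections_within_tolerance(self):
        stack = generate_sc_lumen_stack(63.0, n_sections=4, jitter_sd=2.0, seed=5)
        for sec in stack:
            d = fit_circle_diameter(sec)
            assert abs(d - 126.0) < 3 * 2.0

    def test_single_section(self):
        stack = generate_sc_lumen_stack(63.0, n_sections=1)
        assert len(stack) == 1
        assert stack[0].shape[0] >= 24

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            generate_sc_lumen_stack(-1.0)


@pytest.fixture(scope="module")
def specimen_model():
    from outflowfe.synth import _specimen_model

    return _specimen_model()


class TestSpecimenCurve:
    def test_endpoints_with_two_points(self, specimen_model):
        hp = ground_truth_set("115LF")
        ecm = ViscoelasticParams(24.98, 18.81, 500.0)
        beam = ViscoelasticParams(35.2, 20.51, 585.0)
        curve = generate_specimen_curve(ecm, beam, strain_max=0.02, n_points=2,
                                        n_steps=400, model=specimen_model)
        assert curve.shape == (2, 2)
        assert curve[0] == pytest.approx((0.0, 0.0))
        assert curve[1, 0] == pytest.approx(0.02)
        assert curve[1, 1] > 0

    def test_no_relaxation_equals_elastic(self, specimen_model):
        g, nu = 20.0, 0.495
        visco = ViscoelasticParams(g, g, 500.0, nu)
        elastic = ViscoelasticParams.elastic(g, nu)
        a = generate_specimen_curve(visco, visco, n_points=8, n_steps=600,
                                    model=specimen_model)
        b = generate_specimen_curve(elastic, elastic, n_points=8, n_steps=600,
                                    model=specimen_model)
        np.testing.assert_allclose(a, b, rtol=1e-10)

    def test_monotone_nondecreasing(self, specimen_model):
        ecm = ViscoelasticParams(24.98, 18.81, 500.0)
        beam = ViscoelasticParams(35.2, 20.51, 585.0)
        curve = generate_specimen_curve(ecm, beam, n_points=15, n_steps=1000,
                                        model=specimen_model)
        assert np.all(np.diff(curve[:, 1]) > -1e-9 * curve[:, 1].max())

    def test_elastic_limit_bar_oracle(self, specimen_model):
        # elastic limit at 2% strain: gauge stress equals the composite
        # E * 0.02 (rule of mixtures) within 2%
        g, nu = 15.0, 0.495
        ecm = ViscoelasticParams.elastic(g, nu)
        beam = ViscoelasticParams.elastic(2 * g, nu)
        curve = generate_specimen_curve(ecm, beam, n_points=5, n_steps=1500,
                                        model=specimen_model)
        from outflowfe.synth import SPECIMEN_FIBER_FRACTION as VF

        e_comp = (1 - VF) * ecm.youngs_instantaneous + VF * beam.youngs_instantaneous
        assert curve[-1, 1] == pytest.approx(e_comp * 0.02, rel=0.02)

    def test_table1_matches_one_element_oracle(self, specimen_model):
        # independent oracle: dense-history convolution quadrature of the
        # hereditary integral at a single material point with the transverse
        # stress-free condition solved per time step, composited with the
        # fiber fraction (rule of mixtures)
        ecm = ViscoelasticParams(24.98, 18.81, 500.0)
        beam = ViscoelasticParams(35.2, 20.51, 585.0)
        duration, strain_max = 0.02, 0.02
        curve = generate_specimen_curve(ecm, beam, strain_max=strain_max,
                                        duration=duration, n_points=9,
                                        n_steps=2500, model=specimen_model)

        def uniaxial_history(p, n=400):
            # strain ramp; transverse strains solved so lateral stress = 0
            t = np.linspace(0, duration, n + 1)
            e_ax = strain_max * t / duration
            e_lat = np.zeros(n + 1)
            k = p.bulk_modulus
            g_fun = lambda tt: p.ginf + (p.g0 - p.ginf) * np.exp(-p.beta * tt)
            sig_ax = np.zeros(n + 1)
            for i in range(1, n + 1):
                # solve lateral strain so the deviatoric+volumetric lateral
                # stress vanishes, using trapezoid convolution for the
                # hereditary deviatoric term
                def stresses(el_i):
                    el = e_lat.copy()
                    el[i] = el_i
                    # deviatoric strain histories
                    e_dev_ax = (2.0 / 3.0) * (e_ax - el)
                    e_dev_lat = -(1.0 / 3.0) * (e_ax - el)
                    de_ax = np.diff(e_dev_ax)
                    de_lat = np.diff(e_dev_lat)
                    tm = 0.5 * (t[:-1] + t[1:])
                    g_w = g_fun(t[i] - tm)
                    s_ax = 2.0 * np.sum(g_w[:i] * de_ax[:i])
                    s_lat = 2.0 * np.sum(g_w[:i] * de_lat[:i])
                    vol = k * (e_ax[i] + 2 * el_i)
                    return s_ax + vol, s_lat + vol

                from scipy.optimize import brentq

                f = lambda el_i: stresses(el_i)[1]
                el_i = brentq(f, -0.1, 0.1, xtol=1e-14)
                e_lat[i] = el_i
                sig_ax[i] = stresses(el_i)[0]
            return t, sig_ax

        _, s_ecm = uniaxial_history(ecm)
        _, s_beam = uniaxial_history(beam)
        from outflowfe.synth import SPECIMEN_FIBER_FRACTION as VF

        oracle_end = (1 - VF) * s_ecm[-1] + VF * s_beam[-1]
        assert curve[-1, 1] == pytest.approx(oracle_end, rel=0.05)


class TestSpecimenRefinement:
    def test_gauge_stress_mesh_insensitive(self):
        # refining the bar mesh changes the gauge stress < 3%
        from outflowfe.synth import _specimen_model

        ecm = ViscoelasticParams(24.98, 18.81, 500.0)
        beam = ViscoelasticParams(35.2, 20.51, 585.0)
        coarse = _specimen_model(nx=8, ny=2)
        fine = _specimen_model(nx=16, ny=3)
        a = generate_specimen_curve(ecm, beam, n_points=6, n_steps=800,
                                    model=coarse)
        b = generate_specimen_curve(ecm, beam, n_points=6, n_steps=800,
                                    model=fine)
        assert b[-1, 1] == pytest.approx(a[-1, 1], rel=0.03)


class TestBoundaryTrajectory:
    @pytest.fixture(scope="class")
    def small_model(self):
        from outflowfe.synth import build_complex_model

        scene = generate_scene(1, width_um=150, waviness=0.05, tm_depth_um=70,
                               noise_sd=0.0)
        model = build_complex_model(scene, edge_um=8.0, beam_planar_spacing_um=10.0)
        return scene, model

    def test_no_load_no_motion(self, small_model):
        scene, model = small_model
        protocol = LoadProtocol(kind="sc_pressure_ramp", p_end=0.0, duration=0.05)
        traj = generate_boundary_trajectory(scene, protocol, n_frames=4,
                                            n_steps=200, model=model)
        assert np.abs(traj.coords - traj.coords[0]).max() < 1e-12

    def test_sc_wall_moves_toward_tm(self, small_model):
        # pressurizing the lumen displaces the inner wall toward the TM
        # (negative y in scene coordinates)
        scene, model = small_model
        mesh = model[0]
        protocol = LoadProtocol(kind="sc_pressure_ramp", p_end=30.0,
                                duration=0.02, hold=0.04)
        traj = generate_boundary_trajectory(scene, protocol, n_frames=6,
                                            n_steps=1200, model=model)
        sc = mesh.node_sets["sc_inner_wall_track"]
        mask = np.isin(traj.node_ids, sc)
        dy = (traj.coords[-1] - traj.coords[0])[mask, 1]
        assert np.abs(dy).max() > 0
        assert dy.mean() < 0

    def test_noise_added_and_seeded(self, small_model):
        scene, model = small_model
        noisy = SyntheticScene(scene.seed, scene.boundaries,
                               scene.ground_truth, noise_sd=0.1)
        protocol = LoadProtocol(kind="sc_pressure_ramp", p_end=0.0, duration=0.05)
        a = generate_boundary_trajectory(noisy, protocol, n_frames=4,
                                         n_steps=100, model=model)
        b = generate_boundary_trajectory(noisy, protocol, n_frames=4,
                                         n_steps=100, model=model)
        np.testing.assert_array_equal(a.coords, b.coords)
        spread = np.std(a.coords[:, :, :2] - a.coords[0, :, :2])
        assert 0.01e-3 < spread < 1.0e-3     # mm, roughly the 0.1 um sd

    def test_frame_validation(self, small_model):
        scene, model = small_model
        protocol = LoadProtocol(kind="sc_pressure_ramp", p_end=1.0, duration=0.01)
        with pytest.raises(ValueError):
            generate_boundary_trajectory(scene, protocol, n_frames=1, model=model)

    def test_csv_roundtrip(self, small_model, tmp_path):
        scene, model = small_model
        protocol = LoadProtocol(kind="sc_pressure_ramp", p_end=0.0, duration=0.05)
        traj = generate_boundary_trajectory(scene, protocol, n_frames=3,
                                            n_steps=100, model=model)
        path = tmp_path / "traj.csv"
        trajectory_to_csv(traj, path)
        back = trajectory_from_csv(path)
        np.testing.assert_array_equal(back.node_ids, traj.node_ids)
        np.testing.assert_allclose(back.coords[:, :, :2], traj.coords[:, :, :2],
                                   atol=1e-12)
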