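import numpy as np
import pytest

from outflowfe.beams import (
    BeamElementState,
    BeamNode,
    BeamSection,
    b_matrix,
    beam_internal_force,
    couple_beams_to_solid,
    coupling_forces,
    local_basis,
    rotation_update,
    shape_functions,
    strain_spin_increment,
    update_fiber_vectors,
)
from outflowfe.material import ViscoelasticParams
from outflowfe.meshing import box_mesh, BeamNetwork


def _rodrigues(theta):
    th = np.asarray(theta, dtype=float)
    a = np.linalg.norm(th)
    if a == 0:
        return np.eye(3)
    k = th / a
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(a) * kx + (1 - np.cos(a)) * (kx @ kx)


def _straight_state(length=0.004, r=0.5e-3):
    n1 = BeamNode(x_ref=np.zeros(3), x_cur=np.zeros(3),
                  y_eta=np.array([0.0, 1.0, 0.0]), y_zeta=np.array([0.0, 0.0, 1.0]))
    n2 = BeamNode(x_ref=np.array([length, 0.0, 0.0]),
                  x_cur=np.array([length, 0.0, 0.0]),
                  y_eta=np.array([0.0, 1.0, 0.0]), y_zeta=np.array([0.0, 0.0, 1.0]))
    return BeamElementState(node1=n1, node2=n2, section=BeamSection(r_outer=r))


class TestShapeFunctions:
    def test_kronecker_at_nodes(self):
        corners = [(-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
                   (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1)]
        for a, c in enumerate(corners):
            n, _ = shape_functions(*c)
            expected = np.zeros(8)
            expected[a] = 1.0
            np.testing.assert_allclose(n, expected, atol=1e-14)

    def test_partition_of_unity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(-1, 1, 3)
            n, dn = shape_functions(*p)
            assert n.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(dn.sum(axis=0), 0.0, atol=1e-14)

    def test_center_all_eighth(self):
        n, _ = shape_functions(0, 0, 0)
        np.testing.assert_allclose(n, 1.0 / 8.0)


class TestRotationUpdate:
    def test_zero_identity(self):
        np.testing.assert_allclose(rotation_update(np.zeros(3)), np.eye(3))

    def test_matches_rodrigues_small(self):
        r = rotation_update(np.array([0.0, 0.0, 1e-3]))
        exact = _rodrigues(np.array([0.0, 0.0, 1e-3]))
        assert np.abs(r - exact).max() < 1e-9

    def test_orthogonal_for_moderate_angles(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            th = rng.uniform(-1, 1, 3)
            th *= 0.5 / max(np.linalg.norm(th), 1.0)
            r = rotation_update(th)
            assert np.abs(r.T @ r - np.eye(3)).max() < 1e-12


class TestFiberVectors:
    def test_zero_increment_unchanged(self):
        st = _straight_state()
        d_eta, d_zeta = update_fiber_vectors(st.node1, np.zeros(3))
        np.testing.assert_allclose(d_eta, 0.0)
        np.testing.assert_allclose(st.node1.y_eta, [0, 1, 0])

    def test_composed_quarter_turn(self):
        # 90 degrees about the beam axis in 90 steps of 1 degree maps
        # Y_eta onto the initial Y_zeta
        st = _straight_state()
        step = np.array([np.deg2rad(1.0), 0.0, 0.0])
        for _ in range(90):
            update_fiber_vectors(st.node1, step)
        np.testing.assert_allclose(st.node1.y_eta, [0, 0, 1], atol=1e-4)

    def test_orthogonality_drift(self):
        rng = np.random.default_rng(2)
        st = _straight_state()
        for _ in range(1000):
            update_fiber_vectors(st.node1, rng.normal(0, 1e-3, 3))
            assert abs(np.linalg.norm(st.node1.y_eta) - 1) < 1e-10
        assert abs(st.node1.y_eta @ st.node1.y_zeta) < 1e-8


class TestLocalBasis:
    def test_canonical_alignment(self):
        st = _straight_state()
        q = local_basis(st.node1, st.node2)
        np.testing.assert_allclose(q, np.eye(3)[[0, 1, 2]], atol=1e-14)

    def test_corotational(self):
        st = _straight_state()
        r = _rodrigues(np.array([0.3, -0.2, 0.5]))
        for n in (st.node1, st.node2):
            n.x_cur = r @ n.x_cur
            n.y_eta = r @ n.y_eta
            n.y_zeta = r @ n.y_zeta
        q0 = np.eye(3)
        q1 = local_basis(st.node1, st.node2)
        np.testing.assert_allclose(q1, q0 @ r.T, atol=1e-12)

    def test_right_handed(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            x2 = rng.normal(size=3)
            ye = rng.normal(size=3)
            ye -= (ye @ x2) * x2 / (x2 @ x2)
            ye /= np.linalg.norm(ye)
            n1 = BeamNode(np.zeros(3), np.zeros(3), ye.copy(), np.cross(x2 / np.linalg.norm(x2), ye))
            n2 = BeamNode(x2, x2.copy(), ye.copy(), n1.y_zeta.copy())
            q = local_basis(n1, n2)
            np.testing.assert_allclose(np.cross(q[0], q[1]), q[2], atol=1e-12)

    def test_degenerate_rejected(self):
        st = _straight_state()
        st.node2.x_cur = st.node1.x_cur.copy()
        with pytest.raises(ValueError):
            local_basis(st.node1, st.node2)


class TestStrainSpin:
    def test_pure_stretch(self):
        g = np.diag([0.3, 0.0, 0.0])
        d_eps, d_omega = strain_spin_increment(g)
        np.testing.assert_allclose(d_eps, g)
        np.testing.assert_allclose(d_omega, 0.0)

    def test_pure_spin(self):
        g = np.array([[0, 0.1, 0], [-0.1, 0, 0], [0, 0, 0]])
        d_eps, d_omega = strain_spin_increment(g)
        np.testing.assert_allclose(d_eps, 0.0)
        np.testing.assert_allclose(d_omega, g)

    def test_simple_shear_split(self):
        g = np.zeros((3, 3))
        g[0, 1] = 0.4
        d_eps, d_omega = strain_spin_increment(g)
        assert d_eps[0, 1] == pytest.approx(0.2)
        assert d_omega[0, 1] == pytest.approx(0.2)


class TestBMatrix:
    def _b(self, st, ip=0):
        return b_matrix(
            st.node1.x_cur, st.node2.x_cur, st.node1.y_eta, st.node2.y_eta,
            st.node1.y_zeta, st.node2.y_zeta, st.section, ip,
        )

    def test_rigid_translation_nullspace(self):
        st = _straight_state()
        b = self._b(st)
        d = np.zeros(18)
        d[0:3] = d[9:12] = [1.0, -2.0, 0.5]    # same translation, no tip motion
        np.testing.assert_allclose(b @ d, 0.0, atol=1e-10)

    def test_unit_axial_stretch(self):
        st = _straight_state(length=1.0)
        b = self._b(st)
        d = np.zeros(18)
        d[9] = 1.0                               # node-2 axial displacement
        strain = b @ d
        assert strain[0] == pytest.approx(1.0)

    def test_matches_finite_differences(self):
        # B*d vs central differences of the interpolated displacement field
        rng = np.random.default_rng(7)
        st = _straight_state()
        sec = st.section
        ip = 1
        z_eta, z_zeta = sec.offsets[ip]
        d = rng.normal(0, 1e-3, 18)

        def disp(y):
            # invert the (xi, eta~, zeta~) map for this straight beam
            xi = 2.0 * y[0] / 0.004 - 1.0
            n = np.array([(1 - xi) / 2, (1 + xi) / 2])
            out = np.zeros(3)
            for a in range(2):
                base = 9 * a
                out += n[a] * d[base:base + 3]
                out += n[a] * y[1] * d[base + 3:base + 6]
                out += n[a] * y[2] * d[base + 6:base + 9]
            return out

        y0 = np.array([0.002, z_eta, z_zeta])
        h = 1e-6
        grad = np.zeros((3, 3))
        for j in range(3):
            dy = np.zeros(3)
            dy[j] = h
            grad[:, j] = (disp(y0 + dy) - disp(y0 - dy)) / (2 * h)
        eps_fd = 0.5 * (grad + grad.T)
        expected = np.array([
            eps_fd[0, 0], eps_fd[1, 1], eps_fd[2, 2],
            2 * eps_fd[0, 1], 2 * eps_fd[1, 2], 2 * eps_fd[0, 2],
        ])
        np.testing.assert_allclose(self._b(st, ip) @ d, expected, atol=1e-6)


class TestBeamInternalForce:
    def test_zero_deformation_zero_force(self):
        st = _straight_state()
        mat = ViscoelasticParams(35.2, 20.51, 585.0)
        f = beam_internal_force(st, np.zeros(3), np.zeros(3), np.zeros(3),
                                np.zeros(3), mat, 1e-4)
        np.testing.assert_allclose(f, 0.0, atol=1e-18)

    def test_bar_theory_axial(self):
        st = _straight_state(length=0.004)
        g, nu = 12.0, 0.45
        mat = ViscoelasticParams.elastic(g, nu)
        eps = 1e-4
        f = beam_internal_force(st, np.zeros(3), np.array([eps * 0.004, 0, 0]),
                                np.zeros(3), np.zeros(3), mat, 1e-4)
        e_mod = 2 * g * (1 + nu)
        area = st.section.area
        assert f[6] == pytest.approx(e_mod * area * eps, rel=0.01)

    def test_newtons_third_law(self):
        rng = np.random.default_rng(9)
        st = _straight_state()
        mat = ViscoelasticParams(35.2, 20.51, 585.0)
        f = beam_internal_force(st, rng.normal(0, 1e-5, 3), rng.normal(0, 1e-5, 3),
                                rng.normal(0, 1e-3, 3), rng.normal(0, 1e-3, 3),
                                mat, 1e-4)
        f1, f2 = f[0:3], f[6:9]
        assert np.linalg.norm(f1 + f2) < 1e-10 * max(np.linalg.norm(f1), 1e-30)

    def test_zero_transverse_normal_stress(self):
        rng = np.random.default_rng(10)
        st = _straight_state()
        mat = ViscoelasticParams(35.2, 20.51, 585.0)
        for _ in range(5):
            beam_internal_force(st, rng.normal(0, 1e-5, 3), rng.normal(0, 1e-5, 3),
                                rng.normal(0, 1e-3, 3), rng.normal(0, 1e-3, 3),
                                mat, 1e-4)
        # transverse normal stresses vanish in the co-rotational local frame
        from outflowfe.beams import local_basis
        from outflowfe.material import voigt_to_tensor
        q = local_basis(st.node1, st.node2)
        for ip in range(st.sigma.shape[0]):
            sl = q @ voigt_to_tensor(st.sigma[ip]) @ q.T
            ref = max(np.abs(sl).max(), 1e-30)
            assert abs(sl[1, 1]) < 1e-10 * ref + 1e-18
            assert abs(sl[2, 2]) < 1e-10 * ref + 1e-18

    def test_rigid_rotation_generates_no_strain(self):
        # incremental objectivity: a rigid-rotation trajectory produces
        # stress < 1e-8 x modulus
        st = _straight_state()
        mat = ViscoelasticParams.elastic(35.2, 0.495)
        n = 200
        dth = np.array([0.0, 0.0, np.pi / 2 / n])
        for _ in range(n):
            r = rotation_update(dth)
            du1 = (r - np.eye(3)) @ st.node1.x_cur
            du2 = (r - np.eye(3)) @ st.node2.x_cur
            beam_internal_force(st, du1, du2, dth, dth, mat, 1e-4)
        assert np.abs(st.sigma).max() < 1e-8 * mat.g0

    def test_relaxation_in_held_axial_strain(self):
        st = _straight_state(length=0.004)
        mat = ViscoelasticParams(35.2, 20.51, 585.0)
        eps = 1e-4
        beam_internal_force(st, np.zeros(3), np.array([eps * 0.004, 0, 0]),
                            np.zeros(3), np.zeros(3), mat, 1e-7)
        s_early = st.sigma[0, 0]
        for _ in range(50):
            beam_internal_force(st, np.zeros(3), np.zeros(3), np.zeros(3),
                                np.zeros(3), mat, 2e-4)
        s_late = st.sigma[0, 0]
        # axial stress relaxes toward the long-time modulus ratio
        assert s_late < s_early
        e0 = 2 * 35.2 * 1.495
        einf = 2 * 20.51 * 1.495
        assert s_late / s_early == pytest.approx(einf / e0, rel=0.05)


class TestEnergyConsistency:
    def test_work_equals_stress_power(self):
        # generalized internal-force work per step equals the stress-power
        # integral reconstructed from the strain-displacement operator
        from outflowfe.beams import b_matrix, rotation_update

        rng = np.random.default_rng(5)
        mat = ViscoelasticParams.elastic(12.0, 0.45)
        st = _straight_state()
        sec = st.section
        for step in range(4):
            du1 = rng.normal(0, 1e-6, 3)
            du2 = rng.normal(0, 1e-6, 3)
            dth1 = rng.normal(0, 1e-4, 3)
            dth2 = rng.normal(0, 1e-4, 3)
            ye1, yz1 = st.node1.y_eta.copy(), st.node1.y_zeta.copy()
            ye2, yz2 = st.node2.y_eta.copy(), st.node2.y_zeta.copy()
            f = beam_internal_force(st, du1, du2, dth1, dth2, mat, 1e-4)
            work = f[0:3] @ du1 + f[3:6] @ dth1 + f[6:9] @ du2 + f[9:12] @ dth2
            d = np.concatenate([
                du1, st.node1.y_eta - ye1, st.node1.y_zeta - yz1,
                du2, st.node2.y_eta - ye2, st.node2.y_zeta - yz2,
            ])
            length = np.linalg.norm(st.node2.x_cur - st.node1.x_cur)
            power = 0.0
            for ip in range(sec.offsets.shape[0]):
                b = b_matrix(st.node1.x_cur, st.node2.x_cur,
                             st.node1.y_eta, st.node2.y_eta,
                             st.node1.y_zeta, st.node2.y_zeta, sec, ip)
                eps = b @ d            # engineering shear components
                sig = st.sigma[ip]
                power += (sig @ eps) * length * sec.weights[ip]
            if abs(work) > 0:
                assert power == pytest.approx(work, rel=1e-6)


class TestCoupling:
    @pytest.fixture()
    def embedded(self):
        mesh = box_mesh(1.0, 0.5, 0.5, 4, 2, 2)
        pts = np.column_stack([
            np.linspace(0.1, 0.9, 9),
            np.full(9, 0.25),
            np.full(9, 0.25),
        ])
        segs = np.column_stack([np.arange(8), np.arange(1, 9)])
        beams = BeamNetwork(control_points=pts, segments=segs,
                            group_tag=np.zeros(8, dtype=np.int64))
        coupling = couple_beams_to_solid(beams, mesh, penalty_scale=100.0)
        return mesh, beams, coupling

    def test_all_points_found(self, embedded):
        mesh, beams, coupling = embedded
        assert coupling.host_elem.shape == (9,)
        assert np.all(coupling.stiffness > 0)

    def test_rigid_translation_zero_residual(self, embedded):
        mesh, beams, coupling = embedded
        shift = np.array([0.1, -0.2, 0.05])
        f_b, f_s = coupling_forces(coupling, mesh, mesh.nodes + shift,
                                   beams.control_points + shift)
        np.testing.assert_allclose(f_b, 0.0, atol=1e-12)
        np.testing.assert_allclose(f_s, 0.0, atol=1e-12)

    def test_momentum_conservation(self, embedded):
        mesh, beams, coupling = embedded
        rng = np.random.default_rng(12)
        xs = mesh.nodes + rng.normal(0, 1e-3, mesh.nodes.shape)
        xb = beams.control_points + rng.normal(0, 1e-3, beams.control_points.shape)
        f_b, f_s = coupling_forces(coupling, mesh, xs, xb)
        total = f_b.sum(axis=0) + f_s.sum(axis=0)
        assert np.abs(total).max() < 1e-10 * max(np.abs(f_b).max(), 1e-30)

    def test_orphan_points_rejected(self):
        mesh = box_mesh(1.0, 0.5, 0.5, 4, 2, 2)
        pts = np.array([[0.5, 0.25, 0.25], [5.0, 5.0, 5.0]])
        beams = BeamNetwork(control_points=pts,
                            segments=np.array([[0, 1]]),
                            group_tag=np.zeros(1, dtype=np.int64))
        with pytest.raises(ValueError, match="outside"):
            couple_beams_to_solid(beams, mesh)
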