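import math

import numpy as np
import pytest
import scipy.sparse.linalg as spla

from icrsim.fem import (AxisymModel, ContactPair, DofConstraints, LoadCase,
                        PressureLoad, RigidObstacle, Stepping, contact_update,
                        newton_solve)
from icrsim.mesh import AxisymMesh


def annulus_patch(r0=1.0, r1=2.0, z0=0.0, z1=0.5, n=2):
    """Small structured annular patch (CCW quads)."""
    rs, zs = np.linspace(r0, r1, n + 1), np.linspace(z0, z1, n + 1)
    nodes = np.array([[r, z] for r in rs for z in zs])
    grid = np.arange((n + 1) ** 2).reshape(n + 1, n + 1)
    quads = [[grid[i, j], grid[i + 1, j], grid[i + 1, j + 1], grid[i, j + 1]]
             for i in range(n) for j in range(n)]
    return AxisymMesh(nodes=nodes, quads=np.array(quads))


def sphere_shell(a, b, n_r, n_th):
    """Half meridian (pole to equator) of a thick spherical shell."""
    th = np.linspace(0, math.pi / 2, n_th + 1)
    rr = np.linspace(a, b, n_r + 1)
    nodes = np.array([[R * math.sin(t), R * math.cos(t)] for t in th for R in rr])
    grid = np.arange((n_th + 1) * (n_r + 1)).reshape(n_th + 1, n_r + 1)
    quads = np.array([[grid[i, j], grid[i + 1, j], grid[i + 1, j + 1], grid[i, j + 1]]
                      for i in range(n_th) for j in range(n_r)])
    mesh = AxisymMesh(nodes=nodes, quads=quads)
    if mesh.element_areas().min() < 0:
        mesh = AxisymMesh(nodes=nodes, quads=quads[:, ::-1])
    inner = []
    for e, q in enumerate(mesh.quads):
        for k in range(4):
            n1, n2 = q[k], q[(k + 1) % 4]
            if (abs(np.hypot(*mesh.nodes[n1]) - a) < 1e-9
                    and abs(np.hypot(*mesh.nodes[n2]) - a) < 1e-9):
                inner.append([n1, n2])
    return mesh, np.array(inner)


class TestAssembly:
    def test_zero_state_zero_residual(self, material):
        mesh = annulus_patch()
        model = AxisymModel(mesh, material)
        R, K, _ = model.assemble(np.zeros(model.ndof), LoadCase())
        np.testing.assert_allclose(R, 0.0, atol=1e-12)

    def test_tangent_matches_residual_fd(self, material):
        """Consistent tangent: columns agree with central finite differences
        of the residual on a random deformed patch, including the follower
        pressure load stiffness."""
        mesh = annulus_patch()
        model = AxisymModel(mesh, material)
        rng = np.random.default_rng(1)
        u = 0.02 * rng.standard_normal(model.ndof)
        edge = np.array([[mesh.quads[0][3], mesh.quads[0][0]]])
        case = LoadCase(pressures=[PressureLoad(edge, 5.0)])
        _, K, _ = model.assemble(u, case)
        K = K.toarray()
        h = 1e-7
        Kfd = np.zeros_like(K)
        for dof in range(model.ndof):
            up, um = u.copy(), u.copy()
            up[dof] += h
            um[dof] -= h
            Rp, _, _ = model.assemble(up, case, want_K=False)
            Rm, _, _ = model.assemble(um, case, want_K=False)
            Kfd[:, dof] = (Rp - Rm) / (2 * h)
        assert np.abs(K - Kfd).max() / np.abs(K).max() < 1e-5


class TestLameBenchmark:
    def test_pressurized_thick_sphere(self, material):
        """Small-load inflation of a thick spherical shell matches the
        closed-form linear-elastic solution with mu = 2 C1, nu -> 1/2."""
        a, b, p = 5.0, 6.0, 0.1
        mesh, inner = sphere_shell(a, b, 6, 40)
        model = AxisymModel(mesh, material)
        fixed = [2 * n for n, (r, z) in enumerate(mesh.nodes) if abs(r) < 1e-9]
        fixed += [2 * n + 1 for n, (r, z) in enumerate(mesh.nodes) if abs(z) < 1e-9]
        cons = DofConstraints(model.ndof, fixed)
        state = newton_solve(model, lambda lam: LoadCase(
            pressures=[PressureLoad(inner, lam * p)]), cons,
            stepping=Stepping(initial=1.0))
        x = model.X + state.u.reshape(-1, 2)
        rad = np.hypot(x[:, 0], x[:, 1]) - np.hypot(mesh.nodes[:, 0], mesh.nodes[:, 1])
        u_in = rad[np.unique(inner.ravel())].mean()
        mu, nu = material.shear_modulus, material.poisson_ratio
        E = 2 * mu * (1 + nu)
        u_ref = p * a ** 4 / (E * (b ** 3 - a ** 3)) * (
            (1 - 2 * nu) + (1 + nu) * b ** 3 / (2 * a ** 3))
        assert u_in == pytest.approx(u_ref, rel=0.01)

    def test_quadratic_convergence_tail(self, material):
        """The final Newton iterations of an increment contract at least
        tenfold per iteration (consistent linearization)."""
        mesh, inner = sphere_shell(5.0, 6.0, 4, 20)
        model = AxisymModel(mesh, material)
        fixed = [2 * n for n, (r, z) in enumerate(mesh.nodes) if abs(r) < 1e-9]
        fixed += [2 * n + 1 for n, (r, z) in enumerate(mesh.nodes) if abs(z) < 1e-9]
        cons = DofConstraints(model.ndof, fixed)
        log = []
        newton_solve(model, lambda lam: LoadCase(
            pressures=[PressureLoad(inner, lam * 1.0)]), cons,
            stepping=Stepping(initial=1.0), log=log)
        res = [rec["residual"] for rec in log]
        assert res[-1] <= 0.1 * res[-2] <= 0.01 * res[-3]


class TestNewton:
    def test_zero_load_identity(self, material):
        mesh = annulus_patch()
        model = AxisymModel(mesh, material)
        cons = DofConstraints(model.ndof, [0, 1])
        state = newton_solve(model, lambda lam: LoadCase(), cons,
                             stepping=Stepping(initial=1.0))
        assert state.iterations <= 1
        np.testing.assert_allclose(state.u, 0.0, atol=1e-12)

    def test_step_count_path_independence(self, material):
        """Halving the load increments changes the converged elastic
        solution by less than 1e-8 relative."""
        mesh, inner = sphere_shell(5.0, 6.0, 3, 16)
        model = AxisymModel(mesh, material)
        fixed = [2 * n for n, (r, z) in enumerate(mesh.nodes) if abs(r) < 1e-9]
        fixed += [2 * n + 1 for n, (r, z) in enumerate(mesh.nodes) if abs(z) < 1e-9]
        cons = DofConstraints(model.ndof, fixed)
        case = lambda lam: LoadCase(pressures=[PressureLoad(inner, lam * 2.0)])
        u1 = newton_solve(model, case, cons, stepping=Stepping(initial=0.5)).u
        u2 = newton_solve(model, case, cons, stepping=Stepping(initial=0.25)).u
        assert np.abs(u1 - u2).max() / np.abs(u1).max() < 1e-8


class TestInclinedPlane:
    def test_displacement_lies_in_plane(self, material):
        mesh, inner = sphere_shell(5.0, 6.0, 3, 16)
        model = AxisymModel(mesh, material)
        fixed = [2 * n for n, (r, z) in enumerate(mesh.nodes) if abs(r) < 1e-9]
        eq_nodes = [n for n, (r, z) in enumerate(mesh.nodes) if abs(z) < 1e-9]
        angle = 40.0
        cons = DofConstraints(model.ndof, fixed, slide=[(eq_nodes, angle)])
        state = newton_solve(model, lambda lam: LoadCase(
            pressures=[PressureLoad(inner, lam * 0.5)]), cons,
            stepping=Stepping(initial=1.0))
        u = state.u.reshape(-1, 2)[eq_nodes]
        nrm = np.array([-math.sin(math.radians(angle)),
                        math.cos(math.radians(angle))])
        np.testing.assert_allclose(u @ nrm, 0.0, atol=1e-12)


class TestContact:
    SQ = np.array([(0.0, 0.0), (2.0, 0.0), (2.0, 1.0), (0.0, 1.0)])

    def test_no_force_outside(self):
        obs = RigidObstacle(self.SQ, forbidden="inside")
        pair = ContactPair(nodes=[0], obstacle=obs, stiffness=100.0,
                           smoothing=0.0)
        f, pen, _ = contact_update(pair, np.array([[1.0, 2.0]]))
        assert pen[0] == 0.0
        np.testing.assert_allclose(f, 0.0)

    def test_penalty_force_is_k_times_depth(self):
        obs = RigidObstacle(self.SQ, forbidden="inside")
        pair = ContactPair(nodes=[0], obstacle=obs, stiffness=100.0,
                           smoothing=0.0)
        d = 0.2
        f, pen, K = contact_update(pair, np.array([[1.0, 1.0 - d]]))
        assert pen[0] == pytest.approx(d)
        np.testing.assert_allclose(f[0], [0.0, 100.0 * d], atol=1e-12)
        np.testing.assert_allclose(K[0], [[0, 0], [0, 100.0]], atol=1e-12)

    def test_frictionless_normal_only(self):
        """The contact force has no component tangential to the obstacle
        face, for penetrating points anywhere along it."""
        obs = RigidObstacle(self.SQ, forbidden="inside")
        pair = ContactPair(nodes=[0], obstacle=obs, stiffness=50.0,
                           smoothing=0.0)
        for xq in (0.3, 0.9, 1.7):
            f, _, _ = contact_update(pair, np.array([[xq, 0.95]]))
            assert f[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_forbidden_outside_flips_sign(self):
        obs = RigidObstacle(self.SQ, forbidden="outside")
        pair = ContactPair(nodes=[0], obstacle=obs, stiffness=10.0,
                           smoothing=0.0)
        f, pen, _ = contact_update(pair, np.array([[1.0, 1.3]]))
        assert pen[0] == pytest.approx(0.3)
        np.testing.assert_allclose(f[0], [0.0, -3.0], atol=1e-12)

    def test_smoothing_continuous(self):
        obs = RigidObstacle(self.SQ, forbidden="inside")
        pair = ContactPair(nodes=[0], obstacle=obs, stiffness=100.0,
                           smoothing=0.01)
        eps = pair.smoothing
        f_at_eps, _, _ = contact_update(pair, np.array([[1.0, 1.0 - eps]]))
        assert f_at_eps[0, 1] == pytest.approx(100.0 * eps / 2.0, rel=1e-9)

    def test_equilibrium_penetration_is_f_over_k(self, material):
        """A node pressed onto an obstacle by a known force settles at
        penetration f/k (plus the smoothing offset)."""
        mesh = annulus_patch(n=1)
        model = AxisymModel(mesh, material)
        # clamp everything except the free corner node 1 (r0, z1)
        free_node = 1
        fixed = [d for n in range(4) if n != free_node for d in (2 * n, 2 * n + 1)]
        fixed.append(2 * free_node)  # radial dof too: 1-dof problem
        cons = DofConstraints(model.ndof, fixed)
        k = 1e7  # much stiffer than the (nearly incompressible) patch
        wall = RigidObstacle(np.array([(0.0, 0.5), (3.0, 0.5), (3.0, 2.0),
                                       (0.0, 2.0)]), forbidden="inside")
        pair = ContactPair(nodes=[free_node], obstacle=wall, stiffness=k,
                           smoothing=0.0)
        fz = 2.0  # push the node up into the wall (initial gap zero)

        class PointLoadModel(AxisymModel):
            def assemble(self, u, case, want_K=True):
                R, K, ref = super().assemble(u, case, want_K)
                R[2 * free_node + 1] -= fz
                return R, K, max(ref, abs(fz))

        model2 = PointLoadModel(mesh, material)
        state = newton_solve(model2, lambda lam: LoadCase(contacts=[pair]),
                             cons, stepping=Stepping(initial=1.0))
        x = model2.X + state.u.reshape(-1, 2)
        pen, _ = wall.penetrations(x[[free_node]])
        # equilibrium: contact + elastic forces balance fz; the penalty is
        # far stiffer than the patch, so pen ~ |fz|/k
        assert pen[0] == pytest.approx(abs(fz) / k, rel=0.1)
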