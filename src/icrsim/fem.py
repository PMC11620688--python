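"""Axisymmetric total-Lagrangian finite-element solver.

4-node bilinear quads with selective reduced integration (isochoric energy at
the 2x2 Gauss points, volumetric penalty at the element centroid), follower
pressure loads, inclined-plane sliding boundary conditions via local dof
rotation, frictionless node-to-segment penalty contact against rigid
polylines, and Newton-Raphson with adaptive load incrementation.  All
integrals carry the axisymmetric weight 2*pi*R.

Degrees of freedom: node i owns (2i) = u_r and (2i+1) = u_z, in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .material import (ElementInversionError, YeohParams,
                       first_piola_and_tangent, piola5_and_tangent5)
from .mesh import AxisymMesh, _dshape, _shape

__all__ = ["RigidObstacle", "ContactPair", "PressureLoad", "LoadCase",
           "DofConstraints", "AxisymModel", "SolverState", "Stepping",
           "newton_solve", "NonConvergenceError"]

_F5_IDX = [(0, 0), (0, 1), (1, 0), (1, 1), (2, 2)]
_GAUSS_1D = (-1.0 / math.sqrt(3.0), 1.0 / math.sqrt(3.0))


class NonConvergenceError(RuntimeError):
    def __init__(self, msg, state=None, u_last=None, rn=None, ref=None,
                 iters=0):
        super().__init__(msg)
        self.state = state
        self.u_last = u_last
        self.rn = rn
        self.ref = ref
        self.iters = iters


# ---------------------------------------------------------------------------
# rigid obstacles and contact
# ---------------------------------------------------------------------------

@dataclass
class RigidObstacle:
    """Closed simple polyline in the (r, z) half-plane; ``forbidden`` names
    the side penalized by contact ('inside' for the ring, 'outside' for the
    mold-like insertion tool)."""

    polyline: np.ndarray  # (m, 2), closed implicitly
    forbidden: str = "inside"

    def __post_init__(self):
        self.polyline = np.asarray(self.polyline, dtype=float)
        if self.polyline.ndim != 2 or len(self.polyline) < 3:
            raise ValueError("polyline must be (m >= 3, 2)")
        if self.forbidden not in ("inside", "outside"):
            raise ValueError("forbidden must be 'inside' or 'outside'")
        a = self.polyline
        b = np.roll(a, -1, axis=0)
        self._seg_a, self._seg_d = a, b - a
        self._seg_len2 = np.maximum(np.einsum("ij,ij->i", self._seg_d, self._seg_d), 1e-30)

    def closest_points(self, pts: np.ndarray):
        """Closest boundary points and distances for query points (n, 2)."""
        pts = np.atleast_2d(pts)
        w = pts[:, None, :] - self._seg_a[None, :, :]
        t = np.clip(np.einsum("nmj,mj->nm", w, self._seg_d) / self._seg_len2, 0.0, 1.0)
        proj = self._seg_a[None] + t[..., None] * self._seg_d[None]
        d2 = np.sum((pts[:, None, :] - proj) ** 2, axis=2)
        k = np.argmin(d2, axis=1)
        n = np.arange(len(pts))
        return proj[n, k], np.sqrt(d2[n, k])

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Even-odd point-in-polygon test, vectorized."""
        pts = np.atleast_2d(pts)
        x, y = pts[:, 0][:, None], pts[:, 1][:, None]
        x1, y1 = self._seg_a[:, 0][None], self._seg_a[:, 1][None]
        x2 = x1 + self._seg_d[:, 0][None]
        y2 = y1 + self._seg_d[:, 1][None]
        cond = (y1 <= y) != (y2 <= y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xi = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        crosses = cond & (x < xi)
        return np.sum(crosses, axis=1) % 2 == 1

    def penetrations(self, pts: np.ndarray):
        """(penetration depth >= 0, push direction) per query point."""
        proj, dist = self.closest_points(pts)
        inside = self.contains(pts)
        signed = np.where(inside, -dist, dist)
        pen = signed if self.forbidden == "outside" else -signed
        with np.errstate(invalid="ignore", divide="ignore"):
            n = (proj - pts) / np.maximum(dist, 1e-14)[:, None]
        n[dist < 1e-14] = 0.0
        return np.maximum(pen, 0.0), n


@dataclass
class ContactPair:
    nodes: np.ndarray            # slave node ids
    obstacle: RigidObstacle
    stiffness: np.ndarray        # per-node penalty stiffness, mN/mm
    active: bool = True
    name: str = ""
    smoothing: float = 5e-5      # mm; quadratic force transition near zero gap

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=int)
        self.stiffness = np.broadcast_to(np.asarray(self.stiffness, dtype=float),
                                         self.nodes.shape).copy()


def contact_update(pair: ContactPair, x: np.ndarray):
    """Nodal contact forces and stiffness blocks for current coordinates x.

    Returns (forces (n, 2), gaps (n,), K blocks (n, 2, 2)).  Frictionless by
    construction: the force acts along the obstacle normal only.  The force
    law is regularized over the ``smoothing`` width to keep the derivative
    continuous at gap = 0 (mitigates Newton chatter at contact activation).
    """
    pts = x[pair.nodes]
    pen, nrm = pair.obstacle.penetrations(pts)
    eps = pair.smoothing
    k = pair.stiffness
    if eps > 0:
        quad = pen < eps
        fmag = np.where(quad, k * pen ** 2 / (2.0 * eps), k * (pen - 0.5 * eps))
        dfmag = np.where(quad, k * pen / eps, k)
    else:
        fmag = k * pen
        dfmag = k * (pen > 0)
    f = fmag[:, None] * nrm
    K = dfmag[:, None, None] * np.einsum("ni,nj->nij", nrm, nrm)
    return f, pen, K


# ---------------------------------------------------------------------------
# loads and constraints
# ---------------------------------------------------------------------------

@dataclass
class PressureLoad:
    """Follower pressure on oriented edges (node-id pairs, outward normal at
    (t_z, -t_r)); positive value pushes into the domain."""

    edges: np.ndarray  # (m, 2) node ids
    value: float       # kPa

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if not np.isfinite(self.value):
            raise ValueError("pressure must be finite")


@dataclass
class LoadCase:
    pressures: list = field(default_factory=list)   # [PressureLoad]
    contacts: list = field(default_factory=list)    # [ContactPair]


class DofConstraints:
    """Fixed dofs plus inclined-plane sliding nodes via local dof rotation.

    The sliding plane makes ``angle`` degrees with the r-axis, tilted
    anteriorly outward like the corneoscleral cut: constrained nodes may move
    along d = (cos a, sin a) and are fixed along the plane normal
    n = (-sin a, cos a).
    """

    def __init__(self, ndof: int, fixed_dofs=(), slide: list | None = None):
        self.ndof = ndof
        fixed = set(int(d) for d in fixed_dofs)
        T = sp.identity(ndof, format="lil")
        for nodes, angle in (slide or []):
            a = math.radians(angle)
            d = (math.cos(a), math.sin(a))
            n = (-math.sin(a), math.cos(a))
            for nd in np.asarray(nodes, dtype=int):
                i, j = 2 * nd, 2 * nd + 1
                T[i, i], T[i, j] = d[0], n[0]
                T[j, i], T[j, j] = d[1], n[1]
                fixed.add(j)  # local normal component
        self.T = T.tocsr()
        self.free = np.ones(ndof, dtype=bool)
        self.free[sorted(fixed)] = False

    def reduce(self, K, R):
        Kt = (self.T.T @ K @ self.T).tocsc()
        Rt = self.T.T @ R
        f = self.free
        return Kt[f][:, f], Rt[f]

    def expand(self, dq):
        full = np.zeros(self.ndof)
        full[self.free] = dq
        return self.T @ full


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class AxisymModel:
    """Assembly of the axisymmetric Yeoh continuum on a fixed reference mesh."""

    def __init__(self, mesh: AxisymMesh, material: YeohParams):
        self.mesh = mesh
        self.material = material
        self.X = np.asarray(mesh.nodes, dtype=float)
        self.conn = np.asarray(mesh.quads, dtype=int)
        self.ndof = 2 * len(self.X)
        self._precompute()

    def _gp_data(self, points):
        """B (ne, g, 5, 8) and weights (ne, g) for isoparametric points."""
        Xe = self.X[self.conn]  # (ne, 4, 2)
        Bs, Ws = [], []
        for xi, eta, w in points:
            N = _shape(xi, eta)
            dN = _dshape(xi, eta)
            J = np.einsum("ak,eai->eik", dN, Xe)  # (ne, 2, 2) dX/dxi
            det = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
            if np.any(det <= 0):
                raise ValueError("inverted reference element")
            Jinv = np.empty_like(J)
            Jinv[:, 0, 0] = J[:, 1, 1] / det
            Jinv[:, 0, 1] = -J[:, 0, 1] / det
            Jinv[:, 1, 0] = -J[:, 1, 0] / det
            Jinv[:, 1, 1] = J[:, 0, 0] / det
            dNdX = np.einsum("ak,eki->eai", dN, Jinv)  # (ne, 4, 2)
            R = Xe[:, :, 0] @ N
            B = np.zeros((len(Xe), 5, 8))
            for a in range(4):
                B[:, 0, 2 * a] = dNdX[:, a, 0]       # F_rR
                B[:, 1, 2 * a] = dNdX[:, a, 1]       # F_rZ
                B[:, 2, 2 * a + 1] = dNdX[:, a, 0]   # F_zR
                B[:, 3, 2 * a + 1] = dNdX[:, a, 1]   # F_zZ
                B[:, 4, 2 * a] = N[a] / R            # F_theta
            Bs.append(B)
            Ws.append(w * det * 2.0 * math.pi * R)
        return np.stack(Bs, axis=1), np.stack(Ws, axis=1)

    def _precompute(self):
        iso_pts = [(xi, eta, 1.0) for xi in _GAUSS_1D for eta in _GAUSS_1D]
        self.B_iso, self.W_iso = self._gp_data(iso_pts)
        self.B_vol, self.W_vol = self._gp_data([(0.0, 0.0, 4.0)])
        dof = np.empty((len(self.conn), 8), dtype=int)
        dof[:, 0::2] = 2 * self.conn
        dof[:, 1::2] = 2 * self.conn + 1
        self.edof = dof
        self._rows = np.repeat(dof, 8, axis=1).ravel()
        self._cols = np.tile(dof, (1, 8)).ravel()

    # -- internal forces ----------------------------------------------------

    def _part(self, u_e, B, W, part, want_K: bool = True):
        F5 = np.einsum("egca,ea->egc", B, u_e)
        F5[..., 0] += 1.0
        F5[..., 3] += 1.0
        F5[..., 4] += 1.0
        g = F5.shape[1]
        try:
            P5, A5 = piola5_and_tangent5(F5, self.material, part,
                                         want_tangent=want_K)
        except ElementInversionError as err:
            elems = np.unique(err.where // g)
            raise ElementInversionError(elems) from None
        Bt = np.swapaxes(B, -1, -2)  # (ne, g, 8, 5)
        f = np.sum(W[..., None] * (Bt @ P5[..., None])[..., 0], axis=1)
        if not want_K:
            return f, None
        K = np.sum(W[..., None, None] * (Bt @ (A5 @ B)), axis=1)
        return f, K

    def internal(self, u: np.ndarray, want_K: bool = True):
        u_e = u[self.edof]
        f1, K1 = self._part(u_e, self.B_iso, self.W_iso, "iso", want_K)
        f2, K2 = self._part(u_e, self.B_vol, self.W_vol, "vol", want_K)
        f_e = f1 + f2
        f = np.zeros(self.ndof)
        np.add.at(f, self.edof.ravel(), f_e.ravel())
        if not want_K:
            return f, None
        K = sp.coo_matrix(((K1 + K2).ravel(), (self._rows, self._cols)),
                          shape=(self.ndof, self.ndof)).tocsc()
        return f, K

    # -- external loads -----------------------------------------------------

    def pressure(self, u: np.ndarray, load: PressureLoad, want_K: bool = True):
        """Consistent follower-pressure nodal forces and load stiffness."""
        x = (self.X + u.reshape(-1, 2))[load.edges]  # (m, 2 nodes, 2)
        p = load.value
        m = len(x)
        f_e = np.zeros((m, 4))
        K_e = np.zeros((m, 4, 4))
        dN = np.array([-0.5, 0.5])
        for xi in _GAUSS_1D:  # weight 1 each
            N = np.array([0.5 * (1 - xi), 0.5 * (1 + xi)])
            r = x[:, :, 0] @ N
            rp = x[:, :, 0] @ dN
            zp = x[:, :, 1] @ dN
            c = -p * 2.0 * math.pi
            for a in range(2):
                f_e[:, 2 * a] += c * N[a] * zp * r
                f_e[:, 2 * a + 1] += -c * N[a] * rp * r
                if want_K:
                    for b in range(2):
                        K_e[:, 2 * a, 2 * b] += c * N[a] * zp * N[b]
                        K_e[:, 2 * a, 2 * b + 1] += c * N[a] * dN[b] * r
                        K_e[:, 2 * a + 1, 2 * b] += -c * N[a] * (dN[b] * r + rp * N[b])
        dof = np.empty((m, 4), dtype=int)
        dof[:, 0::2] = 2 * load.edges
        dof[:, 1::2] = 2 * load.edges + 1
        f = np.zeros(self.ndof)
        np.add.at(f, dof.ravel(), f_e.ravel())
        if not want_K:
            return f, None
        rows = np.repeat(dof, 4, axis=1).ravel()
        cols = np.tile(dof, (1, 4)).ravel()
        K = sp.coo_matrix((K_e.ravel(), (rows, cols)),
                          shape=(self.ndof, self.ndof)).tocsc()
        return f, K

    def assemble(self, u: np.ndarray, case: LoadCase, want_K: bool = True):
        """Residual R = f_int - f_ext - f_contact and consistent tangent."""
        f_int, K = self.internal(u, want_K)
        f_ext = np.zeros(self.ndof)
        for load in case.pressures:
            if load.value == 0.0 or len(load.edges) == 0:
                continue
            fp, Kp = self.pressure(u, load, want_K)
            f_ext += fp
            if want_K:
                K = K - Kp
        f_c = np.zeros(self.ndof)
        x = self.X + u.reshape(-1, 2)
        for pair in case.contacts:
            if not pair.active or len(pair.nodes) == 0:
                continue
            fc, pen, Kc = contact_update(pair, x)
            idx = 2 * pair.nodes
            np.add.at(f_c, idx, fc[:, 0])
            np.add.at(f_c, idx + 1, fc[:, 1])
            act = np.nonzero(pen > 0)[0]
            if want_K and len(act):
                nd = pair.nodes[act]
                rows = np.repeat(np.stack([2 * nd, 2 * nd + 1], axis=1), 2, axis=1).ravel()
                cols = np.tile(np.stack([2 * nd, 2 * nd + 1], axis=1), (1, 2)).ravel()
                K = K + sp.coo_matrix((Kc[act].ravel(), (rows, cols)),
                                      shape=(self.ndof, self.ndof)).tocsc()
        R = f_int - f_ext - f_c
        ref = max(np.linalg.norm(f_ext), np.linalg.norm(f_int), np.linalg.norm(f_c))
        return R, K, ref


# ---------------------------------------------------------------------------
# Newton-Raphson with adaptive load stepping
# ---------------------------------------------------------------------------

@dataclass
class Stepping:
    initial: float = 0.25
    minimum: float = 1e-4
    maximum: float = 1.0
    grow: float = 1.7
    cut: float = 0.35
    max_iter: int = 14
    rtol: float = 1e-8
    atol: float = 1e-9
    fast_iter: int = 6
    stabilize: float = 50.0  # mN/mm artificial spring for failed increments
    #: trust region: largest nodal displacement update per Newton iteration
    #: (mm); prevents soft thin-walled regions from overshooting past the
    #: geometric stiffening range before contact or tension catches them
    du_cap: float = 0.15
    #: residual floor (relative to the force scale) at which a chattering
    #: penalty-contact increment counts as converged; the chatter amplitude
    #: of faceted rigid obstacles sits orders of magnitude above rtol
    contact_floor: float = 2e-4


@dataclass
class SolverState:
    u: np.ndarray
    load_factor: float = 1.0
    converged: bool = False
    iterations: int = 0
    log: list = field(default_factory=list)
    contact: dict = field(default_factory=dict)
    reactions: np.ndarray | None = None


def _newton_increment(model, u, case, cons, step: Stepping, log, tag,
                      alpha: float = 0.0, u_anchor=None):
    """Solve one load increment; returns (u, n_iter, residual history).

    ``alpha`` adds an artificial spring alpha*(u - u_anchor) to the residual
    (automatic stabilization for snap-throughs); callers must relax it away
    afterwards for an unbiased equilibrium.
    """
    u = u.copy()
    anchor = u if u_anchor is None else u_anchor
    hist = []
    has_contact = any(p.active and len(p.nodes) for p in case.contacts)
    stab = sp.identity(model.ndof, format="csc") * alpha if alpha > 0 else None

    def resid(v, want_K):
        R, K, ref = model.assemble(v, case, want_K)
        if alpha > 0:
            R = R + alpha * (v - anchor)
            if want_K:
                K = K + stab
        return R, K, ref

    for it in range(step.max_iter):
        R, K, ref = resid(u, True)
        Kr, Rr = cons.reduce(K, R)
        rn = float(np.linalg.norm(Rr))
        hist.append(rn)
        log.append({"stage": tag[0], "increment": tag[1], "iter": it,
                    "residual": rn, "alpha": alpha,
                    "lam": tag[2] if len(tag) > 2 else None})
        if rn <= step.rtol * max(ref, 1.0) + step.atol:
            return u, it, hist
        if not np.isfinite(rn):
            raise NonConvergenceError("residual is not finite")
        du = cons.expand(spla.spsolve(Kr, -Rr))
        du_inf = float(np.abs(du).max())
        if step.du_cap > 0 and du_inf > step.du_cap:
            du *= step.du_cap / du_inf
        # Newton residuals are not monotone: accept the full step unless it
        # blows up (then back-track to the best finite trial).  A window test
        # catches contact-chatter limit cycles that alternate residuals.
        best = None
        for scale in (1.0, 0.5, 0.25, 0.1):
            try:
                u_try = u + scale * du
                Rt, _, _ = resid(u_try, False)
                rt = float(np.linalg.norm((cons.T.T @ Rt)[cons.free]))
            except ElementInversionError:
                continue
            if not np.isfinite(rt):
                continue
            if best is None or rt < best[0]:
                best = (rt, u_try)
            if scale == 1.0 and rt < 1e3 * rn:
                break
            if rt < rn:
                break
        if best is None:
            raise NonConvergenceError("line search failed (element inversion)")
        rt, u = best
        # penalty contact against faceted obstacles chatters at a small
        # residual amplitude; a stalled increment below the contact floor
        # counts as converged
        if len(hist) >= 7 and rt > 0.5 * hist[-7]:
            if alpha == 0.0 and has_contact and \
                    rt <= step.contact_floor * max(ref, 1.0):
                return u, it + 1, hist
            raise NonConvergenceError("Newton stalled (contact chatter)",
                                      u_last=u, rn=rt, ref=ref, iters=it + 1)
    if alpha == 0.0 and has_contact and \
            hist[-1] <= step.contact_floor * max(ref, 1.0):
        return u, step.max_iter, hist
    raise NonConvergenceError(f"no convergence in {step.max_iter} iterations",
                              u_last=u, rn=hist[-1], ref=ref,
                              iters=step.max_iter)


def newton_solve(model: AxisymModel, case_fn, cons: DofConstraints,
                 u0: np.ndarray | None = None, stepping: Stepping | None = None,
                 stage: str = "stage", log: list | None = None,
                 accept_damped: bool = False) -> SolverState:
    """Ramp the load factor from 0 to 1 adaptively.

    ``case_fn(lam)`` must return the LoadCase at load factor lam; contact
    pair activity may not depend on lam (toggle between stages instead).
    When an increment fails outright it is retried with a small artificial
    spring to its starting state (automatic stabilization), which is then
    relaxed away at the same load level; only if that also fails is the
    increment cut.
    """
    step = stepping or Stepping()
    log = log if log is not None else []
    u = np.zeros(model.ndof) if u0 is None else u0.copy()
    lam, dlam = 0.0, step.initial
    n_inc = 0
    total_iters = 0

    def _attempt(u_from, case, a, tag):
        try:
            v, iters, _ = _newton_increment(model, u_from, case, cons, step,
                                            log, tag, alpha=a)
            return v, iters
        except (ElementInversionError, NonConvergenceError):
            return None, 0

    while lam < 1.0 - 1e-12:
        dlam = min(dlam, 1.0 - lam)
        case = case_fn(lam + dlam)
        u_new, iters = _attempt(u, case, 0.0, (stage, n_inc, lam + dlam))
        if u_new is None and step.stabilize > 0.0:
            # damped predictor through the snap, then a cascade of
            # relaxations back to true equilibrium; the increment counts
            # only if the final (alpha = 0) solve converges
            a_try = step.stabilize
            for _ in range(3):
                u_stab, it1 = _attempt(u, case, a_try, (stage, n_inc, lam + dlam))
                if u_stab is not None:
                    u_damped = u_stab
                    a_rel = a_try / 10.0
                    while u_stab is not None and a_rel > 1e-2 * step.stabilize:
                        u_stab, it2 = _attempt(u_stab, case, a_rel,
                                               (stage, n_inc, lam + dlam))
                        it1 += it2
                        if u_stab is not None:
                            u_damped = u_stab
                        a_rel /= 10.0
                    if u_stab is not None:
                        u_new, it2 = _attempt(u_stab, case, 0.0,
                                              (stage, n_inc, lam + dlam))
                        if u_new is not None:
                            iters = it1 + it2
                            break
                    if accept_damped:
                        # states on flutter-prone branches may have no
                        # reachable undamped equilibrium; keep the damped
                        # one and let the next stage re-equilibrate
                        u_new, iters = u_damped, it1
                        break
                a_try *= 10.0
        if u_new is None:
            dlam *= step.cut
            if dlam < step.minimum:
                raise NonConvergenceError(
                    f"{stage}: increment below minimum at load factor {lam:.4f}",
                    state=SolverState(u=u, load_factor=lam, converged=False,
                                      log=log))
            continue
        u = u_new
        lam += dlam
        n_inc += 1
        total_iters += iters
        if iters <= step.fast_iter:
            dlam = min(dlam * step.grow, step.maximum)
    state = SolverState(u=u, load_factor=lam, converged=True,
                        iterations=total_iters, log=log)
    # residual at convergence = reaction forces on constrained dofs
    R, _, _ = model.assemble(u, case_fn(1.0))
    state.reactions = cons.T.T @ R
    x = model.X + u.reshape(-1, 2)
    for pair in case_fn(1.0).contacts:
        if pair.active and len(pair.nodes):
            f, pen, _ = contact_update(pair, x)
            state.contact[pair.name or "pair"] = {
                "nodes": pair.nodes, "penetration": pen, "force": f}
    return state


def make_cornea_constraints(mesh: AxisymMesh, model: AxisymModel,
                            angle: float | None = None) -> DofConstraints:
    """Axis symmetry (u_r = 0), orphan-node lockout, and the inclined-plane
    sliding condition at the corneoscleral rim."""
    if angle is None:
        angle = mesh.geom.limbus_plane_angle if mesh.geom else 40.0
    fixed = [2 * int(n) for n in mesh.node_sets["axis"]]
    for n in mesh.orphan_nodes():
        fixed += [2 * int(n), 2 * int(n) + 1]
    slide = [(mesh.node_sets["limbus"], angle)]
    return DofConstraints(model.ndof, fixed, slide)
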