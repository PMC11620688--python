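"""Stress-free corneal geometry recovery.

The imaged (physiological) cornea is already loaded by the intraocular
pressure, so the finite-element reference configuration must be the unknown
unloaded shape.  It is recovered by the classic fixed-point iteration: inflate
the current trial geometry to the physiological IOP, subtract the nodal
discrepancy from the trial coordinates, and repeat until the inflated shape
matches the target everywhere to better than 1e-2 um.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fem import (AxisymModel, LoadCase, NonConvergenceError, PressureLoad,
                  SolverState, Stepping, make_cornea_constraints, newton_solve)
from .material import YeohParams
from .mesh import AxisymMesh

__all__ = ["PrestressResult", "recover_stress_free", "inflate"]

#: exact mmHg -> kPa conversion factor
MMHG_TO_KPA = 133.322 / 1000.0


@dataclass
class PrestressResult:
    stress_free_nodes: np.ndarray
    iterations: int
    final_error: float  # um, max nodal distance between inflated and target
    error_history: list = field(default_factory=list)
    inflated_state: SolverState | None = None  # state on the stress-free mesh


def inflate(mesh: AxisymMesh, material: YeohParams, iop_kpa: float,
            u0=None, stepping: Stepping | None = None,
            log: list | None = None) -> tuple[AxisymModel, SolverState]:
    """Inflate a (reference) mesh by IOP on the posterior surface."""
    model = AxisymModel(mesh, material)
    cons = make_cornea_constraints(mesh, model)
    edges = mesh.edge_nodes(mesh.edge_sets["posterior"])
    case_fn = lambda lam: LoadCase(
        pressures=[PressureLoad(edges, lam * iop_kpa)])
    stepping = stepping or Stepping(initial=0.5)
    state = newton_solve(model, case_fn, cons, u0=u0, stepping=stepping,
                         stage="inflate", log=log)
    return model, state


def recover_stress_free(target_mesh: AxisymMesh, material: YeohParams,
                        iop_kpa: float, tol_um: float = 1e-2,
                        max_iter: int = 50,
                        stepping: Stepping | None = None) -> PrestressResult:
    """Fixed-point recovery of the unloaded geometry.

    X^(k+1) = X^(k) - (x(X^(k)) - X_target), where x(.) is the IOP-inflated
    nodal position of trial geometry X^(k).  Applies under-relaxation (0.5)
    only if the error sequence diverges.  The criterion is checked over all
    nodes (stricter than surface-only).
    """
    if iop_kpa < 0:
        raise ValueError("IOP must be nonnegative")
    X_target = np.asarray(target_mesh.nodes, dtype=float)
    X = X_target.copy()
    tol_mm = tol_um * 1e-3
    errors: list[float] = []
    relax = 1.0
    u_warm = None
    state = None
    for it in range(1, max_iter + 1):
        mesh_k = target_mesh.with_nodes(X)
        try:
            if u_warm is not None:
                # the previous inflated displacement is a near-solution: try a
                # single full-load solve before falling back to a cold ramp
                try:
                    model, state = inflate(mesh_k, material, iop_kpa, u0=u_warm,
                                           stepping=Stepping(initial=1.0, minimum=0.5))
                except NonConvergenceError:
                    model, state = inflate(mesh_k, material, iop_kpa,
                                           stepping=stepping)
            else:
                model, state = inflate(mesh_k, material, iop_kpa,
                                       stepping=stepping)
        except NonConvergenceError as err:
            raise NonConvergenceError(
                f"prestress iterate {it} failed to inflate", state=err.state)
        x = X + state.u.reshape(-1, 2)
        err_mm = float(np.max(np.linalg.norm(x - X_target, axis=1)))
        errors.append(err_mm * 1e3)
        if err_mm < tol_mm:
            return PrestressResult(stress_free_nodes=X, iterations=it,
                                   final_error=err_mm * 1e3,
                                   error_history=errors, inflated_state=state)
        if len(errors) >= 2 and errors[-1] > errors[-2]:
            relax = 0.5
        X = X - relax * (x - X_target)
        u_warm = state.u
    raise NonConvergenceError(
        f"prestress did not reach {tol_um} um in {max_iter} iterations "
        f"(last error {errors[-1]:.3g} um)",
        state=SolverState(u=np.zeros(2 * len(X)), converged=False))
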