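"""Optical and mechanical outcome metrics.

Mean keratometry K_mean = (n - 1)/R with the keratometric index n = 1.3375
and R the radius (in meters) of the best-fit sphere to the anterior surface
over a 3 mm optical zone centred on the apex; axial length change as the
axial displacement of the anterior apex node; central corneal thickness
change from the two axis nodes; contact pressure and area from the converged
penalty contact forces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["KERATOMETRIC_INDEX", "OutcomeMetrics", "fit_best_sphere",
           "keratometry", "compute_outcomes", "contact_summary"]

KERATOMETRIC_INDEX = 1.3375


@dataclass
class OutcomeMetrics:
    k_pre: float                 # D
    k_post: float                # D
    delta_k_mean: float          # D
    delta_axial_length: float    # um
    delta_cct: float             # um
    max_contact_pressure: float  # kPa
    contact_area: float          # mm^2


def fit_best_sphere(points: np.ndarray, zone_diameter: float = 3.0) -> float:
    """Least-squares sphere radius (mm) from anterior (r, z) samples.

    Axisymmetry reduces the sphere fit to a circle fit in the half-plane with
    the centre constrained to the symmetry axis (an unconstrained fit would be
    ill-posed with half-plane data).  Zone membership uses the current radial
    coordinate.
    """
    pts = np.asarray(points, dtype=float)
    zone = pts[np.abs(pts[:, 0]) <= 0.5 * zone_diameter]
    if len(zone) < 5:
        raise ValueError("need at least 5 anterior nodes inside the optical zone")
    r, z = zone[:, 0], zone[:, 1]
    z_apex = z.max()

    def residual(q):
        z0, R = q
        return np.hypot(r, z - z0) - R

    R0 = 7.8
    sol = least_squares(residual, x0=[z_apex - R0, R0], method="lm")
    return float(sol.x[1])


def keratometry(points: np.ndarray, zone_diameter: float = 3.0,
                n_index: float = KERATOMETRIC_INDEX) -> float:
    """Mean keratometry in diopters; the fitted radius is converted to meters."""
    R_mm = fit_best_sphere(points, zone_diameter)
    return (n_index - 1.0) / (R_mm * 1e-3)


def contact_summary(x: np.ndarray, contact: dict, edges: np.ndarray):
    """Max nodal contact pressure (kPa) and active contact area (mm^2).

    Nodal pressure = |force| / (2 pi r * tributary length); the tributary
    length of a node is half the summed current length of its adjacent tunnel
    edges.  An edge counts toward the contact area when both its nodes carry
    contact force.
    """
    if not contact:
        return 0.0, 0.0
    forces = {}
    for pair in contact.values():
        for nd, f in zip(pair["nodes"], pair["force"]):
            forces[int(nd)] = forces.get(int(nd), 0.0) + float(np.hypot(*f))
    trib = {}
    e_nodes = np.asarray(edges, dtype=int)
    lengths = np.linalg.norm(x[e_nodes[:, 0]] - x[e_nodes[:, 1]], axis=1)
    for (n1, n2), L in zip(e_nodes, lengths):
        trib[int(n1)] = trib.get(int(n1), 0.0) + 0.5 * L
        trib[int(n2)] = trib.get(int(n2), 0.0) + 0.5 * L
    p_max = 0.0
    for nd, f in forces.items():
        if f <= 0.0 or nd not in trib:
            continue
        r = max(x[nd, 0], 1e-9)
        p_max = max(p_max, f / (2.0 * math.pi * r * trib[nd]))
    area = 0.0
    for (n1, n2), L in zip(e_nodes, lengths):
        if forces.get(int(n1), 0.0) > 0.0 and forces.get(int(n2), 0.0) > 0.0:
            rbar = 0.5 * (x[n1, 0] + x[n2, 0])
            area += 2.0 * math.pi * rbar * L
    return p_max, area


def compute_outcomes(mesh, x_pre: np.ndarray, x_post: np.ndarray,
                     contact: dict | None = None,
                     zone_diameter: float = 3.0) -> OutcomeMetrics:
    """Outcome metrics between the untreated (pre) and implanted (post)
    configurations given on the same node table."""
    ant = mesh.node_sets["anterior"]
    apex_ant = int(mesh.grid[0, 0])
    apex_post = int(mesh.grid[0, mesh.grid.shape[1] - 1])
    k_pre = keratometry(x_pre[ant], zone_diameter)
    k_post = keratometry(x_post[ant], zone_diameter)
    dal = (x_post[apex_ant, 1] - x_pre[apex_ant, 1]) * 1e3
    cct_pre = x_pre[apex_ant, 1] - x_pre[apex_post, 1]
    cct_post = x_post[apex_ant, 1] - x_post[apex_post, 1]
    dcct = (cct_post - cct_pre) * 1e3
    if contact:
        edges = np.concatenate([
            mesh.edge_nodes(mesh.edge_sets[k])
            for k in ("tunnel_upper", "tunnel_lower", "tunnel_tips")
            if len(mesh.edge_sets[k])])
        p_max, area = contact_summary(x_post, contact, edges)
    else:
        p_max, area = 0.0, 0.0
    return OutcomeMetrics(k_pre=k_pre, k_post=k_post,
                          delta_k_mean=k_post - k_pre,
                          delta_axial_length=dal, delta_cct=dcct,
                          max_contact_pressure=p_max, contact_area=area)
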