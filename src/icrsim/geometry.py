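"""Two-sphere average-cornea geometry.

The cornea is bounded by an anterior sphere (radius 7.80 mm) and a posterior
sphere (radius 6.78 mm) sharing the optical axis, with apical separation equal
to the central thickness (0.52 mm).  The corneoscleral rim sits where the
thickness measured along the anterior normal reaches the peripheral value
(0.68 mm).  Coordinates are (r, z) in mm with z along the optical axis,
positive anterior, and the anterior apex at z = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = ["CorneaGeometry"]


@dataclass(frozen=True)
class CorneaGeometry:
    anterior_radius: float = 7.80  # mm
    posterior_radius: float = 6.78  # mm
    central_thickness: float = 0.52  # mm
    peripheral_thickness: float = 0.68  # mm
    limbus_plane_angle: float = 40.0  # degrees, sliding plane at the rim

    def __post_init__(self):
        if self.anterior_radius <= self.posterior_radius:
            raise ValueError("anterior radius must exceed posterior radius")
        if not 0 < self.central_thickness < self.peripheral_thickness:
            raise ValueError("thickness must increase from apex to limbus")

    # -- surfaces -----------------------------------------------------------

    def anterior_point(self, phi):
        """Anterior-surface point at polar angle phi from the apex."""
        ra = self.anterior_radius
        phi = np.asarray(phi, dtype=float)
        return np.stack([ra * np.sin(phi), ra * (np.cos(phi) - 1.0)], axis=-1)

    def inward_normal(self, phi):
        """Unit vector from the anterior surface toward the anterior centre."""
        phi = np.asarray(phi, dtype=float)
        return np.stack([-np.sin(phi), -np.cos(phi)], axis=-1)

    def normal_thickness(self, phi):
        """Corneal thickness along the anterior normal at angle phi."""
        ra, rp, ct = self.anterior_radius, self.posterior_radius, self.central_thickness
        e = ra - ct - rp  # centre separation along the axis
        phi = np.asarray(phi, dtype=float)
        b = ra - e * np.cos(phi)  # = -(u . w)
        w2 = ra * ra - 2.0 * ra * e * np.cos(phi) + e * e
        disc = b * b - (w2 - rp * rp)
        if np.any(disc <= 0):
            raise ValueError("degenerate two-sphere geometry: arcs intersect")
        return b - np.sqrt(disc)

    def point(self, phi, t):
        """Material point at angle phi and depth fraction t (0 = anterior)."""
        phi = np.asarray(phi, dtype=float)
        t = np.asarray(t, dtype=float)
        a = self.anterior_point(phi)
        return a + (t * self.normal_thickness(phi))[..., None] * self.inward_normal(phi)

    def phi_at_depth_radius(self, r: float, t: float) -> float:
        """Polar angle at which the depth-fraction-``t`` surface has radial
        coordinate ``r`` (e.g. the tunnel centreline at r = diameter/2)."""
        f = lambda p: float(self.point(p, t)[0]) - r
        hi = self.rim_angle
        if f(hi) < 0:
            raise ValueError(f"radius {r} mm lies outside the corneal span")
        return float(brentq(f, 0.0, hi, xtol=1e-14))

    # -- rim ----------------------------------------------------------------

    @property
    def rim_angle(self) -> float:
        """Polar angle of the corneoscleral rim (normal thickness = peripheral)."""
        f = lambda p: self.normal_thickness(p) - self.peripheral_thickness
        hi = math.asin(min(0.999, 0.95 * self.posterior_radius / self.anterior_radius))
        if f(1e-6) >= 0 or f(hi) <= 0:
            raise ValueError("peripheral thickness unreachable on this geometry")
        return float(brentq(f, 1e-6, hi, xtol=1e-14))

    @property
    def rim_radius(self) -> float:
        return float(self.anterior_point(self.rim_angle)[0])

    def volume(self, n: int = 4000) -> float:
        """Solid-of-revolution volume between the surfaces (fine quadrature)."""
        phi = np.linspace(0.0, self.rim_angle, n)
        # integrate 2*pi*r over the quadrilateral strips of a fine (phi,t) grid
        tt = np.linspace(0.0, 1.0, 200)
        pts = self.point(phi[:, None], tt[None, :])  # (n, nt, 2)
        r, z = pts[..., 0], pts[..., 1]
        # shoelace per cell, exact for the polygonal approximation
        x00, y00 = r[:-1, :-1], z[:-1, :-1]
        x10, y10 = r[1:, :-1], z[1:, :-1]
        x11, y11 = r[1:, 1:], z[1:, 1:]
        x01, y01 = r[:-1, 1:], z[:-1, 1:]
        area = 0.5 * ((x00 * y10 - x10 * y00) + (x10 * y11 - x11 * y10)
                      + (x11 * y01 - x01 * y11) + (x01 * y00 - x00 * y01))
        rbar = 0.25 * (x00 + x10 + x11 + x01)
        return float(2.0 * math.pi * np.sum(np.abs(area) * rbar))
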