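"""Parametric intracorneal ring (ICR) cross-section library.

The campaign design sweeps 20 ring families (4 aspect-ratio categories x 5
cross-sectional primitives), each in 5 sizes and implanted at 3 optical
diameters, for 300 configurations in total.  Every family's largest size has
the same cross-sectional area; the smaller sizes are obtained by isotropic
scaling with factors 0.935, 0.869, 0.793 and 0.715 — except for the
Keraring-like family, whose horizontal dimension is fixed across sizes and
whose vertical dimension is scaled by the *squared* factors so that the area
series matches the isotropic families size-by-size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RingCrossSection",
    "ImplantConfig",
    "SIZE_FACTORS",
    "CATEGORY_RATIOS",
    "CATEGORY_BIN_EDGES",
    "DesignRegistry",
    "default_registry",
    "build_family",
    "classify_category",
    "enumerate_campaign",
    "polygon_area",
    "polygon_perimeter",
    "polygon_centroid",
    "polygon_is_simple",
]

#: Isotropic scale factors for sizes 2..5 (size 1 is the base, factor 1).
SIZE_FACTORS = (1.0, 0.935, 0.869, 0.793, 0.715)

#: Nominal horizontal/vertical ratio of each category.
CATEGORY_RATIOS = {
    "horizontal": 2.0,
    "rotated": 1.5,
    "square": 1.0,
    "vertical": 0.5,
}

#: Bin edges (midpoints between nominal ratios) used to classify a ratio.
CATEGORY_BIN_EDGES = (1.75, 1.25, 0.75)

#: Common cross-sectional area of all largest-size rings, mm^2.
BASE_AREA_MM2 = 0.09


# ---------------------------------------------------------------------------
# polygon helpers
# ---------------------------------------------------------------------------

def polygon_area(poly: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon (positive if CCW)."""
    p = np.asarray(poly, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_perimeter(poly: np.ndarray) -> float:
    p = np.asarray(poly, dtype=float)
    d = np.roll(p, -1, axis=0) - p
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def polygon_centroid(poly: np.ndarray) -> np.ndarray:
    """Area centroid of a simple polygon."""
    p = np.asarray(poly, dtype=float)
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def _segments_intersect(p1, p2, p3, p4) -> bool:
    """Proper intersection test for open segments p1p2 and p3p4."""

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if abs(v) < 1e-14 else (1 if v > 0 else -1)

    o1, o2 = orient(p1, p2, p3), orient(p1, p2, p4)
    o3, o4 = orient(p3, p4, p1), orient(p3, p4, p2)
    return o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4)


def polygon_is_simple(poly: np.ndarray) -> bool:
    """True if no two non-adjacent edges properly intersect (O(n^2) test)."""
    p = np.asarray(poly, dtype=float)
    n = len(p)
    for i in range(n):
        a, b = p[i], p[(i + 1) % n]
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue
            c, d = p[j], p[(j + 1) % n]
            if _segments_intersect(a, b, c, d):
                return False
    return True


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RingCrossSection:
    """A closed planar ring cross-section in local (horizontal, vertical) mm
    coordinates, centred at its area centroid."""

    family_id: str
    category: str
    polygon: np.ndarray  # (n, 2), CCW, closed implicitly (last != first)
    size_index: int  # 1..5, 1 = largest
    isotropic: bool = True

    def __post_init__(self):
        poly = np.asarray(self.polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
            raise ValueError("polygon must be an (n>=3, 2) vertex array")
        if not polygon_is_simple(poly):
            raise ValueError(f"ring polygon for {self.family_id!r} is self-intersecting")
        if polygon_area(poly) <= 0:
            raise ValueError("polygon must be counter-clockwise with positive area")
        object.__setattr__(self, "polygon", poly)

    @property
    def horizontal_extent(self) -> float:
        return float(np.ptp(self.polygon[:, 0]))

    @property
    def vertical_extent(self) -> float:
        return float(np.ptp(self.polygon[:, 1]))

    @property
    def area(self) -> float:
        return polygon_area(self.polygon)

    @property
    def ratio(self) -> float:
        return self.horizontal_extent / self.vertical_extent


@dataclass(frozen=True)
class ImplantConfig:
    """One campaign configuration: a cross-section at an optical diameter."""

    cross_section: RingCrossSection
    diameter: float  # mm, centre-line diameter of the ring
    depth_fraction: float = 0.75

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if not 0.0 < self.depth_fraction < 1.0:
            raise ValueError("depth_fraction must lie in (0, 1)")

    @property
    def key(self) -> tuple:
        return (self.cross_section.family_id, self.cross_section.size_index, self.diameter)


# ---------------------------------------------------------------------------
# unit primitives (extents exactly 1 x 1, centred at the centroid)
# ---------------------------------------------------------------------------

def _center(poly: np.ndarray) -> np.ndarray:
    return poly - polygon_centroid(poly)


def _unit_rect(fillet: float = 0.15, n_arc: int = 5) -> np.ndarray:
    """Rounded rectangle spanning [-0.5, 0.5]^2 with corner radius ``fillet``."""
    r = fillet
    pts = []
    corners = [(0.5 - r, 0.5 - r, 0.0), (-0.5 + r, 0.5 - r, 0.5 * math.pi),
               (-0.5 + r, -0.5 + r, math.pi), (0.5 - r, -0.5 + r, 1.5 * math.pi)]
    for cx, cy, a0 in corners:
        for t in np.linspace(a0, a0 + 0.5 * math.pi, n_arc):
            pts.append((cx + r * math.cos(t), cy + r * math.sin(t)))
    return _center(np.array(pts))


def _unit_ellipse(n: int = 48) -> np.ndarray:
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return _center(np.column_stack([0.5 * np.cos(t), 0.5 * np.sin(t)]))


def _round_corners(poly: np.ndarray, radius: float) -> np.ndarray:
    """Fillet the corners of a convex polygon (erosion-dilation) and rescale
    back to exactly unit extents.  Manufactured implant profiles carry such
    finishing radii, and smooth corners keep the contact solver stable."""
    from shapely.geometry import Polygon as _P
    from shapely.geometry.polygon import orient as _orient
    rounded = _P(poly).buffer(-radius).buffer(radius, quad_segs=4)
    xy = np.asarray(_orient(rounded, sign=1.0).exterior.coords)[:-1]
    xy = xy / np.array([np.ptp(xy[:, 0]), np.ptp(xy[:, 1])])
    return _center(xy)


def _unit_trapezoid(top: float = 0.5) -> np.ndarray:
    """Keraring-like wedge: flat base, narrower flat top, filleted."""
    h = top / 2.0
    poly = np.array([(-0.5, -0.5), (0.5, -0.5), (h, 0.5), (-h, 0.5)])
    return _round_corners(poly, 0.08)


def _unit_triangle() -> np.ndarray:
    """Isoceles triangle, apex up, filleted corners."""
    poly = np.array([(-0.5, -0.5), (0.5, -0.5), (0.0, 0.5)])
    return _round_corners(poly, 0.08)


def _unit_diamond() -> np.ndarray:
    poly = np.array([(0.5, 0.0), (0.0, 0.5), (-0.5, 0.0), (0.0, -0.5)])
    return _round_corners(poly, 0.08)


PRIMITIVES = {
    "rect": _unit_rect,
    "ellipse": _unit_ellipse,
    "trapezoid": _unit_trapezoid,
    "triangle": _unit_triangle,
    "diamond": _unit_diamond,
}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def classify_category(cs: RingCrossSection | float) -> str:
    """Classify by the horizontal/vertical extent ratio.

    Nearest of the nominal ratios {2, 1.5, 1, 0.5} using the bin edges
    (1.75, 1.25, 0.75).
    """
    ratio = cs if isinstance(cs, (int, float)) else cs.ratio
    if not np.isfinite(ratio) or ratio <= 0:
        raise ValueError("extent ratio must be positive and finite")
    e_h, e_r, e_s = CATEGORY_BIN_EDGES
    if ratio >= e_h:
        return "horizontal"
    if ratio >= e_r:
        return "rotated"
    if ratio >= e_s:
        return "square"
    return "vertical"


def build_family(base_polygon: np.ndarray, family_id: str,
                 isotropic: bool = True) -> list[RingCrossSection]:
    """Generate the 5 sizes of a family from its largest cross-section.

    Isotropic families scale both coordinates by the size factors; the
    Keraring mode (``isotropic=False``) keeps the horizontal dimension fixed
    and scales the vertical one by the squared factors, preserving the area
    series of the isotropic families.
    """
    base = np.asarray(base_polygon, dtype=float)
    if not polygon_is_simple(base):
        raise ValueError("base polygon is self-intersecting")
    if polygon_area(base) < 0:
        base = base[::-1]
    base = base - polygon_centroid(base)
    category = classify_category(float(np.ptp(base[:, 0]) / np.ptp(base[:, 1])))
    out = []
    for k, s in enumerate(SIZE_FACTORS, start=1):
        if isotropic:
            poly = base * s
        else:
            poly = base * np.array([1.0, s * s])
        poly = poly - polygon_centroid(poly)
        out.append(RingCrossSection(family_id=family_id, category=category,
                                    polygon=poly, size_index=k,
                                    isotropic=isotropic))
    return out


@dataclass
class FamilySpec:
    family_id: str
    primitive: str
    ratio: float  # nominal horizontal/vertical extent ratio
    isotropic: bool = True
    area: float = BASE_AREA_MM2
    aliases: tuple[str, ...] = ()

    def base_polygon(self) -> np.ndarray:
        unit = PRIMITIVES[self.primitive]()
        k = polygon_area(unit)  # shape factor: area / (H * V)
        h = math.sqrt(self.ratio * self.area / k)
        v = h / self.ratio
        return unit * np.array([h, v])


@dataclass
class DesignRegistry:
    """Ordered registry of ring families; the design unit of the campaign."""

    families: list[FamilySpec] = field(default_factory=list)

    def register(self, spec: FamilySpec) -> None:
        if any(f.family_id == spec.family_id for f in self.families):
            raise ValueError(f"duplicate family_id {spec.family_id!r}")
        self.families.append(spec)

    def cross_sections(self) -> list[RingCrossSection]:
        out = []
        for f in self.families:
            out.extend(build_family(f.base_polygon(), f.family_id, f.isotropic))
        return out

    def to_dict(self) -> dict:
        return {
            "families": [
                {"id": f.family_id, "primitive": f.primitive, "ratio": f.ratio,
                 "isotropic": f.isotropic, "area_mm2": f.area,
                 "aliases": list(f.aliases)}
                for f in self.families
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignRegistry":
        reg = cls()
        for f in d["families"]:
            reg.register(FamilySpec(f["id"], f["primitive"], float(f["ratio"]),
                                    bool(f.get("isotropic", True)),
                                    float(f.get("area_mm2", BASE_AREA_MM2)),
                                    tuple(f.get("aliases", ()))))
        return reg


def default_registry() -> DesignRegistry:
    """The 20-family campaign registry: 4 categories x 5 primitives.

    The horizontal trapezoid doubles as the Keraring-like family (fixed
    horizontal dimension across sizes); the horizontal ellipse and rotated
    rectangle stand in for the Intacs- and Myoring-like profiles via their
    public nominal aspect, not manufacturer drawings.
    """
    reg = DesignRegistry()
    for cat, ratio in CATEGORY_RATIOS.items():
        for prim in PRIMITIVES:
            fid = f"{cat}-{prim}"
            aniso = cat == "horizontal" and prim == "trapezoid"
            aliases: tuple[str, ...] = ()
            if aniso:
                aliases = ("keraring",)
            elif fid == "horizontal-ellipse":
                aliases = ("intacs",)
            elif fid == "rotated-rect":
                aliases = ("myoring",)
            reg.register(FamilySpec(fid, prim, ratio, isotropic=not aniso,
                                    aliases=aliases))
    return reg


def enumerate_campaign(designs: DesignRegistry | Sequence[RingCrossSection],
                       diameters: Iterable[float] = (5.0, 5.5, 6.0),
                       sizes: Iterable[int] | None = None,
                       depth_fraction: float = 0.75) -> list[ImplantConfig]:
    """Deterministic (family, size, diameter)-ordered campaign enumeration."""
    if isinstance(designs, DesignRegistry):
        sections = designs.cross_sections()
    else:
        sections = list(designs)
    keys = [(cs.family_id, cs.size_index) for cs in sections]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (family_id, size_index) in design list")
    size_filter = set(sizes) if sizes is not None else None
    diameters = sorted(set(float(d) for d in diameters))
    fam_order = {fid: i for i, fid in enumerate(dict.fromkeys(k[0] for k in keys))}
    sections.sort(key=lambda cs: (fam_order[cs.family_id], cs.size_index))
    configs = []
    for cs in sections:
        if size_filter is not None and cs.size_index not in size_filter:
            continue
        for d in diameters:
            configs.append(ImplantConfig(cs, d, depth_fraction))
    return configs
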