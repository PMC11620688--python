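"""Nearly-incompressible Yeoh hyperelasticity.

Strain energy W = sum_i C_i (Ibar1 - 3)^i + (kappa/2)(J - 1)^2, with Ibar1
the first invariant of the isochoric right Cauchy-Green tensor and J = det F.
At J = 1 this coincides with the incompressible Yeoh law with the corneal
parameters C1 = 35.5 kPa, C2 = 3.2 kPa, C3 = 1.9 kPa.  Incompressibility is
enforced by the volumetric penalty (default bulk modulus 1000 x 2 C1), which
the solver integrates selectively (isochoric term at the 2x2 Gauss points,
volumetric term at the element centroid) to avoid locking.

Unit system: mm - kPa - mN.  All functions broadcast over leading axes of F.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["YeohParams", "RingMaterial", "strain_energy", "first_piola_and_tangent",
           "stress_and_tangent", "cauchy_stress", "ElementInversionError"]


class ElementInversionError(ValueError):
    """det F <= 0 encountered; carries the offending (flat) state indices."""

    def __init__(self, where):
        self.where = np.atleast_1d(where)
        super().__init__(f"non-positive det F at state(s) {self.where[:10].tolist()}")


@dataclass(frozen=True)
class YeohParams:
    C1: float = 35.5  # kPa
    C2: float = 3.2   # kPa
    C3: float = 1.9   # kPa
    bulk_modulus: float | None = None  # kPa; default 1000 * 2 C1

    def __post_init__(self):
        if self.C1 <= 0:
            raise ValueError("C1 must be positive")
        if self.bulk_modulus is None:
            object.__setattr__(self, "bulk_modulus", 1e3 * 2.0 * self.C1)
        if self.bulk_modulus < 1e3 * 2.0 * self.C1 * (1 - 1e-12):
            raise ValueError("bulk modulus below the near-incompressibility floor")

    @property
    def shear_modulus(self) -> float:
        """Small-strain shear modulus mu = 2 C1."""
        return 2.0 * self.C1

    @property
    def poisson_ratio(self) -> float:
        mu, k = self.shear_modulus, self.bulk_modulus
        return (3 * k - 2 * mu) / (2 * (3 * k + mu))


@dataclass(frozen=True)
class RingMaterial:
    """PMMA-like ring stiffness; ~5e4 times stiffer than the corneal shear
    modulus, which justifies treating the implant as a rigid obstacle."""

    youngs_modulus: float = 3.6e6  # kPa (3600 MPa)
    poisson_ratio: float = 0.4

    def __post_init__(self):
        if not 0.0 < self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5)")


def _check_J(J):
    bad = ~(J > 0)
    if np.any(bad):
        raise ElementInversionError(np.nonzero(bad.ravel())[0])


def strain_energy(F, p: YeohParams, part: str = "both"):
    """Energy density (kPa) of the deformation gradient(s) F (..., 3, 3)."""
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    _check_J(J)
    W = 0.0
    if part in ("iso", "both"):
        I1 = np.einsum("...ij,...ij->...", F, F)
        x = J ** (-2.0 / 3.0) * I1 - 3.0
        W = W + p.C1 * x + p.C2 * x ** 2 + p.C3 * x ** 3
    if part in ("vol", "both"):
        W = W + 0.5 * p.bulk_modulus * (J - 1.0) ** 2
    return W


def first_piola_and_tangent(F, p: YeohParams, part: str = "both",
                            want_tangent: bool = True):
    """First Piola-Kirchhoff stress P = dW/dF and tangent A = d2W/dF dF.

    Returns (P (..., 3, 3), A (..., 3, 3, 3, 3)); the tangent has major
    symmetry A_ijkl = A_klij by construction (``A`` is None when
    ``want_tangent`` is False).
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    _check_J(J)
    Fit = np.swapaxes(np.linalg.inv(F), -1, -2)  # F^{-T}
    eye = np.eye(3)
    P = np.zeros_like(F)
    A = np.zeros(F.shape + (3, 3)) if want_tangent else None

    if part in ("iso", "both"):
        I1 = np.einsum("...ij,...ij->...", F, F)
        Jm23 = J ** (-2.0 / 3.0)
        x = Jm23 * I1 - 3.0
        psi1 = p.C1 + 2.0 * p.C2 * x + 3.0 * p.C3 * x ** 2
        G = 2.0 * Jm23[..., None, None] * (F - (I1 / 3.0)[..., None, None] * Fit)
        P = P + psi1[..., None, None] * G
        if want_tangent:
            psi11 = 2.0 * p.C2 + 6.0 * p.C3 * x
            d_ikjl = np.einsum("ik,jl->ijkl", eye, eye)
            FxFit = np.einsum("...ij,...kl->...ijkl", F, Fit)
            FitxF = np.einsum("...ij,...kl->...ijkl", Fit, F)
            FitxFit = np.einsum("...ij,...kl->...ijkl", Fit, Fit)
            Fit_kj_il = np.einsum("...kj,...il->...ijkl", Fit, Fit)
            I1e = I1[..., None, None, None, None]
            dG = 2.0 * Jm23[..., None, None, None, None] * (
                d_ikjl
                - (2.0 / 3.0) * (FxFit + FitxF)
                + (2.0 / 9.0) * I1e * FitxFit
                + (1.0 / 3.0) * I1e * Fit_kj_il
            )
            A = A + psi11[..., None, None, None, None] * np.einsum("...ij,...kl->...ijkl", G, G) \
                + psi1[..., None, None, None, None] * dG

    if part in ("vol", "both"):
        k = p.bulk_modulus
        a = k * (J - 1.0) * J
        P = P + a[..., None, None] * Fit
        if want_tangent:
            da = k * (2.0 * J - 1.0)
            A = A + (da * J)[..., None, None, None, None] * np.einsum("...ij,...kl->...ijkl", Fit, Fit) \
                - a[..., None, None, None, None] * np.einsum("...kj,...il->...ijkl", Fit, Fit)
    return P, A


#: component order of the reduced axisymmetric deformation gradient
#: (rR, rZ, zR, zZ, theta-theta)
F5_INDEX = ((0, 0), (0, 1), (1, 0), (1, 1), (2, 2))
_POS = {ij: c for c, ij in enumerate(F5_INDEX)}
# index maps for the term Fit_kj * Fit_il restricted to the reduced space;
# pairs outside the axisymmetric block structure are identically zero (slot 5)
_M1 = np.array([[_POS.get((k, j), 5) for (k, l) in F5_INDEX]
                for (i, j) in F5_INDEX])
_M2 = np.array([[_POS.get((i, l), 5) for (k, l) in F5_INDEX]
                for (i, j) in F5_INDEX])


def piola5_and_tangent5(F5, p: YeohParams, part: str = "both",
                        want_tangent: bool = True):
    """Reduced axisymmetric evaluation of P = dW/dF and A = d2W/dFdF.

    ``F5`` holds the five nonzero components (rR, rZ, zR, zZ, hoop) of the
    axisymmetric deformation gradient; the returned P5 (..., 5) and A5
    (..., 5, 5) are the restrictions of the full tensors to those
    components.  Algebraically identical to :func:`first_piola_and_tangent`
    on the embedded 3x3 gradient, but without 3x3x3x3 intermediates (the
    assembly hot path).
    """
    F5 = np.asarray(F5, dtype=float)
    a, b, c, d, e = (F5[..., k] for k in range(5))
    det2 = a * d - b * c
    J = det2 * e
    _check_J(J)
    # F^{-T} components in the same ordering
    Fit5 = np.stack([d / det2, -c / det2, -b / det2, a / det2, 1.0 / e], axis=-1)
    P = np.zeros_like(F5)
    A = np.zeros(F5.shape + (5,)) if want_tangent else None
    eye5 = np.eye(5)
    zero_pad = np.zeros(F5.shape[:-1] + (1,))
    Fit6 = np.concatenate([Fit5, zero_pad], axis=-1)
    T5 = Fit6[..., _M1] * Fit6[..., _M2] if want_tangent else None

    if part in ("iso", "both"):
        I1 = np.sum(F5 * F5, axis=-1)
        Jm23 = J ** (-2.0 / 3.0)
        x = Jm23 * I1 - 3.0
        psi1 = p.C1 + 2.0 * p.C2 * x + 3.0 * p.C3 * x ** 2
        G = 2.0 * Jm23[..., None] * (F5 - (I1 / 3.0)[..., None] * Fit5)
        P = P + psi1[..., None] * G
        if want_tangent:
            psi11 = 2.0 * p.C2 + 6.0 * p.C3 * x
            FxFit = F5[..., :, None] * Fit5[..., None, :]
            FitxFit = Fit5[..., :, None] * Fit5[..., None, :]
            I1e = I1[..., None, None]
            dG = 2.0 * Jm23[..., None, None] * (
                eye5 - (2.0 / 3.0) * (FxFit + np.swapaxes(FxFit, -1, -2))
                + (2.0 / 9.0) * I1e * FitxFit + (1.0 / 3.0) * I1e * T5)
            A = A + psi11[..., None, None] * (G[..., :, None] * G[..., None, :]) \
                + psi1[..., None, None] * dG

    if part in ("vol", "both"):
        k = p.bulk_modulus
        av = k * (J - 1.0) * J
        P = P + av[..., None] * Fit5
        if want_tangent:
            dav = k * (2.0 * J - 1.0)
            A = A + (dav * J)[..., None, None] * (Fit5[..., :, None] * Fit5[..., None, :]) \
                - av[..., None, None] * T5
    return P, A


def cauchy_stress(F, p: YeohParams, part: str = "both"):
    """Cauchy stress sigma = J^-1 P F^T."""
    F = np.asarray(F, dtype=float)
    P, _ = first_piola_and_tangent(F, p, part)
    J = np.linalg.det(F)
    return np.einsum("...iJ,...jJ->...ij", P, F) / J[..., None, None]


def stress_and_tangent(F, p: YeohParams, part: str = "both"):
    """Cauchy stress and spatial tangent moduli.

    The spatial tangent is the push-forward c_ijkl = J^-1 F_jJ F_lL A_iJkL of
    the material tangent; the solver itself works with (P, A) directly.
    """
    F = np.asarray(F, dtype=float)
    P, A = first_piola_and_tangent(F, p, part)
    J = np.linalg.det(F)
    sigma = np.einsum("...iJ,...jJ->...ij", P, F) / J[..., None, None]
    c = np.einsum("...iJkL,...jJ,...lL->...ijkl", A, F, F) / J[..., None, None, None, None]
    return sigma, c
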