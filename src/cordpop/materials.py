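"""Constitutive models of the contusion model's tissues.

One-dimensional (uniaxial, incompressible) response functions for the
tissue material models: one-term Ogden hyperelasticity (gray matter, dura),
Mooney-Rivlin with quasi-linear viscoelasticity (white matter), a Prony
reduced-relaxation series for every viscoelastic tissue, linear elasticity
(pia), and a Mie-Gruneisen Us-Up equation of state (cerebrospinal fluid).
These closed forms serve verification and the surrogate's stiffness
bookkeeping; they are not a 3-D finite-element constitutive update.

Convention note (conventions for Ogden differ by constant factors between
references and FE codes): the one-term Ogden strain energy used here is

    W = (mu1/alpha) * (lam1^alpha + lam2^alpha + lam3^alpha - 3)

whose incompressible uniaxial Cauchy stress is
``sigma = mu1*(lam^alpha - lam^(-alpha/2))`` and whose small-strain shear
modulus is ``mu1*alpha/2`` (gray matter: 34.7*7.61/2 = 132.0 kPa).

The white-matter parameters D and gamma are stored for completeness but are
not used by the incompressible 1-D operators; their role in the source QLV
formulation is ambiguous and deliberately left uninterpreted.  Stored
Poisson ratios are metadata only for the same reason.  Prony relaxation
times are taken to be seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "OgdenParams", "MooneyRivlinQLVParams", "PronySeries",
    "LinearElasticParams", "UsUpEosParams",
    "GRAY_MATTER_OGDEN", "WHITE_MATTER_MR", "DURA_OGDEN", "PIA_ELASTIC",
    "CSF_EOS", "GRAY_MATTER_PRONY", "WHITE_MATTER_PRONY", "DURA_PRONY",
    "MATERIAL_REGISTRY",
    "ogden_uniaxial_stress", "ogden_strain_energy",
    "mooney_rivlin_uniaxial_stress", "mooney_rivlin_strain_energy",
    "prony_g", "qlv_stress_history", "eos_pressure",
]


@dataclass(frozen=True)
class OgdenParams:
    """One-term Ogden hyperelastic parameters (mu1 in kPa)."""

    mu1: float
    alpha: float
    nu: float = 0.45          # metadata; 1-D operators are incompressible
    density: float = 1000.0   # kg/m^3

    def __post_init__(self) -> None:
        if self.mu1 * self.alpha <= 0:
            raise ValueError("mu1*alpha must be > 0 for a stable Ogden solid")
        if not -1.0 < self.nu < 0.5:
            raise ValueError("Poisson ratio must be in (-1, 0.5)")

    @property
    def shear_modulus(self) -> float:
        """Small-strain shear modulus mu1*alpha/2, kPa."""
        return self.mu1 * self.alpha / 2.0


@dataclass(frozen=True)
class MooneyRivlinQLVParams:
    """Mooney-Rivlin elastic core of the white-matter QLV model (kPa).

    ``d`` and ``gamma`` are carried verbatim but unused by the 1-D
    incompressible response (see module docstring).
    """

    c10: float
    c01: float
    d: float = 0.0
    gamma: float = 0.0
    nu: float = 0.49
    density: float = 1000.0

    def __post_init__(self) -> None:
        if self.c10 <= 0 or self.c10 + self.c01 <= 0:
            raise ValueError("require c10 > 0 and c10 + c01 > 0")


@dataclass(frozen=True)
class PronySeries:
    """Reduced relaxation g(t) = 1 - sum g_i (1 - exp(-t/tau_i)), tau in s."""

    g: tuple[float, ...]
    tau: tuple[float, ...]

    def __post_init__(self) -> None:
        g, tau = np.asarray(self.g, float), np.asarray(self.tau, float)
        if g.shape != tau.shape or g.ndim != 1 or g.size == 0:
            raise ValueError("g and tau must be equal-length 1-D sequences")
        if np.any(g <= 0) or g.sum() >= 1.0:
            raise ValueError("require g_i > 0 and sum g_i < 1")
        if np.any(np.diff(tau) <= 0) or np.any(tau <= 0):
            raise ValueError("tau_i must be positive and strictly increasing")

    @property
    def long_term(self) -> float:
        """g(inf) = 1 - sum g_i."""
        return 1.0 - float(np.sum(self.g))


@dataclass(frozen=True)
class LinearElasticParams:
    """Linear elastic (E in MPa)."""

    E: float
    nu: float
    density: float = 1000.0


@dataclass(frozen=True)
class UsUpEosParams:
    """Mie-Gruneisen EOS with linear Us-Up Hugoniot (c0 in m/s)."""

    c0: float
    s: float
    gamma0: float
    density: float = 1000.0


# Tissue parameter registry (densities kg/m^3; moduli kPa unless noted)
GRAY_MATTER_OGDEN = OgdenParams(mu1=34.7, alpha=7.61, nu=0.45, density=1045)
GRAY_MATTER_PRONY = PronySeries(g=(0.4183, 0.2252, 0.1213),
                                tau=(0.64, 6.4, 64.0))
WHITE_MATTER_MR = MooneyRivlinQLVParams(c10=3270.0, c01=910.0, d=239.3,
                                        gamma=6172.0, nu=0.49, density=1041)
WHITE_MATTER_PRONY = PronySeries(g=(0.5256, 0.3163, 0.125, 0.007),
                                 tau=(0.01, 0.02, 0.2, 2.0))
DURA_OGDEN = OgdenParams(mu1=3250.0, alpha=16.2, nu=0.45, density=1174)
DURA_PRONY = PronySeries(g=(0.318, 0.128, 0.0997, 0.0997),
                         tau=(0.0009, 0.081, 0.564, 4.69))
PIA_ELASTIC = LinearElasticParams(E=39.3, nu=0.3, density=1075)
CSF_EOS = UsUpEosParams(c0=1381.7, s=1.979, gamma0=0.11, density=1007)

MATERIAL_REGISTRY = {
    "gray_matter": {"elastic": GRAY_MATTER_OGDEN, "prony": GRAY_MATTER_PRONY},
    "white_matter": {"elastic": WHITE_MATTER_MR, "prony": WHITE_MATTER_PRONY},
    "dura": {"elastic": DURA_OGDEN, "prony": DURA_PRONY},
    "pia": {"elastic": PIA_ELASTIC, "prony": None},
    "csf": {"elastic": CSF_EOS, "prony": None},
}


def _check_stretch(lam) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch lam must be > 0")
    return lam


def ogden_strain_energy(p: OgdenParams, lam) -> np.ndarray | float:
    """Incompressible uniaxial strain energy density W(lam), kPa."""
    lam = _check_stretch(lam)
    w = (p.mu1 / p.alpha) * (lam ** p.alpha
                             + 2.0 * lam ** (-p.alpha / 2.0) - 3.0)
    return w if w.ndim else float(w)


def ogden_uniaxial_stress(p: OgdenParams, lam) -> np.ndarray | float:
    """Incompressible uniaxial Cauchy stress, kPa.

    sigma = mu1 * (lam^alpha - lam^(-alpha/2)); zero at lam=1, same sign
    as lam - 1.
    """
    lam = _check_stretch(lam)
    s = p.mu1 * (lam ** p.alpha - lam ** (-p.alpha / 2.0))
    return s if s.ndim else float(s)


def mooney_rivlin_strain_energy(p: MooneyRivlinQLVParams,
                                lam) -> np.ndarray | float:
    """W = c10*(I1-3) + c01*(I2-3) for incompressible uniaxial stretch."""
    lam = _check_stretch(lam)
    i1 = lam ** 2 + 2.0 / lam
    i2 = 2.0 * lam + lam ** -2
    w = p.c10 * (i1 - 3.0) + p.c01 * (i2 - 3.0)
    return w if w.ndim else float(w)


def mooney_rivlin_uniaxial_stress(p: MooneyRivlinQLVParams,
                                  lam) -> np.ndarray | float:
    """sigma = 2*(lam^2 - 1/lam)*(c10 + c01/lam), kPa; zero at lam=1."""
    lam = _check_stretch(lam)
    s = 2.0 * (lam ** 2 - 1.0 / lam) * (p.c10 + p.c01 / lam)
    return s if s.ndim else float(s)


def prony_g(p: PronySeries, t) -> np.ndarray | float:
    """Reduced relaxation factor g(t); g(0)=1, g(inf)=1-sum g_i."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time t must be >= 0")
    g = np.asarray(p.g)[:, None]
    tau = np.asarray(p.tau)[:, None]
    out = 1.0 - np.sum(g * (1.0 - np.exp(-t.ravel()[None, :] / tau)), axis=0)
    out = out.reshape(t.shape)
    return out if out.ndim else float(out)


def qlv_stress_history(elastic_op: Callable[[np.ndarray], np.ndarray],
                       p: PronySeries,
                       strain_history: Sequence[float],
                       times: Sequence[float]) -> np.ndarray:
    """Quasi-linear viscoelastic stress history.

    Evaluates the hereditary integral
    ``sigma(t) = int_0^t g(t - s) d sigma_e(eps(s))`` with the standard
    recursive exponential update, exact when the instantaneous elastic
    stress ``sigma_e`` is piecewise linear in time between the supplied
    samples.  ``elastic_op`` maps stretch (1 + engineering strain) to
    instantaneous stress; ``times`` must be strictly increasing from 0.
    A step strain relaxes from sigma_e to (1 - sum g_i) * sigma_e.
    """
    t = np.asarray(times, dtype=float)
    eps = np.asarray(strain_history, dtype=float)
    if t.ndim != 1 or t.shape != eps.shape:
        raise ValueError("times and strain_history must be 1-D, same length")
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing from 0")
    sig_e = np.asarray(elastic_op(1.0 + eps), dtype=float)
    g = np.asarray(p.g)
    tau = np.asarray(p.tau)
    g_inf = 1.0 - g.sum()
    sigma = np.empty_like(sig_e)
    # per-term viscous state q_i(t) = int_0^t g_i exp(-(t-s)/tau_i) dsig_e(s);
    # the initial value sig_e(0) enters as a step at t=0
    q = g * sig_e[0]
    sigma[0] = g_inf * sig_e[0] + q.sum()
    for k in range(1, t.size):
        dt = t[k] - t[k - 1]
        dsig = sig_e[k] - sig_e[k - 1]
        e = np.exp(-dt / tau)
        q = e * q + g * (tau / dt) * (1.0 - e) * dsig
        sigma[k] = g_inf * sig_e[k] + q.sum()
    return sigma


def eos_pressure(p: UsUpEosParams, eta, e_m=0.0) -> np.ndarray | float:
    """Mie-Gruneisen pressure with a linear Us-Up Hugoniot, Pa.

    ``eta`` is the nominal volumetric compression 1 - rho0/rho and ``e_m``
    the internal energy per unit mass (J/kg):

        p = rho0*c0^2*eta*(1 - gamma0*eta/2) / (1 - s*eta)^2
            + gamma0*rho0*e_m

    Zero at (eta, e_m) = (0, 0); the small-eta slope is the bulk modulus
    rho0*c0^2.  Raises for eta at or beyond the Hugoniot pole 1/s.
    """
    eta = np.asarray(eta, dtype=float)
    if np.any(eta >= 1.0 / p.s):
        raise ValueError(
            f"volumetric compression eta must be below the Hugoniot "
            f"singularity 1/s = {1.0 / p.s:.4g}")
    e_m = np.asarray(e_m, dtype=float)
    k0 = p.density * p.c0 ** 2
    out = (k0 * eta * (1.0 - p.gamma0 * eta / 2.0) / (1.0 - p.s * eta) ** 2
           + p.gamma0 * p.density * e_m)
    return out if out.ndim else float(out)
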