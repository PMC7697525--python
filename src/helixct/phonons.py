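"""Characteristic frequencies and analytic phonon dispersion relations.

For a homopolymer the linearized twist/radial equations admit helical
plane-wave solutions, and the 2x2 secular problem yields an acoustic
branch (collective twist, omega -> 0 as q -> 0) and an optical branch
(H-bond stretch/stacking, finite omega(0)).  All frequencies are stored
as angular frequencies in rad/s; use the ``nu_*`` accessors for THz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import HelixFrame, derive_frame
from .params import (
    ACCEL_EV_AMU_NM2,
    BasePairSpecies,
    ModelParams,
    angular_frequency_to_thz,
    default_params,
)

__all__ = [
    "CharacteristicFrequencies",
    "DispersionCurve",
    "characteristic_frequencies",
    "coupling_constants",
    "secular_matrix",
    "dispersion_exact",
    "dispersion_approx",
    "phonon_gaps",
    "sound_velocity",
    "sound_velocity_closed_form",
    "frequency_table",
]

_OSCILLATION_LABELS = [
    ("Twist", "omega_phi"),
    ("Stacking", "omega_S"),
    ("H-Bonding", "omega_H"),
    ("Twist-Stacking", "omega_phiS"),
    ("Twist-Radial", "omega_phirho"),
    ("Stretch-Stacking", "omega_HS"),
]


@dataclass(frozen=True)
class CharacteristicFrequencies:
    """The six characteristic angular frequencies (rad/s) of a homopolymer.

    omega_phi: twist; omega_S: stacking; omega_H: H-bond stretch;
    omega_phiS / omega_phirho: twist-stacking and twist-radial coupled
    frequencies; omega_HS: stretch-stacking coupling, satisfying
    omega_HS^2 = mu (omega_H^2 + 2 omega_S^2) exactly.
    """

    omega_phi: float
    omega_S: float
    omega_H: float
    omega_phiS: float
    omega_phirho: float
    omega_HS: float

    def nu(self, name: str) -> float:
        """Ordinary frequency (THz) for one of the omega_* field names."""
        return angular_frequency_to_thz(getattr(self, name))

    def tau(self, name: str) -> float:
        """Time scale 1/nu (ps)."""
        return 1.0 / self.nu(name)

    @property
    def nu_phi(self) -> float:
        return self.nu("omega_phi")

    @property
    def nu_S(self) -> float:
        return self.nu("omega_S")

    @property
    def nu_H(self) -> float:
        return self.nu("omega_H")

    @property
    def nu_phiS(self) -> float:
        return self.nu("omega_phiS")

    @property
    def nu_phirho(self) -> float:
        return self.nu("omega_phirho")

    @property
    def nu_HS(self) -> float:
        return self.nu("omega_HS")


@dataclass(frozen=True)
class DispersionCurve:
    """Two-branch phonon dispersion sampled on a wavevector grid.

    q in 1/nm; omega_minus (acoustic) and omega_plus (optical) in rad/s.
    """

    q: np.ndarray
    omega_minus: np.ndarray
    omega_plus: np.ndarray
    species: str
    exact: bool

    @property
    def nu_minus(self) -> np.ndarray:
        return self.omega_minus / (2.0 * math.pi * 1e12)

    @property
    def nu_plus(self) -> np.ndarray:
        return self.omega_plus / (2.0 * math.pi * 1e12)


def characteristic_frequencies(
    params: ModelParams, frame: HelixFrame | None = None
) -> CharacteristicFrequencies:
    """Compute the six characteristic frequencies from the parameter set.

    omega_phi^2  = (2 kB / M) [f0/(xi l0)]^2
    omega_H^2    = D alpha^2 / (2 M)
    omega_S^2    = kS / M
    omega_phirho^2 = mu (omega_H^2 + omega_S^2) + [(1+lambda^2)/lambda] bB^2 omega_phi^2
    omega_phiS^2   = mu omega_S^2 - [(1+lambda^2)/lambda] bB^2 omega_phi^2
    omega_HS^2     = mu (omega_H^2 + 2 omega_S^2)
    """
    if frame is None:
        frame = derive_frame(params.geometry)
    lat = params.lattice
    lam = params.pair.lambda_
    mu = params.pair.mu

    w_phi2 = (2.0 * lat.kB / lat.M) * (frame.f0 / (frame.xi * frame.l0)) ** 2
    w_H2 = lat.D * lat.alpha**2 / (2.0 * lat.M)
    w_S2 = lat.kS / lat.M
    # convert eV/(amu nm^2) -> s^-2 once, here
    w_phi2 *= ACCEL_EV_AMU_NM2
    w_H2 *= ACCEL_EV_AMU_NM2
    w_S2 *= ACCEL_EV_AMU_NM2

    cross = (1.0 + lam**2) / lam * frame.bB**2 * w_phi2
    w_phirho2 = mu * (w_H2 + w_S2) + cross
    w_phiS2 = mu * w_S2 - cross
    w_HS2 = mu * (w_H2 + 2.0 * w_S2)
    return CharacteristicFrequencies(
        omega_phi=math.sqrt(w_phi2),
        omega_S=math.sqrt(w_S2),
        omega_H=math.sqrt(w_H2),
        omega_phiS=math.sqrt(w_phiS2),
        omega_phirho=math.sqrt(w_phirho2),
        omega_HS=math.sqrt(w_HS2),
    )


def coupling_constants(
    pair: BasePairSpecies, frame: HelixFrame
) -> tuple[float, float, float]:
    """Twist-radial coupling constants (A_lambda, B_lambda, C_lambda).

    A_lambda = (1 + lambda)/lB  (1/nm), B_lambda = aB (1 + 1/lambda)/2 (nm),
    C_lambda = A_lambda B_lambda (dimensionless).
    """
    lam = pair.lambda_
    a = (1.0 + lam) / frame.lB
    b = frame.aB * (1.0 + 1.0 / lam) / 2.0
    return a, b, a * b


def _g_h(q, cf: CharacteristicFrequencies, frame: HelixFrame):
    q = np.asarray(q, dtype=float)
    g = 4.0 * cf.omega_phi**2 * np.sin(q * frame.xi / 2.0) ** 2
    h = cf.omega_phirho**2 - cf.omega_phiS**2 * np.cos(q * frame.xi)
    return g, h


def secular_matrix(
    omega: float,
    q: float,
    cf: CharacteristicFrequencies,
    frame: HelixFrame,
    pair: BasePairSpecies,
) -> np.ndarray:
    """2x2 complex secular matrix of the helical-wave eigenproblem.

    [[2 w_phi^2 (1-cos q xi) - w^2,   2i A w_phi^2 sin q xi       ],
     [-2i B w_phi^2 sin q xi,         w_phirho^2 - w_phiS^2 cos q xi - w^2]]

    Its determinant vanishes exactly on the two dispersion branches.
    """
    a_l, b_l, _ = coupling_constants(pair, frame)
    s = math.sin(q * frame.xi)
    g, h = _g_h(q, cf, frame)
    return np.array(
        [
            [g - omega**2, 2j * a_l * cf.omega_phi**2 * s],
            [-2j * b_l * cf.omega_phi**2 * s, h - omega**2],
        ],
        dtype=complex,
    )


def dispersion_exact(
    q_grid,
    cf: CharacteristicFrequencies,
    frame: HelixFrame,
    pair: BasePairSpecies,
) -> DispersionCurve:
    """Exact two-branch dispersion from the vanishing secular determinant.

    omega_pm^2 = (G+H)/2 +- (1/2) sqrt[(H-G)^2 + 16 C w_phi^4 sin^2(q xi)]
    with G = 4 w_phi^2 sin^2(q xi/2), H = w_phirho^2 - w_phiS^2 cos(q xi).
    """
    q = np.atleast_1d(np.asarray(q_grid, dtype=float))
    _, _, c_l = coupling_constants(pair, frame)
    g, h = _g_h(q, cf, frame)
    root = np.sqrt(
        (h - g) ** 2 + 16.0 * c_l * cf.omega_phi**4 * np.sin(q * frame.xi) ** 2
    )
    w_minus2 = np.clip((g + h - root) / 2.0, 0.0, None)
    w_plus2 = (g + h + root) / 2.0
    return DispersionCurve(
        q=q,
        omega_minus=np.sqrt(w_minus2),
        omega_plus=np.sqrt(w_plus2),
        species=pair.name,
        exact=True,
    )


def dispersion_approx(
    q_grid,
    cf: CharacteristicFrequencies,
    frame: HelixFrame,
    pair: BasePairSpecies,
) -> DispersionCurve:
    """Decoupled-branch approximation.

    nu_minus^2 = 4 nu_phi^2 sin^2(q xi/2);
    nu_plus^2  = mu [nu_H^2 + 2 nu_S^2 sin^2(q xi/2)].
    Accurate to better than 2% across the Brillouin zone for the default
    parameter set; nu_plus(pi/xi) equals nu_HS identically.
    """
    q = np.atleast_1d(np.asarray(q_grid, dtype=float))
    s2 = np.sin(q * frame.xi / 2.0) ** 2
    w_minus = 2.0 * cf.omega_phi * np.sqrt(s2)
    w_plus = np.sqrt(pair.mu * (cf.omega_H**2 + 2.0 * cf.omega_S**2 * s2))
    return DispersionCurve(
        q=q,
        omega_minus=w_minus,
        omega_plus=w_plus,
        species=pair.name,
        exact=False,
    )


def phonon_gaps(
    cf: CharacteristicFrequencies, frame: HelixFrame, pair: BasePairSpecies
) -> dict:
    """Branch separations Delta nu(0) and Delta nu(q*) in THz.

    The gap is minimal at q = 0 (where it is set by the H-bond frequency)
    and maximal at the zone boundary q* = pi/xi.
    """
    curve = dispersion_exact(np.array([0.0, frame.qstar]), cf, frame, pair)
    dnu = curve.nu_plus - curve.nu_minus
    return {"dnu_q0_thz": float(dnu[0]), "dnu_qstar_thz": float(dnu[1]), "qstar": frame.qstar}


def sound_velocity(
    cf: CharacteristicFrequencies,
    frame: HelixFrame,
    pair: BasePairSpecies,
    q_probe: float = 1e-3,
) -> float:
    """Acoustic sound velocity d(omega_-)/dq at q -> 0, in km/s.

    Two-point stencil at q = ``q_probe`` (1/nm); omega/q in (rad/s)/(1/nm)
    = nm/s, converted to km/s.
    """
    curve = dispersion_exact(np.array([q_probe]), cf, frame, pair)
    return float(curve.omega_minus[0] / q_probe) * 1e-12


def sound_velocity_closed_form(
    cf: CharacteristicFrequencies, frame: HelixFrame, pair: BasePairSpecies
) -> float:
    """Closed-form q->0 slope xi w_phi sqrt(1 - 4 C w_phi^2 / H(0)), km/s."""
    _, _, c_l = coupling_constants(pair, frame)
    h0 = cf.omega_phirho**2 - cf.omega_phiS**2
    v = frame.xi * cf.omega_phi * math.sqrt(1.0 - 4.0 * c_l * cf.omega_phi**2 / h0)
    return v * 1e-12


def frequency_table(species_list: list[str] | None = None) -> pd.DataFrame:
    """Six-row characteristic-frequency table per species.

    Columns: species, oscillation, symbol, omega_1e12_rad_s, nu_thz, tau_ps.
    """
    if species_list is None:
        species_list = ["GC", "AT"]
    rows = []
    for sp in species_list:
        params = default_params(sp)
        frame = derive_frame(params.geometry)
        cf = characteristic_frequencies(params, frame)
        for label, attr in _OSCILLATION_LABELS:
            omega = getattr(cf, attr)
            nu = angular_frequency_to_thz(omega)
            rows.append(
                {
                    "species": sp,
                    "oscillation": label,
                    "symbol": attr,
                    "omega_1e12_rad_s": omega / 1e12,
                    "nu_thz": nu,
                    "tau_ps": 1.0 / nu,
                }
            )
    return pd.DataFrame(rows)
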