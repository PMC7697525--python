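"""Model parameter registry and unit conventions.

Internal unit system: lengths in nm, energies in eV, masses in amu, angles
in rad.  A single audited constant, :data:`ACCEL_EV_AMU_NM2`, converts a
squared angular frequency expressed in eV/(amu nm^2) to SI s^-2; every
frequency reported by the package goes through it exactly once.

The defaults encode the standard homopolymer parameter set for B-form
dsDNA: geometry (equilibrium twist theta0, rise h0, radius R0), the
Peyrard-Dauxois-Bishop lattice constants (Morse depth/width, stacking
stiffness and range, backbone spring constant, base-pair mass) and the
tight-binding electronic constants (base on-site energies, glycosidic
hopping tP, backbone on-site energy gamma, face-to-face pi-pi transfer
integral t0, Slater-Koster hybridization ratios).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Mapping

from scipy import constants as _const

__all__ = [
    "ACCEL_EV_AMU_NM2",
    "HBAR2_OVER_ME_EV_NM2",
    "BASE_MASSES_AMU",
    "GeometryParams",
    "LatticeParams",
    "BasePairSpecies",
    "ElectronicParams",
    "ModelParams",
    "default_params",
    "angular_frequency_to_thz",
    "thz_to_angular_frequency",
    "period_ps",
]

#: Converts omega^2 in eV/(amu nm^2) to s^-2 (== e / (amu * 1e-18 m^2)).
ACCEL_EV_AMU_NM2: float = _const.e / (_const.atomic_mass * 1e-18)

#: hbar^2 / m_e in eV nm^2 (~0.0762), used by the Slater-Koster prefactor.
HBAR2_OVER_ME_EV_NM2: float = _const.hbar**2 / (_const.m_e * _const.e) * 1e18

#: Nucleobase masses in amu.
BASE_MASSES_AMU: Mapping[str, float] = MappingProxyType(
    {"G": 347.05, "C": 307.05, "A": 331.06, "T": 322.05}
)


def angular_frequency_to_thz(omega: float) -> float:
    """Convert an angular frequency (rad/s) to an ordinary frequency in THz."""
    if omega < 0:
        raise ValueError("angular frequency must be non-negative")
    return omega / (2.0 * math.pi * 1e12)


def thz_to_angular_frequency(nu: float) -> float:
    """Inverse of :func:`angular_frequency_to_thz`."""
    if nu < 0:
        raise ValueError("frequency must be non-negative")
    return nu * 2.0 * math.pi * 1e12


def period_ps(nu_thz: float) -> float:
    """Oscillation period tau = 1/nu in picoseconds, for nu in THz."""
    if nu_thz <= 0:
        raise ValueError("frequency must be positive")
    return 1.0 / nu_thz


@dataclass(frozen=True)
class GeometryParams:
    """Equilibrium double-helix geometry.

    theta0: equilibrium twist angle between consecutive base pairs (rad).
    h0: rise per base pair along the helix axis (nm).
    R0: helix radius (nm).
    """

    theta0: float = math.pi / 5.2
    h0: float = 0.34
    R0: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.theta0 < math.pi):
            raise ValueError("theta0 must lie in (0, pi)")
        if self.h0 <= 0 or self.R0 <= 0:
            raise ValueError("h0 and R0 must be positive")


@dataclass(frozen=True)
class LatticeParams:
    """Lattice (PDB-model) constants, all in the internal unit system.

    Note the stacking range b and Morse width alpha are conventionally
    quoted in 1/Angstrom; they are stored here in 1/nm (x10), and the
    spring constants, quoted in eV/A^2, are stored in eV/nm^2 (x100).
    """

    kB: float = 4.0  # backbone spring constant, eV/nm^2  (0.04 eV/A^2)
    kS: float = 70.0  # stacking stiffness, eV/nm^2        (0.7 eV/A^2)
    b: float = 5.0  # stacking range, 1/nm                (0.5 1/A)
    D: float = 0.15  # Morse depth, eV
    alpha: float = 50.0  # Morse inverse width, 1/nm      (5 1/A)
    M: float = 653.5  # base-pair mass, amu

    def __post_init__(self) -> None:
        for name in ("kB", "kS", "b", "D", "alpha", "M"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class BasePairSpecies:
    """A Watson-Crick pair reduced to its two point masses.

    The convention is lambda = m_heavy / m_light >= 1, the heavier base
    sitting on the reference strand, so that the complementary radial
    displacement is rho_bar = lambda * rho.  mu = (1 + lambda)^2 / lambda
    is the reduced-mass factor entering the coupled radial frequencies.
    """

    name: str
    mass_heavy: float
    mass_light: float

    def __post_init__(self) -> None:
        if self.mass_heavy < self.mass_light:
            raise ValueError("convention requires mass_heavy >= mass_light")

    @classmethod
    def from_name(cls, name: str) -> "BasePairSpecies":
        if name == "GC":
            return cls("GC", BASE_MASSES_AMU["G"], BASE_MASSES_AMU["C"])
        if name == "AT":
            return cls("AT", BASE_MASSES_AMU["A"], BASE_MASSES_AMU["T"])
        raise ValueError(f"unknown base-pair species {name!r}; expected 'GC' or 'AT'")

    @property
    def lambda_(self) -> float:
        return self.mass_heavy / self.mass_light

    @property
    def mu(self) -> float:
        lam = self.lambda_
        return (1.0 + lam) ** 2 / lam

    @property
    def pair_mass(self) -> float:
        return self.mass_heavy + self.mass_light


@dataclass(frozen=True)
class ElectronicParams:
    """Tight-binding electronic constants (energies in eV).

    Base on-site energies quoted as literature ranges are stored as
    (low, high) intervals; band-structure defaults bypass them and use
    the pair coefficients a_xy = eps_X + eps_Y and
    b_xy = (eps_X^2 + eps_Y^2)/(2 tP^2) directly, so the published band
    quantities do not depend on a within-range choice.

    t_perp is stored for completeness but is not used by the default
    renormalization chain (its insertion point in the first decimation
    step is not defined unambiguously).
    """

    eps_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: MappingProxyType(
            {"G": (7.8, 8.2), "A": (8.2, 8.2), "C": (8.9, 8.9), "T": (9.0, 9.1)}
        )
    )
    tP: float = 1.5  # glycosidic hopping, eV
    gamma: float = 0.0  # backbone on-site energy, eV (literature range 0..12)
    t_perp: float = 0.01  # interstrand hopping, eV (stored, unused)
    t0: float = 0.08  # optimal face-to-face transfer integral, eV
    eta_ppsigma: float = 5.27
    eta_pppi: float = -2.26
    phi0: float = 0.14  # twist oscillation amplitude, rad (~8 deg)
    rho0: float = 0.05  # radial oscillation amplitude, nm
    a_xy: float = 16.6  # eps_X + eps_Y, eV
    b_xy: float = 30.9  # (eps_X^2 + eps_Y^2)/(2 tP^2), dimensionless

    def __post_init__(self) -> None:
        if self.tP == 0:
            raise ValueError("tP must be non-zero")
        if self.eta_ppsigma <= 0:
            raise ValueError("eta_ppsigma must be positive")

    @property
    def eta_bar(self) -> float:
        """eta_bar = 1 + |eta_pppi| / eta_ppsigma (> 1)."""
        return 1.0 + abs(self.eta_pppi) / self.eta_ppsigma

    def amplitude_sq(self, R0: float) -> float:
        """Helical-wave amplitude factor A0^2 = phi0^2 + (rho0/R0)^2."""
        return self.phi0**2 + (self.rho0 / R0) ** 2


_ELECTRONIC_BY_SPECIES = {
    "GC": dict(t0=0.08, t_perp=0.01, a_xy=16.6, b_xy=30.9),
    "AT": dict(t0=0.09, t_perp=0.02, a_xy=17.4, b_xy=33.6),
}


@dataclass(frozen=True)
class ModelParams:
    """Complete, immutable parameter set for one homopolymer species.

    Parameter scans should derive modified copies via
    :func:`dataclasses.replace` rather than mutate in place.
    """

    species: str
    geometry: GeometryParams
    lattice: LatticeParams
    pair: BasePairSpecies
    electronic: ElectronicParams

    def with_electronic(self, **changes) -> "ModelParams":
        return replace(self, electronic=replace(self.electronic, **changes))

    def with_lattice(self, **changes) -> "ModelParams":
        return replace(self, lattice=replace(self.lattice, **changes))

    def as_dict(self) -> dict:
        """Flat JSON-serializable view of the full registry."""
        e = self.electronic
        return {
            "species": self.species,
            "geometry": {
                "theta0_rad": self.geometry.theta0,
                "h0_nm": self.geometry.h0,
                "R0_nm": self.geometry.R0,
            },
            "lattice": {
                "kB_eV_nm2": self.lattice.kB,
                "kS_eV_nm2": self.lattice.kS,
                "b_inv_nm": self.lattice.b,
                "D_eV": self.lattice.D,
                "alpha_inv_nm": self.lattice.alpha,
                "M_amu": self.lattice.M,
            },
            "pair": {
                "mass_heavy_amu": self.pair.mass_heavy,
                "mass_light_amu": self.pair.mass_light,
                "lambda": self.pair.lambda_,
                "mu": self.pair.mu,
            },
            "electronic": {
                "eps_ranges_eV": {k: list(v) for k, v in e.eps_ranges.items()},
                "tP_eV": e.tP,
                "gamma_eV": e.gamma,
                "t_perp_eV": e.t_perp,
                "t0_eV": e.t0,
                "eta_ppsigma": e.eta_ppsigma,
                "eta_pppi": e.eta_pppi,
                "eta_bar": e.eta_bar,
                "phi0_rad": e.phi0,
                "rho0_nm": e.rho0,
                "a_xy_eV": e.a_xy,
                "b_xy": e.b_xy,
            },
        }


def default_params(species: str) -> ModelParams:
    """Default parameter registry for a 'GC' or 'AT' homopolymer.

    lambda and mu are computed from the base masses; the per-species
    electronic constants (t0, t_perp, a_xy, b_xy) are the standard
    homopolymer values.
    """
    pair = BasePairSpecies.from_name(species)  # raises for unknown names
    return ModelParams(
        species=species,
        geometry=GeometryParams(),
        lattice=LatticeParams(),
        pair=pair,
        electronic=ElectronicParams(**_ELECTRONIC_BY_SPECIES[species]),
    )
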