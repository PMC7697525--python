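"""Potential energies of the lattice Hamiltonian and numerical derivatives.

These are the full (nonlinear) PDB-type potentials: Morse hydrogen-bond
stretching, anharmonically modulated stacking, and the harmonic backbone
term evaluated with the exact helical inter-base distance.  The linearized
equations integrated by :mod:`helixct.dynamics` are derived analytically;
the functions here serve the simulator's energy logs and, through the
finite-difference Hessian, an independent check on that linearization.

Forces are obtained by numerically differentiating the clean potentials
(central differences) rather than from hand-expanded force expressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import HelixFrame, pair_distance
from .params import ACCEL_EV_AMU_NM2, BasePairSpecies, LatticeParams, ModelParams

__all__ = [
    "LatticeConfiguration",
    "morse_energy",
    "stacking_energy",
    "backbone_energy",
    "potential_energy",
    "kinetic_energy",
    "total_energy",
    "potential_gradient",
    "hessian_matrix",
    "hessian_frequencies",
]


@dataclass
class LatticeConfiguration:
    """Twist/radial displacement fields over N sites.

    phi are twist deviations from the uniform equilibrium winding, so the
    relative angle across bond (n, n+1) is theta0 + phi_{n+1} - phi_n.
    lambdas holds the per-site mass ratio lambda_n = m_n / m_bar_n.
    """

    phi: np.ndarray
    rho: np.ndarray
    lambdas: np.ndarray
    boundary: str = "periodic"

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if not (self.phi.shape == self.rho.shape == self.lambdas.shape):
            raise ValueError("phi, rho and lambdas must have equal length")
        if self.boundary not in ("periodic", "free"):
            raise ValueError("boundary must be 'periodic' or 'free'")
        if not (np.all(np.isfinite(self.phi)) and np.all(np.isfinite(self.rho))):
            raise ValueError("non-finite configuration entries")

    @classmethod
    def from_species(
        cls, phi, rho, species: list[str], boundary: str = "periodic"
    ) -> "LatticeConfiguration":
        lams = np.array([BasePairSpecies.from_name(s).lambda_ for s in species])
        return cls(np.asarray(phi, float), np.asarray(rho, float), lams, boundary)

    @property
    def n_sites(self) -> int:
        return self.phi.size

    def _bond_indices(self) -> tuple[np.ndarray, np.ndarray]:
        n = self.n_sites
        if self.boundary == "periodic":
            left = np.arange(n)
            right = (left + 1) % n
        else:
            left = np.arange(n - 1)
            right = left + 1
        return left, right


def morse_energy(config: LatticeConfiguration, lattice: LatticeParams) -> float:
    """Hydrogen-bond stretching U_H = sum_n D (exp(-(alpha/2)(1+lambda_n) rho_n) - 1)^2.

    (1+lambda_n) rho_n is the total pair opening rho_n + rho_bar_n.  Each
    fully dissociated site contributes the Morse depth D.
    """
    arg = -(lattice.alpha / 2.0) * (1.0 + config.lambdas) * config.rho
    return float(lattice.D * np.sum((np.exp(arg) - 1.0) ** 2))


def stacking_energy(config: LatticeConfiguration, lattice: LatticeParams) -> float:
    """Stacking U_S = (1/8) sum k_S [1 + exp(-(b/2) u+)] (u-)^2.

    u+- = (1+lambda_n) rho_n +- (1+lambda_{n+1}) rho_{n+1}; the term
    penalizes relative radial displacements of neighbouring pairs and
    vanishes identically for any uniform radial field.
    """
    if config.n_sites < 2:
        raise ValueError("stacking requires N >= 2")
    left, right = config._bond_indices()
    w = (1.0 + config.lambdas) * config.rho
    u_plus = w[left] + w[right]
    u_minus = w[left] - w[right]
    mod = 1.0 + np.exp(-(lattice.b / 2.0) * u_plus)
    return float(lattice.kS / 8.0 * np.sum(mod * u_minus**2))


def backbone_energy(
    config: LatticeConfiguration, lattice: LatticeParams, frame: HelixFrame
) -> float:
    """Backbone U_B = (kB/2) sum [(d - l0)^2 + (d_bar - l0)^2].

    Both strands contribute; the complementary strand uses rho -> lambda rho.
    Depends only on relative twist angles, hence invariant under a rigid
    rotation of the whole chain.
    """
    if config.n_sites < 2:
        raise ValueError("backbone requires N >= 2")
    left, right = config._bond_indices()
    theta = frame.theta0 + config.phi[right] - config.phi[left]
    d = pair_distance(config.rho[left], config.rho[right], theta, frame)
    rho_bar = config.lambdas * config.rho
    d_bar = pair_distance(rho_bar[left], rho_bar[right], theta, frame)
    return float(
        lattice.kB / 2.0 * np.sum((d - frame.l0) ** 2 + (d_bar - frame.l0) ** 2)
    )


def potential_energy(
    config: LatticeConfiguration, lattice: LatticeParams, frame: HelixFrame
) -> float:
    """U_H + U_S + U_B (eV); zero exactly at the B-form equilibrium."""
    return (
        morse_energy(config, lattice)
        + stacking_energy(config, lattice)
        + backbone_energy(config, lattice, frame)
    )


def kinetic_energy(
    config: LatticeConfiguration,
    p_phi: np.ndarray,
    p_rho: np.ndarray,
    lattice: LatticeParams,
    frame: HelixFrame,
) -> float:
    """Kinetic term (1/2M) sum [P_rho^2/lambda + P_phi^2/(xi^2 + P(rho))].

    The twist inertia metric uses the small-displacement expansion
    P(rho) = lambda rho^2 + 2 R0 rho; at equilibrium it reduces to xi^2.
    """
    p_phi = np.asarray(p_phi, float)
    p_rho = np.asarray(p_rho, float)
    metric = frame.xi**2 + config.lambdas * config.rho**2 + 2.0 * frame.R0 * config.rho
    return float(
        np.sum(p_rho**2 / config.lambdas + p_phi**2 / metric) / (2.0 * lattice.M)
    )


def total_energy(
    config: LatticeConfiguration,
    p_phi: np.ndarray,
    p_rho: np.ndarray,
    lattice: LatticeParams,
    frame: HelixFrame,
) -> float:
    """Full lattice Hamiltonian H_l = T + U_H + U_S + U_B (eV)."""
    return kinetic_energy(config, p_phi, p_rho, lattice, frame) + potential_energy(
        config, lattice, frame
    )


def _pack(config: LatticeConfiguration) -> np.ndarray:
    return np.concatenate([config.phi, config.rho])


def _unpack(z: np.ndarray, template: LatticeConfiguration) -> LatticeConfiguration:
    n = template.n_sites
    return LatticeConfiguration(
        z[:n].copy(), z[n:].copy(), template.lambdas, template.boundary
    )


def potential_gradient(
    config: LatticeConfiguration,
    lattice: LatticeParams,
    frame: HelixFrame,
    step: float = 1e-6,
) -> np.ndarray:
    """Central-difference gradient of the total potential, shape (2N,).

    Layout: first N entries d/dphi (eV/rad), last N d/drho (eV/nm).
    """
    z0 = _pack(config)
    grad = np.empty_like(z0)
    for i in range(z0.size):
        zp, zm = z0.copy(), z0.copy()
        zp[i] += step
        zm[i] -= step
        grad[i] = (
            potential_energy(_unpack(zp, config), lattice, frame)
            - potential_energy(_unpack(zm, config), lattice, frame)
        ) / (2.0 * step)
    return grad


def hessian_matrix(
    config: LatticeConfiguration,
    lattice: LatticeParams,
    frame: HelixFrame,
    step: float = 1e-5,
) -> np.ndarray:
    """Symmetrized finite-difference Hessian of U at ``config``, shape (2N, 2N)."""
    z0 = _pack(config)
    m = z0.size

    def U(z: np.ndarray) -> float:
        return potential_energy(_unpack(z, config), lattice, frame)

    u0 = U(z0)
    h = np.empty((m, m))
    for i in range(m):
        zp, zm = z0.copy(), z0.copy()
        zp[i] += step
        zm[i] -= step
        h[i, i] = (U(zp) - 2.0 * u0 + U(zm)) / step**2
        for j in range(i + 1, m):
            zpp, zpm, zmp, zmm = z0.copy(), z0.copy(), z0.copy(), z0.copy()
            zpp[[i, j]] += step
            zmm[[i, j]] -= step
            zpm[i] += step
            zpm[j] -= step
            zmp[i] -= step
            zmp[j] += step
            h[i, j] = h[j, i] = (U(zpp) - U(zpm) - U(zmp) + U(zmm)) / (
                4.0 * step**2
            )
    return h


def hessian_frequencies(
    params: ModelParams,
    frame: HelixFrame,
    n_sites: int,
    q_list: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normal-mode frequencies of the full potentials on a homopolymer ring.

    Builds the mass-weighted finite-difference Hessian at equilibrium
    (twist inertia M xi^2, radial inertia M lambda), Bloch-transforms the
    site-0 coupling blocks, and returns, per commensurate wavevector, the
    two branch frequencies in rad/s.

    Returns (q, omega_lower, omega_upper).  q values must satisfy
    q xi = 2 pi k / N for integer k; non-commensurate requests are
    rejected.  Tiny negative eigenvalues from FD noise on the q=0 twist
    zero mode are clipped at zero.
    """
    lam = params.pair.lambda_
    config = LatticeConfiguration(
        np.zeros(n_sites), np.zeros(n_sites), np.full(n_sites, lam), "periodic"
    )
    H = hessian_matrix(config, params.lattice, frame)

    masses = np.concatenate(
        [
            np.full(n_sites, params.lattice.M * frame.xi**2),
            np.full(n_sites, params.lattice.M * lam),
        ]
    )
    W = H / np.sqrt(np.outer(masses, masses)) * ACCEL_EV_AMU_NM2  # s^-2

    if q_list is None:
        ks = np.arange(n_sites // 2 + 1)
        q_list = 2.0 * np.pi * ks / (n_sites * frame.xi)
    else:
        q_list = np.asarray(q_list, dtype=float)
        ks = q_list * n_sites * frame.xi / (2.0 * np.pi)
        if not np.allclose(ks, np.round(ks), atol=1e-8):
            raise ValueError("q not commensurate with the N-site ring")
        ks = np.round(ks).astype(int)

    # signed site offsets for the Bloch phase (minimum image on the ring)
    offsets = np.arange(n_sites)
    offsets = np.where(offsets > n_sites // 2, offsets - n_sites, offsets)

    lower = np.empty(len(q_list))
    upper = np.empty(len(q_list))
    for idx, q in enumerate(np.atleast_1d(q_list)):
        phase = np.exp(-1j * q * frame.xi * offsets)
        block = np.zeros((2, 2), dtype=complex)
        for a in range(2):
            for b in range(2):
                row = W[a * n_sites, b * n_sites : (b + 1) * n_sites]
                block[a, b] = np.sum(row * phase)
        evals = np.linalg.eigvalsh((block + block.conj().T) / 2.0)
        evals = np.clip(evals, 0.0, None)
        lower[idx], upper[idx] = np.sqrt(evals)
    return np.atleast_1d(q_list), lower, upper
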