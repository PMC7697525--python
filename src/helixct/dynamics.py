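"""Time-domain integration of the linearized twist/radial equations.

The simulator integrates the *linearized* coupled equations of motion
(the object of the analytic dispersion theory) with fixed-step RK4, for
homopolymers and arbitrary GC/AT sequences.  Site-dependent coupled
frequencies handle heteropolymers; for a homopolymer the equations
reduce to

  phi_dd_n + w_phi^2 (2 phi_n - phi_{n-1} - phi_{n+1})
      = A_lambda w_phi^2 (rho_{n+1} - rho_{n-1})
  rho_dd_n + w_phirho^2 rho_n
      - (1/2) w_phiS^2 (rho_{n-1} + rho_{n+1})
      = B_lambda w_phi^2 (phi_{n-1} - phi_{n+1})

whose plane-wave solutions are the two phonon branches.  The codon
collective variables x_n = 2 phi_n - phi_{n-1} - phi_{n+1} (and likewise
y_n for rho) satisfy the very same equations -- a self-similar
renormalization property that holds recursively for nested triplets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import HelixFrame, derive_frame
from .params import ACCEL_EV_AMU_NM2, BasePairSpecies, ModelParams, default_params
from .phonons import (
    CharacteristicFrequencies,
    characteristic_frequencies,
    coupling_constants,
    dispersion_exact,
)

__all__ = [
    "ChainState",
    "Trajectory",
    "SiteCoefficients",
    "site_coefficients",
    "linear_rhs",
    "integrate",
    "init_helical_wave",
    "codon_fields",
    "codon_residual",
    "make_sequence",
    "mode_amplitude",
    "mode_spectrum",
]


@dataclass
class ChainState:
    """Twist/radial displacement and velocity fields at one instant."""

    phi: np.ndarray  # rad
    rho: np.ndarray  # nm
    phi_dot: np.ndarray  # rad/s
    rho_dot: np.ndarray  # nm/s
    time: float = 0.0  # s
    boundary: str = "periodic"

    def __post_init__(self) -> None:
        arrays = [self.phi, self.rho, self.phi_dot, self.rho_dot]
        shapes = {np.asarray(a).shape for a in arrays}
        if len(shapes) != 1:
            raise ValueError("all state fields must have equal length")
        for a in arrays:
            if not np.all(np.isfinite(a)):
                raise ValueError("non-finite state entries")
        if self.boundary not in ("periodic", "free"):
            raise ValueError("boundary must be 'periodic' or 'free'")

    @property
    def n_sites(self) -> int:
        return np.asarray(self.phi).size


@dataclass
class Trajectory:
    """Recorded fields over time: times (s), phi/rho of shape (T, N)."""

    times: np.ndarray
    phi: np.ndarray
    rho: np.ndarray
    boundary: str
    dt: float
    stride: int


@dataclass
class SiteCoefficients:
    """Precomputed per-site coefficients of the linearized equations.

    w_phi2 is site independent (same backbone and pair mass everywhere);
    w_phirho2[n] and the bond-resolved w_phiS2_minus/plus[n] (coupling of
    site n to n-1 / n+1) carry the lambda_n, lambda_{n+-1} dependence for
    heteropolymers.  phi_coupling[n] = (aB/2)(1 + 1/lambda_n) w_phi^2,
    rho_coupling[n] = w_phi^2 (1 + lambda_n)/lB.
    """

    w_phi2: float
    w_phirho2: np.ndarray
    w_phiS2_minus: np.ndarray
    w_phiS2_plus: np.ndarray
    rho_coupling: np.ndarray
    phi_coupling: np.ndarray
    lambdas: np.ndarray
    boundary: str


def site_coefficients(
    species: list[str],
    params: ModelParams | None = None,
    frame: HelixFrame | None = None,
    boundary: str = "periodic",
) -> SiteCoefficients:
    """Build the coefficient arrays for a per-site species list.

    The same effective Morse potential and pair mass M are used for both
    pair types (only lambda distinguishes them), matching the default
    parameter registry.
    """
    if params is None:
        params = default_params("GC")
    if frame is None:
        frame = derive_frame(params.geometry)
    lat = params.lattice
    lam = np.array([BasePairSpecies.from_name(s).lambda_ for s in species])
    n = lam.size
    if n < 3:
        raise ValueError("need at least 3 sites")

    w_phi2 = (
        (2.0 * lat.kB / lat.M)
        * (frame.f0 / (frame.xi * frame.l0)) ** 2
        * ACCEL_EV_AMU_NM2
    )
    w_H2 = lat.D * lat.alpha**2 / (2.0 * lat.M) * ACCEL_EV_AMU_NM2
    w_S2 = lat.kS / lat.M * ACCEL_EV_AMU_NM2

    w_phirho2 = (1.0 + lam) ** 2 / lam * (w_H2 + w_S2) + (
        1.0 + lam**2
    ) / lam * frame.bB**2 * w_phi2

    lam_m = np.roll(lam, 1)  # lambda_{n-1}
    lam_p = np.roll(lam, -1)  # lambda_{n+1}

    def w_phiS2(lam_n, lam_nb):
        return (1.0 + lam_n) * (1.0 + lam_nb) / lam_n * w_S2 - (
            1.0 + lam_n * lam_nb
        ) / lam_n * frame.bB**2 * w_phi2

    return SiteCoefficients(
        w_phi2=w_phi2,
        w_phirho2=w_phirho2,
        w_phiS2_minus=w_phiS2(lam, lam_m),
        w_phiS2_plus=w_phiS2(lam, lam_p),
        rho_coupling=w_phi2 * (1.0 + lam) / frame.lB,
        phi_coupling=frame.aB / 2.0 * (1.0 + 1.0 / lam) * w_phi2,
        lambdas=lam,
        boundary=boundary,
    )


def linear_rhs(
    phi: np.ndarray, rho: np.ndarray, coeffs: SiteCoefficients
) -> tuple[np.ndarray, np.ndarray]:
    """Accelerations (phi_dd in rad/s^2, rho_dd in nm/s^2).

    For free boundaries the couplings across the missing wrap-around bond
    are dropped (one-sided ends, qualitative use only).
    """
    phi_m, phi_p = np.roll(phi, 1), np.roll(phi, -1)
    rho_m, rho_p = np.roll(rho, 1), np.roll(rho, -1)
    w_m = (1.0 + np.roll(coeffs.lambdas, 1)) * rho_m
    w_p = (1.0 + np.roll(coeffs.lambdas, -1)) * rho_p

    if coeffs.boundary == "free":
        # zero every term that reaches through the wrap-around bond
        phi_m = phi_m.copy()
        phi_p = phi_p.copy()
        rho_m = rho_m.copy()
        rho_p = rho_p.copy()
        w_m = w_m.copy()
        w_p = w_p.copy()
        phi_m[0] = phi[0]
        phi_p[-1] = phi[-1]
        rho_m[0] = 0.0
        rho_p[-1] = 0.0
        w_m[0] = 0.0
        w_p[-1] = 0.0

    lam = coeffs.lambdas
    # twist equation: restoring second difference + radial drive through lB;
    # rho_coupling[n]/( (1+lambda_n) w_phi^2 ) == 1/lB for every site
    lB_inv = coeffs.rho_coupling[0] / (coeffs.w_phi2 * (1.0 + lam[0]))
    phi_dd = -coeffs.w_phi2 * (2.0 * phi - phi_m - phi_p) + coeffs.w_phi2 * lB_inv * (
        w_p - w_m
    )

    w_phiS2_m = coeffs.w_phiS2_minus
    w_phiS2_p = coeffs.w_phiS2_plus
    if coeffs.boundary == "free":
        w_phiS2_m = w_phiS2_m.copy()
        w_phiS2_p = w_phiS2_p.copy()
        w_phiS2_m[0] = 0.0
        w_phiS2_p[-1] = 0.0
    rho_dd = (
        -coeffs.w_phirho2 * rho
        + 0.5 * w_phiS2_m * rho_m
        + 0.5 * w_phiS2_p * rho_p
        + coeffs.phi_coupling * (phi_m - phi_p)
    )
    return phi_dd, rho_dd


def integrate(
    state: ChainState,
    coeffs: SiteCoefficients,
    dt: float,
    steps: int,
    stride: int = 1,
) -> Trajectory:
    """Fixed-step RK4 integration of the first-order system.

    dt in seconds (default recommendation 1 fs, ~1/450 of the fastest
    period); records every ``stride`` steps including the initial state.
    Aborts with RuntimeError if the state norm grows by more than 1e3
    (instability diagnostic -- cannot happen for a stable dt).
    """
    if coeffs.boundary != state.boundary:
        raise ValueError("state and coefficients disagree on boundary")
    phi = state.phi.astype(float).copy()
    rho = state.rho.astype(float).copy()
    vphi = state.phi_dot.astype(float).copy()
    vrho = state.rho_dot.astype(float).copy()

    n_rec = steps // stride + 1
    times = np.empty(n_rec)
    phis = np.empty((n_rec, phi.size))
    rhos = np.empty((n_rec, rho.size))
    times[0] = state.time
    phis[0] = phi
    rhos[0] = rho

    norm0 = max(
        np.max(np.abs(phi)) + np.max(np.abs(vphi)) * dt,
        np.max(np.abs(rho)) + np.max(np.abs(vrho)) * dt,
        1e-300,
    )
    rec = 1
    for step in range(1, steps + 1):
        k1p, k1r = vphi, vrho
        a1p, a1r = linear_rhs(phi, rho, coeffs)
        k2p = vphi + 0.5 * dt * a1p
        k2r = vrho + 0.5 * dt * a1r
        a2p, a2r = linear_rhs(phi + 0.5 * dt * k1p, rho + 0.5 * dt * k1r, coeffs)
        k3p = vphi + 0.5 * dt * a2p
        k3r = vrho + 0.5 * dt * a2r
        a3p, a3r = linear_rhs(phi + 0.5 * dt * k2p, rho + 0.5 * dt * k2r, coeffs)
        k4p = vphi + dt * a3p
        k4r = vrho + dt * a3r
        a4p, a4r = linear_rhs(phi + dt * k3p, rho + dt * k3r, coeffs)

        phi = phi + dt / 6.0 * (k1p + 2.0 * k2p + 2.0 * k3p + k4p)
        rho = rho + dt / 6.0 * (k1r + 2.0 * k2r + 2.0 * k3r + k4r)
        vphi = vphi + dt / 6.0 * (a1p + 2.0 * a2p + 2.0 * a3p + a4p)
        vrho = vrho + dt / 6.0 * (a1r + 2.0 * a2r + 2.0 * a3r + a4r)

        if step % stride == 0:
            times[rec] = state.time + step * dt
            phis[rec] = phi
            rhos[rec] = rho
            rec += 1
        if step % 1000 == 0 or step == steps:
            norm = max(np.max(np.abs(phi)), np.max(np.abs(rho)))
            if not np.isfinite(norm) or norm > 1e3 * norm0:
                raise RuntimeError(
                    f"integration unstable at step {step}: norm grew by "
                    f"{norm / norm0:.1e}; reduce dt"
                )
    return Trajectory(
        times=times[:rec],
        phi=phis[:rec],
        rho=rhos[:rec],
        boundary=state.boundary,
        dt=dt,
        stride=stride,
    )


def _check_commensurate(q: float, n_sites: int, xi: float) -> None:
    k = q * n_sites * xi / (2.0 * math.pi)
    if abs(k - round(k)) > 1e-8:
        raise ValueError(
            f"q={q} not commensurate with an N={n_sites} ring (q xi N/2pi = {k:.4f})"
        )


def init_helical_wave(
    q: float,
    branch: str,
    phi0: float,
    n_sites: int,
    params: ModelParams,
    frame: HelixFrame | None = None,
    cf: CharacteristicFrequencies | None = None,
) -> tuple[ChainState, float]:
    """Real plane-wave eigenstate of the secular problem at (q, branch).

    Realizes the real part of phi_n = phi0 e^{i(w t - n q xi)} with the
    radial amplitude/phase fixed by the eigenvector ratio
    rho0/phi0 = (w^2 - G)/(2 i A w_phi^2 sin q xi); phases are chosen so
    phi is cosine-like at t=0, site 0.  Returns (state, omega).
    """
    if branch not in ("acoustic", "optical"):
        raise ValueError("branch must be 'acoustic' or 'optical'")
    if frame is None:
        frame = derive_frame(params.geometry)
    if cf is None:
        cf = characteristic_frequencies(params, frame)
    _check_commensurate(q, n_sites, frame.xi)

    curve = dispersion_exact(np.array([q]), cf, frame, params.pair)
    omega = float(curve.omega_minus[0] if branch == "acoustic" else curve.omega_plus[0])
    a_l, _, _ = coupling_constants(params.pair, frame)
    s = math.sin(q * frame.xi)
    g = 4.0 * cf.omega_phi**2 * math.sin(q * frame.xi / 2.0) ** 2
    h = cf.omega_phirho**2 - cf.omega_phiS**2 * math.cos(q * frame.xi)

    n = np.arange(n_sites)
    if abs(s) < 1e-12:
        # off-diagonal coupling vanishes: pure twist or pure radial mode
        pure_twist = abs(omega**2 - g) <= abs(omega**2 - h)
        if pure_twist:
            phi = phi0 * np.cos(-n * q * frame.xi)
            rho = np.zeros(n_sites)
            vphi = omega * phi0 * np.sin(n * q * frame.xi)
            vrho = np.zeros(n_sites)
        else:
            rho0 = params.electronic.rho0
            phi = np.zeros(n_sites)
            rho = rho0 * np.cos(-n * q * frame.xi)
            vphi = np.zeros(n_sites)
            vrho = omega * rho0 * np.sin(n * q * frame.xi)
    else:
        # eigenvector ratio rho0 = i * r * phi0 with r = (G - w^2)/(2 A w_phi^2 sin q xi)
        ratio = (g - omega**2) / (2.0 * a_l * cf.omega_phi**2 * s)
        if branch == "acoustic":
            phi_amp = phi0  # twist-dominated: set the twist amplitude
        else:
            # radial-dominated (|r| >> 1): set the radial amplitude instead
            phi_amp = params.electronic.rho0 / abs(ratio)
        phi = phi_amp * np.cos(-n * q * frame.xi)
        rho = ratio * phi_amp * np.sin(n * q * frame.xi)
        vphi = omega * phi_amp * np.sin(n * q * frame.xi)
        vrho = -ratio * omega * phi_amp * np.cos(n * q * frame.xi)
    state = ChainState(phi=phi, rho=rho, phi_dot=vphi, rho_dot=vrho, time=0.0)
    return state, omega


def codon_fields(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Codon collective variables x = 2 phi - phi_- - phi_+, y likewise."""
    x = 2.0 * traj.phi - np.roll(traj.phi, 1, axis=1) - np.roll(traj.phi, -1, axis=1)
    y = 2.0 * traj.rho - np.roll(traj.rho, 1, axis=1) - np.roll(traj.rho, -1, axis=1)
    return x, y


def codon_residual(
    traj: Trajectory, coeffs: SiteCoefficients, nested: int = 1
) -> float:
    """Max relative residual of the codon equations over a trajectory.

    Second time derivatives are taken by central differences at the
    recording interval; the residual of both collective equations is
    normalized by the largest acceleration scale present.  ``nested``
    applies the triplet reduction recursively (nested codons).  Requires
    a homopolymer trajectory recorded with stride 1 on a periodic ring.
    """
    if traj.phi.shape[0] < 3:
        raise ValueError("trajectory too short for time differentiation")
    if traj.boundary != "periodic":
        raise ValueError("codon residual is defined on a periodic homopolymer ring")
    if np.ptp(coeffs.lambdas) != 0:
        raise ValueError("codon renormalization requires a homopolymer")
    x, y = traj.phi, traj.rho
    for _ in range(nested):
        x = 2.0 * x - np.roll(x, 1, axis=1) - np.roll(x, -1, axis=1)
        y = 2.0 * y - np.roll(y, 1, axis=1) - np.roll(y, -1, axis=1)
    dt_rec = traj.dt * traj.stride

    x_dd = (x[2:] - 2.0 * x[1:-1] + x[:-2]) / dt_rec**2
    y_dd = (y[2:] - 2.0 * y[1:-1] + y[:-2]) / dt_rec**2
    xm = np.roll(x[1:-1], 1, axis=1)
    xp = np.roll(x[1:-1], -1, axis=1)
    ym = np.roll(y[1:-1], 1, axis=1)
    yp = np.roll(y[1:-1], -1, axis=1)

    # rho_coupling = A_lambda w_phi^2 drives the codon twist equation too
    res_x = x_dd + coeffs.w_phi2 * (2.0 * x[1:-1] - xm - xp) - coeffs.rho_coupling[
        0
    ] * (yp - ym)
    res_y = (
        y_dd
        + coeffs.w_phirho2[0] * y[1:-1]
        - 0.5 * coeffs.w_phiS2_minus[0] * ym
        - 0.5 * coeffs.w_phiS2_plus[0] * yp
        - coeffs.phi_coupling[0] * (xm - xp)
    )
    scale_x = np.max(np.abs(x_dd)) + 1e-300
    scale_y = np.max(np.abs(y_dd)) + 1e-300
    return float(max(np.max(np.abs(res_x)) / scale_x, np.max(np.abs(res_y)) / scale_y))


def make_sequence(
    kind: str,
    length: int | None = None,
    seed: int | None = None,
    p_gc: float = 0.5,
    species: str = "GC",
    fasta: str | None = None,
) -> list[str]:
    """Generate a per-site pair-species list ('GC'/'AT').

    kind='homopolymer': ``length`` copies of ``species``.
    kind='random': Bernoulli(p_gc) GC/AT draw, deterministic given seed.
    kind='fasta': map a sequence string or FASTA file (first record) to
    pair species per position (A/T -> AT, G/C -> GC, case-insensitive);
    ambiguity codes are rejected.
    """
    if kind == "homopolymer":
        if length is None:
            raise ValueError("length required for homopolymer")
        BasePairSpecies.from_name(species)
        return [species] * length
    if kind == "random":
        if length is None:
            raise ValueError("length required for random sequence")
        rng = np.random.default_rng(seed)
        return ["GC" if u < p_gc else "AT" for u in rng.random(length)]
    if kind == "fasta":
        if fasta is None:
            raise ValueError("fasta string or path required")
        import os

        if os.path.exists(fasta):
            from Bio import SeqIO

            record = next(SeqIO.parse(fasta, "fasta"))
            letters = str(record.seq)
        else:
            letters = fasta
        mapping = {"A": "AT", "T": "AT", "G": "GC", "C": "GC"}
        out = []
        for ch in letters.strip().upper():
            if ch not in mapping:
                raise ValueError(
                    f"invalid base {ch!r}: only A/C/G/T are defined in this model"
                )
            out.append(mapping[ch])
        return out
    raise ValueError("kind must be 'homopolymer', 'random' or 'fasta'")


def mode_amplitude(traj: Trajectory, k: int) -> np.ndarray:
    """Complex spatial-Fourier amplitude phi_hat_k(t) of the twist field."""
    return np.fft.fft(traj.phi, axis=1)[:, k] / traj.phi.shape[1]


def mode_spectrum(traj: Trajectory, k: int) -> dict:
    """Peak temporal frequencies (THz) of spatial mode k.

    Hann-windowed FFT of the complex mode amplitudes; the twist field
    projects mainly onto the acoustic branch and the radial field onto
    the optical branch, so the two peaks estimate nu_-(q_k) and
    nu_+(q_k).  Also returns the frequency resolution (bin width).
    """
    n_t = traj.times.size
    window = np.hanning(n_t)
    dt_rec = traj.dt * traj.stride
    freqs = np.fft.fftfreq(n_t, d=dt_rec) / 1e12  # THz

    def peak(signal: np.ndarray) -> float:
        spec = np.abs(np.fft.fft(window * signal))
        spec[0] = 0.0  # ignore DC
        return abs(float(freqs[int(np.argmax(spec))]))

    phi_k = np.fft.fft(traj.phi, axis=1)[:, k]
    rho_k = np.fft.fft(traj.rho, axis=1)[:, k]
    return {
        "nu_acoustic_thz": peak(phi_k),
        "nu_optical_thz": peak(rho_k),
        "resolution_thz": 1.0 / (n_t * dt_rec) / 1e12,
    }
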