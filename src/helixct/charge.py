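"""Twist/radial-dependent pi-pi transfer integrals and renormalized sites.

The hopping between stacked base pairs falls off with the chord distance
between their attachment points on the helix cylinder,

    t(rho_n, rho_m, theta) = t0 [1 - (eta_bar/l0^2) chord^2],

which reduces to the optimal face-to-face value t0 at theta = 0, rho = 0.
For a synchronized helical phonon of wavevector q the hopping becomes
site independent, t(q) = t0 [1 - 4 chi A0^2 sin^2(q xi / 2)], with
electron-phonon coupling chi = eta_bar (R0/l0)^2 and amplitude factor
A0^2 = phi0^2 + (rho0/R0)^2.

The sugar-phosphate backbone is decimated exactly, yielding the
energy-dependent on-site renormalization eps_XY(E) of the effective 1D
chain Hamiltonian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import HelixFrame, derive_frame
from .params import HBAR2_OVER_ME_EV_NM2, ModelParams

__all__ = [
    "TransferIntegralModel",
    "slater_koster_v",
    "transfer_integral",
    "transfer_integral_phonon",
    "backbone_tau",
    "onsite_epsilon",
    "onsite_renormalized",
    "onsite_epsilon_from_taus",
    "build_effective_chain",
    "chain_hamiltonian",
]


@dataclass(frozen=True)
class TransferIntegralModel:
    """Geometry-aware pi-pi hopping model for one homopolymer species.

    chi = eta_bar (R0/l0)^2 is constructed from the hybridization ratio
    and the equilibrium frame, never stored independently.
    """

    t0: float  # optimal face-to-face integral, eV
    eta_bar: float
    frame: HelixFrame

    def __post_init__(self) -> None:
        if self.t0 <= 0:
            raise ValueError("t0 must be positive")

    @property
    def chi(self) -> float:
        """Electron-phonon coupling strength eta_bar (R0/l0)^2."""
        return self.eta_bar * (self.frame.R0 / self.frame.l0) ** 2

    @classmethod
    def from_params(
        cls, params: ModelParams, frame: HelixFrame | None = None
    ) -> "TransferIntegralModel":
        if frame is None:
            frame = derive_frame(params.geometry)
        return cls(t0=params.electronic.t0, eta_bar=params.electronic.eta_bar, frame=frame)


def slater_koster_v(eta: float, d: float, Rc: float) -> float:
    """Two-center hybridization element V = eta (hbar^2/(m_e d^2)) e^{-d/Rc}.

    d and Rc in nm; result in eV.  The sign of eta carries through (ppPi
    elements are negative).
    """
    if d <= 0 or Rc <= 0:
        raise ValueError("d and Rc must be positive")
    return eta * HBAR2_OVER_ME_EV_NM2 / d**2 * math.exp(-d / Rc)


def transfer_integral(
    rho_n, rho_m, theta, model: TransferIntegralModel, form: str = "full"
):
    """pi-pi hopping t(rho_n, rho_m, theta) in eV, vectorized.

    form='full':        t0 [1 - (eta_bar/l0^2) chord^2] with the exact
                        chord distance on the helix cylinder.
    form='equilibrium': the B-form value t(0, theta0)
                        = t0 [1 - eta_bar (2 R0/l0)^2 sin^2(theta0/2)]
                        (arguments ignored).
    form='small_twist': t0 [1 - chi theta^2] (radial variables frozen).
    form='radial_twist': t0 [1 - chi ((v_n - v_m)^2 + (1+v_n)(1+v_m) theta^2)],
                        v = rho/R0.
    form='linearized':  t0 [1 - chi ((v_n - v_m)^2 + theta^2)].

    The full form satisfies t <= t0 with equality only face-to-face, is
    even in theta and symmetric under site exchange.
    """
    f = model.frame
    theta = np.asarray(theta, dtype=float)
    if form == "equilibrium":
        val = model.t0 * (
            1.0
            - model.eta_bar
            * (2.0 * f.R0 / f.l0) ** 2
            * math.sin(f.theta0 / 2.0) ** 2
        )
        return float(val)
    rho_n = np.asarray(rho_n, dtype=float)
    rho_m = np.asarray(rho_m, dtype=float)
    if form == "full":
        rn = f.R0 + rho_n
        rm = f.R0 + rho_m
        chord2 = rn**2 + rm**2 - 2.0 * rn * rm * np.cos(theta)
        out = model.t0 * (1.0 - model.eta_bar / f.l0**2 * chord2)
    elif form == "small_twist":
        out = model.t0 * (1.0 - model.chi * theta**2)
    elif form == "radial_twist":
        vn = rho_n / f.R0
        vm = rho_m / f.R0
        out = model.t0 * (
            1.0 - model.chi * ((vn - vm) ** 2 + (1.0 + vn) * (1.0 + vm) * theta**2)
        )
    elif form == "linearized":
        vn = rho_n / f.R0
        vm = rho_m / f.R0
        out = model.t0 * (1.0 - model.chi * ((vn - vm) ** 2 + theta**2))
    else:
        raise ValueError(f"unknown form {form!r}")
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def transfer_integral_phonon(q, model: TransferIntegralModel, A0sq: float):
    """Phonon-modulated hopping t(q) = t0 [1 - 4 chi A0^2 sin^2(q xi/2)].

    Site independent: a synchronized helical wave modulates every bond
    identically.  Raises if the modulation drives t(q) <= 0 anywhere
    (cannot happen for the defaults, where 4 chi A0^2 ~= 0.27 < 1).
    """
    q = np.asarray(q, dtype=float)
    t = model.t0 * (
        1.0 - 4.0 * model.chi * A0sq * np.sin(q * model.frame.xi / 2.0) ** 2
    )
    if np.any(t <= 0):
        raise ValueError("phonon modulation closed the hopping channel (t(q) <= 0)")
    t = np.asarray(t)
    return float(t) if t.ndim == 0 else t


def backbone_tau(eps_j: float, E, tP: float, gamma_j: float):
    """Effective base <-> backbone hopping tau_j = tP + (eps_j/tP)(E - gamma_j)."""
    E = np.asarray(E, dtype=float)
    out = np.asarray(tP + eps_j / tP * (E - gamma_j))
    return float(out) if out.ndim == 0 else out


def onsite_epsilon(E, a_xy: float, b_xy: float, tP: float, gamma: float):
    """Backbone-decimated on-site term, closed polynomial form.

    eps_XY(E) = 2 [tP^2 + a_XY (E-gamma) + b_XY (E-gamma)^2] / (E-gamma)
    with a_XY = eps_X + eps_Y and b_XY = (eps_X^2 + eps_Y^2)/(2 tP^2);
    assumes a uniform backbone on-site energy gamma.  E = gamma is a pole
    and is rejected.
    """
    E = np.asarray(E, dtype=float)
    x = E - gamma
    if np.any(x == 0):
        raise ValueError("E = gamma is a pole of the renormalized on-site energy")
    out = np.asarray(2.0 * (tP**2 + a_xy * x + b_xy * x**2) / x)
    return float(out) if out.ndim == 0 else out


def onsite_epsilon_from_taus(
    E, eps_x: float, eps_y: float, tP: float, gamma: float
):
    """Decimation sum eps_XY(E) = tau_X^2/(E-gamma) + tau_Y^2/(E-gamma).

    Algebraically identical to :func:`onsite_epsilon` with
    a_XY = eps_X + eps_Y, b_XY = (eps_X^2 + eps_Y^2)/(2 tP^2) for a
    uniform gamma; kept as an independent route for verification.
    """
    E = np.asarray(E, dtype=float)
    x = E - gamma
    if np.any(x == 0):
        raise ValueError("E = gamma is a pole of the renormalized on-site energy")
    tau_x = backbone_tau(eps_x, E, tP, gamma)
    tau_y = backbone_tau(eps_y, E, tP, gamma)
    out = np.asarray((tau_x**2 + tau_y**2) / x)
    return float(out) if out.ndim == 0 else out


def onsite_renormalized(
    E: float, t_pair: float, a_xy: float, b_xy: float, tP: float, gamma: float
) -> float:
    """Full renormalized on-site energy eps~ = t_pair + eps_XY(E)."""
    return t_pair + onsite_epsilon(E, a_xy, b_xy, tP, gamma)


def build_effective_chain(
    n_sites: int,
    E: float,
    q: float,
    params: ModelParams,
    frame: HelixFrame | None = None,
    gamma: float | None = None,
) -> tuple[np.ndarray, float]:
    """Tridiagonal coefficients of the effective 1D chain at energy E.

    Returns (diagonal, hopping): diagonal[n] = t(q) + eps_XY(E) (uniform
    for a homopolymer with a synchronized phonon), off-diagonal = -t(q).
    Hermiticity is automatic (a single real hopping on both sides).
    """
    if frame is None:
        frame = derive_frame(params.geometry)
    e = params.electronic
    if gamma is None:
        gamma = e.gamma
    model = TransferIntegralModel.from_params(params, frame)
    t_q = transfer_integral_phonon(q, model, e.amplitude_sq(frame.R0))
    eps = onsite_epsilon(E, e.a_xy, e.b_xy, e.tP, gamma)
    return np.full(n_sites, t_q + eps), -t_q


def chain_hamiltonian(
    n_sites: int,
    E: float,
    q: float,
    params: ModelParams,
    frame: HelixFrame | None = None,
    gamma: float | None = None,
    periodic: bool = True,
) -> np.ndarray:
    """Dense N x N effective chain operator (for diagonalization checks)."""
    diag, hop = build_effective_chain(n_sites, E, q, params, frame, gamma)
    h = np.diag(diag) + hop * (np.eye(n_sites, k=1) + np.eye(n_sites, k=-1))
    if periodic:
        h[0, -1] = hop
        h[-1, 0] = hop
    return h
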