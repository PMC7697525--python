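"""Derived equilibrium geometry of the double helix.

The rigid-base-pair cylindrical model places base n at
(r_n cos phi_n, r_n sin phi_n, c phi_n) with c = h0/theta0, so the
distance between neighbours along one strand depends only on the
relative twist angle theta_{n,n+1} and the two radial displacements.
All constants here follow from (theta0, h0, R0) alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import GeometryParams

__all__ = ["HelixFrame", "derive_frame", "pair_distance"]


@dataclass(frozen=True)
class HelixFrame:
    """Equilibrium geometry constants (lengths in nm).

    c: pitch parameter h0/theta0.
    xi: helix-arc constant sqrt(c^2 + R0^2); xi*theta is the arc length
        between consecutive bases in the small-oscillation limit.
    l0: equilibrium inter-base distance along a strand.
    f0: c^2 theta0 + R0^2 sin(theta0)  (nm^2).
    g0: R0 (1 - cos theta0).
    lB: 2 f0/g0, the backbone twist-radial coupling length (~25 bp).
    aB: g0 xi^2 / f0, comparable to the rise h0.
    bB: aB/xi (dimensionless).
    """

    theta0: float
    h0: float
    R0: float
    c: float
    xi: float
    l0: float
    f0: float
    g0: float
    lB: float
    aB: float
    bB: float

    @property
    def qstar(self) -> float:
        """Zone-boundary phonon wavevector q* = pi/xi (1/nm)."""
        return math.pi / self.xi


def derive_frame(geom: GeometryParams) -> HelixFrame:
    """Compute all equilibrium constants from (theta0, h0, R0).

    Raises ValueError for theta0 == 0 (the pitch parameter c = h0/theta0
    diverges; GeometryParams normally forbids this already).
    """
    if geom.theta0 == 0:
        raise ValueError("theta0 = 0: pitch parameter c = h0/theta0 is undefined")
    c = geom.h0 / geom.theta0
    xi = math.hypot(c, geom.R0)
    l0 = math.sqrt(geom.h0**2 + 4.0 * geom.R0**2 * math.sin(geom.theta0 / 2.0) ** 2)
    f0 = c**2 * geom.theta0 + geom.R0**2 * math.sin(geom.theta0)
    g0 = geom.R0 * (1.0 - math.cos(geom.theta0))
    lB = 2.0 * f0 / g0
    aB = g0 * xi**2 / f0
    return HelixFrame(
        theta0=geom.theta0,
        h0=geom.h0,
        R0=geom.R0,
        c=c,
        xi=xi,
        l0=l0,
        f0=f0,
        g0=g0,
        lB=lB,
        aB=aB,
        bB=aB / xi,
    )


def pair_distance(rho_n, rho_m, theta, frame: HelixFrame):
    """Distance between adjacent bases on one strand (nm), vectorized.

    d = sqrt(c^2 theta^2 + (R0+rho_n)^2 + (R0+rho_m)^2
             - 2 (R0+rho_n)(R0+rho_m) cos theta)

    The complementary-strand distance is the same function evaluated at
    rho -> lambda*rho.  Angles are relative twist angles and are used
    unwrapped (no mod 2*pi).
    """
    rho_n = np.asarray(rho_n, dtype=float)
    rho_m = np.asarray(rho_m, dtype=float)
    theta = np.asarray(theta, dtype=float)
    rn = frame.R0 + rho_n
    rm = frame.R0 + rho_m
    if np.any(rn < 0) or np.any(rm < 0):
        raise ValueError("radial displacement below -R0 (negative radius)")
    # rn^2 + rm^2 - 2 rn rm cos(theta) rewritten without cancellation
    d2 = (
        frame.c**2 * theta**2
        + (rn - rm) ** 2
        + 4.0 * rn * rm * np.sin(theta / 2.0) ** 2
    )
    out = np.sqrt(d2)
    return float(out) if out.ndim == 0 else out
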