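"""Linearized equations of motion, RK4 integration, codon renormalization."""

import math

import numpy as np
import pytest

import helixct as hx


@pytest.fixture(scope="module")
def ring48(gc_params, frame):
    return hx.site_coefficients(["GC"] * 48, gc_params, frame)


def wave_state(q_index, branch, gc_params, frame, cf, n=48):
    q = 2 * math.pi * q_index / (n * frame.xi)
    return hx.init_helical_wave(q, branch, 0.14, n, gc_params, frame, cf)


class TestLinearRHS:
    def test_rigid_rotation_never_accelerates(self, ring48):
        phi_dd, rho_dd = hx.linear_rhs(np.full(48, 0.3), np.zeros(48), ring48)
        assert np.max(np.abs(phi_dd)) == 0.0
        assert np.max(np.abs(rho_dd)) == 0.0

    @pytest.mark.parametrize("branch", ["acoustic", "optical"])
    @pytest.mark.parametrize("q_index", [3, 7, 17, 24])
    def test_helical_wave_is_eigenmode(self, ring48, gc_params, frame, cf_gc, branch, q_index):
        """Plane-wave substitution: accelerations equal -omega^2 times the
        fields, confirming the analytic dispersion dynamically."""
        state, omega = wave_state(q_index, branch, gc_params, frame, cf_gc)
        phi_dd, rho_dd = hx.linear_rhs(state.phi, state.rho, ring48)
        scale = omega**2 * max(np.linalg.norm(state.phi), np.linalg.norm(state.rho))
        assert np.linalg.norm(phi_dd + omega**2 * state.phi) / scale < 1e-8
        assert np.linalg.norm(rho_dd + omega**2 * state.rho) / scale < 1e-8

    def test_homopolymer_equals_hs_form(self, ring48, gc_params, frame, cf_gc, rng):
        # rho equation rewritten with omega_HS^2: identical accelerations
        phi = 0.05 * rng.standard_normal(48)
        rho = 0.01 * rng.standard_normal(48)
        _, rho_dd = hx.linear_rhs(phi, rho, ring48)
        w_hs2 = cf_gc.omega_HS**2
        w_pr2 = cf_gc.omega_phirho**2
        _, b_l, _ = hx.coupling_constants(gc_params.pair, frame)
        rho_m, rho_p = np.roll(rho, 1), np.roll(rho, -1)
        phi_m, phi_p = np.roll(phi, 1), np.roll(phi, -1)
        alt = (
            -0.5 * w_pr2 * (2 * rho + rho_m + rho_p)
            + 0.5 * w_hs2 * (rho_m + rho_p)
            + b_l * cf_gc.omega_phi**2 * (phi_m - phi_p)
        )
        assert np.allclose(rho_dd, alt, rtol=1e-10, atol=1e-3 * np.max(np.abs(rho_dd)))

    def test_too_short_chain_rejected(self, gc_params, frame):
        with pytest.raises(ValueError):
            hx.site_coefficients(["GC", "GC"], gc_params, frame)


class TestIntegration:
    def test_zero_state_stays_zero(self, ring48):
        n = 48
        state = hx.ChainState(np.zeros(n), np.zeros(n), np.zeros(n), np.zeros(n))
        traj = hx.integrate(state, ring48, 1e-15, 100, stride=10)
        assert np.all(traj.phi == 0) and np.all(traj.rho == 0)

    @pytest.mark.parametrize("branch", ["acoustic", "optical"])
    def test_mode_preservation_over_ten_periods(
        self, ring48, gc_params, frame, cf_gc, branch
    ):
        """A pure (q, branch) excitation keeps its amplitude (<0.1% drift)
        and leaks <1e-3 into other spatial modes."""
        k = 7
        state, omega = wave_state(k, branch, gc_params, frame, cf_gc)
        steps = int(10 * (2 * math.pi / omega) / 1e-15)
        traj = hx.integrate(state, ring48, 1e-15, steps, stride=steps)
        f0 = np.fft.fft(state.phi if branch == "acoustic" else state.rho)
        f1 = np.fft.fft(traj.phi[-1] if branch == "acoustic" else traj.rho[-1])
        a0, a1 = abs(f0[k]), abs(f1[k])
        assert abs(a1 - a0) / a0 < 1e-3
        leak = np.abs(f1.copy())
        leak[k] = leak[48 - k] = 0.0
        assert leak.max() / a0 < 1e-3

    def test_time_reversal_symmetry(self, ring48, gc_params, frame, cf_gc):
        # forward 400 steps, then backward with -dt from the final phase-space
        # point: the initial fields are recovered to integrator accuracy
        state, _ = wave_state(5, "acoustic", gc_params, frame, cf_gc)
        fwd = hx.integrate(state, ring48, 1e-15, 400, stride=400)
        vphi, vrho = _final_velocities(state, ring48, 400)
        rev = hx.integrate(
            hx.ChainState(fwd.phi[-1], fwd.rho[-1], vphi, vrho),
            ring48,
            -1e-15,
            400,
            stride=400,
        )
        assert np.allclose(rev.phi[-1], state.phi, atol=1e-10 * np.max(np.abs(state.phi)))
        assert np.allclose(rev.rho[-1], state.rho, atol=1e-10 * np.max(np.abs(state.phi)))

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_instability_detection(self, ring48):
        n = 48
        rho = 0.01 * (-1.0) ** np.arange(n)  # excites the fastest optical mode
        state = hx.ChainState(np.zeros(n), rho, np.zeros(n), np.zeros(n))
        with pytest.raises(RuntimeError):
            # dt far beyond the stability limit of the fastest mode
            hx.integrate(state, ring48, 5e-13, 20000, stride=1000)

    def test_spectrum_recovers_both_branches(self, ring48, gc_params, frame, cf_gc, rng):
        """Temporal FFT of a randomly excited ring shows peaks at the two
        analytic branch frequencies, within the FFT resolution."""
        n = 48
        state = hx.ChainState(
            0.02 * rng.standard_normal(n),
            0.01 * rng.standard_normal(n),
            np.zeros(n),
            np.zeros(n),
        )
        traj = hx.integrate(state, ring48, 4e-15, 16384, stride=1)
        for k in (5, 11):
            q = 2 * math.pi * k / (n * frame.xi)
            exact = hx.dispersion_exact([q], cf_gc, frame, gc_params.pair)
            spec = hx.mode_spectrum(traj, k)
            assert spec["nu_acoustic_thz"] == pytest.approx(
                exact.nu_minus[0], abs=spec["resolution_thz"]
            )
            assert spec["nu_optical_thz"] == pytest.approx(
                exact.nu_plus[0], abs=spec["resolution_thz"]
            )


def _final_velocities(state, coeffs, steps, dt=1e-15):
    """Integrate the first-order system tracking velocities (helper)."""
    phi, rho = state.phi.copy(), state.rho.copy()
    vphi, vrho = state.phi_dot.copy(), state.rho_dot.copy()
    for _ in range(steps):
        k1p, k1r = vphi, vrho
        a1p, a1r = hx.linear_rhs(phi, rho, coeffs)
        k2p, k2r = vphi + 0.5 * dt * a1p, vrho + 0.5 * dt * a1r
        a2p, a2r = hx.linear_rhs(phi + 0.5 * dt * k1p, rho + 0.5 * dt * k1r, coeffs)
        k3p, k3r = vphi + 0.5 * dt * a2p, vrho + 0.5 * dt * a2r
        a3p, a3r = hx.linear_rhs(phi + 0.5 * dt * k2p, rho + 0.5 * dt * k2r, coeffs)
        k4p, k4r = vphi + dt * a3p, vrho + dt * a3r
        a4p, a4r = hx.linear_rhs(phi + dt * k3p, rho + dt * k3r, coeffs)
        phi = phi + dt / 6 * (k1p + 2 * k2p + 2 * k3p + k4p)
        rho = rho + dt / 6 * (k1r + 2 * k2r + 2 * k3r + k4r)
        vphi = vphi + dt / 6 * (a1p + 2 * a2p + 2 * a3p + a4p)
        vrho = vrho + dt / 6 * (a1r + 2 * a2r + 2 * a3r + a4r)
    return vphi, vrho


class TestCodonRenormalization:
    def test_linear_trajectory_satisfies_codon_equations(
        self, ring48, gc_params, frame, cf_gc
    ):
        state, _ = wave_state(7, "optical", gc_params, frame, cf_gc)
        traj = hx.integrate(state, ring48, 1e-15, 2000, stride=1)
        assert hx.codon_residual(traj, ring48) < 1e-4

    def test_nested_triplets_satisfy_same_equations(
        self, ring48, gc_params, frame, cf_gc
    ):
        state, _ = wave_state(5, "acoustic", gc_params, frame, cf_gc)
        traj = hx.integrate(state, ring48, 1e-15, 2000, stride=1)
        assert hx.codon_residual(traj, ring48, nested=2) < 1e-4

    def test_zero_trajectory_zero_residual(self, ring48):
        n = 48
        state = hx.ChainState(np.zeros(n), np.zeros(n), np.zeros(n), np.zeros(n))
        traj = hx.integrate(state, ring48, 1e-15, 10, stride=1)
        x, y = hx.codon_fields(traj)
        assert np.all(x == 0) and np.all(y == 0)

    def test_heteropolymer_rejected(self, gc_params, frame):
        coeffs = hx.site_coefficients(["GC", "AT"] * 6, gc_params, frame)
        state = hx.ChainState(np.zeros(12), np.zeros(12), np.zeros(12), np.zeros(12))
        traj = hx.integrate(state, coeffs, 1e-15, 10, stride=1)
        with pytest.raises(ValueError):
            hx.codon_residual(traj, coeffs)


class TestHelicalWaveInit:
    def test_q_zero_acoustic_is_uniform_twist(self, gc_params, frame, cf_gc):
        state, omega = hx.init_helical_wave(0.0, "acoustic", 0.14, 12, gc_params, frame, cf_gc)
        assert omega == 0.0
        assert np.allclose(state.phi, 0.14)
        assert np.all(state.rho == 0)

    def test_zone_boundary_modes_decouple(self, gc_params, frame, cf_gc):
        n = 12
        q = math.pi / frame.xi  # q xi = pi, commensurate with even n
        ac, _ = hx.init_helical_wave(q, "acoustic", 0.14, n, gc_params, frame, cf_gc)
        op, _ = hx.init_helical_wave(q, "optical", 0.14, n, gc_params, frame, cf_gc)
        assert np.all(ac.rho == 0) and np.any(ac.phi != 0)
        assert np.all(op.phi == 0) and np.any(op.rho != 0)

    def test_amplitude_ratio_matches_secular_row(self, gc_params, frame, cf_gc):
        n, k = 48, 9
        q = 2 * math.pi * k / (n * frame.xi)
        state, omega = hx.init_helical_wave(q, "acoustic", 0.14, n, gc_params, frame, cf_gc)
        a_l, _, _ = hx.coupling_constants(gc_params.pair, frame)
        g = 4 * cf_gc.omega_phi**2 * math.sin(q * frame.xi / 2) ** 2
        expected = abs(g - omega**2) / (2 * a_l * cf_gc.omega_phi**2 * abs(math.sin(q * frame.xi)))
        assert np.max(np.abs(state.rho)) / np.max(np.abs(state.phi)) == pytest.approx(
            expected, rel=1e-3
        )

    def test_non_commensurate_q_rejected(self, gc_params, frame, cf_gc):
        with pytest.raises(ValueError):
            hx.init_helical_wave(0.777, "acoustic", 0.14, 12, gc_params, frame, cf_gc)


class TestMakeSequence:
    def test_homopolymer(self):
        assert hx.make_sequence("homopolymer", 12) == ["GC"] * 12

    def test_random_is_deterministic_and_binomial(self):
        a = hx.make_sequence("random", 10000, seed=1)
        b = hx.make_sequence("random", 10000, seed=1)
        assert a == b
        frac = a.count("GC") / len(a)
        assert abs(frac - 0.5) < 0.02

    def test_fasta_mapping(self):
        assert hx.make_sequence("fasta", fasta="acGT") == ["AT", "GC", "GC", "AT"]

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValueError):
            hx.make_sequence("fasta", fasta="ACGN")

    def test_fasta_file(self, tmp_path):
        p = tmp_path / "seq.fa"
        p.write_text(">toy\nGGAA\n")
        assert hx.make_sequence("fasta", fasta=str(p)) == ["GC", "GC", "AT", "AT"]
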