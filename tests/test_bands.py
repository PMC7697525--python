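"""Transfer-matrix band structure, gaps and the gamma scan."""

import math

import numpy as np
import pytest

import helixct as hx

# published band-structure table, meV: (W_wider, W_narrower, Eg(0,0), Eg(0,q*))
PRINTED_BANDS = {"GC": (29.7, 24.4, 80.3, 73.0), "AT": (22.0, 16.6, 93.5, 87.4)}


def kappa_grid(frame, n=201):
    return np.linspace(0.0, math.pi / frame.h0, n)


class TestCouplingFunction:
    def test_limits(self, gc_params, frame):
        t0 = gc_params.electronic.t0
        assert hx.coupling_function(0.0, 0.0, gc_params, frame) == pytest.approx(3 * t0)
        assert hx.coupling_function(math.pi / frame.h0, 0.0, gc_params, frame) == (
            pytest.approx(-t0)
        )
        assert hx.coupling_function(2 * math.pi / (3 * frame.h0), 0.0, gc_params, frame) == (
            pytest.approx(0.0, abs=1e-15)
        )


class TestCarrierBands:
    @pytest.mark.parametrize("species", ["GC", "AT"])
    def test_printed_table_within_one_percent(self, species, frame):
        params = hx.default_params(species)
        res0 = hx.carrier_bands(kappa_grid(frame), 0.0, params, 0.0, frame)
        res_star = hx.carrier_bands(kappa_grid(frame), frame.qstar, params, 0.0, frame)
        w_wide, w_narrow, eg0, eg_star = PRINTED_BANDS[species]
        wide, narrow = res0.widths_sorted
        assert wide * 1e3 == pytest.approx(w_wide, rel=0.01)
        assert narrow * 1e3 == pytest.approx(w_narrow, rel=0.01)
        assert res0.gap_kappa0 * 1e3 == pytest.approx(eg0, rel=0.01)
        assert res_star.gap_kappa0 * 1e3 == pytest.approx(eg_star, rel=0.01)

    def test_bands_do_not_overlap(self, gc_params, frame):
        res = hx.carrier_bands(kappa_grid(frame), 0.0, gc_params, 0.0, frame)
        assert res.min_separation > 0
        assert not res.gap_closed

    def test_root_product_vieta_identity(self, gc_params, frame):
        # at gamma = 0 the product of roots is 2 tP^2/(2 b - 1) for every kappa
        e = gc_params.electronic
        res = hx.carrier_bands(kappa_grid(frame, 41), 0.0, gc_params, 0.0, frame)
        product = res.E_plus * res.E_minus
        assert np.allclose(product, 2 * e.tP**2 / (2 * e.b_xy - 1), rtol=1e-12)

    def test_gap_decreases_monotonically_with_q(self, gc_params, frame):
        qs = np.linspace(0.0, frame.qstar, 25)
        gaps = [hx.bandgap_closed_form(gc_params, 0.0, q, frame) for q in qs]
        assert np.all(np.diff(gaps) < 0)

    @pytest.mark.parametrize("species, printed", [("GC", 9.0), ("AT", 6.5)])
    def test_relative_gap_reduction(self, species, printed, frame):
        params = hx.default_params(species)
        eg0 = hx.bandgap_closed_form(params, 0.0, 0.0, frame)
        eg_star = hx.bandgap_closed_form(params, 0.0, frame.qstar, frame)
        reduction = (eg0 - eg_star) / eg0 * 100
        assert reduction == pytest.approx(printed, abs=1.0)  # percentage points

    def test_at_bands_sit_above_gc_bands(self, gc_params, at_params, frame):
        # polyA-polyT band centre is shifted up relative to polyG-polyC
        gc = hx.carrier_bands(kappa_grid(frame), 0.0, gc_params, 0.0, frame)
        at = hx.carrier_bands(kappa_grid(frame), 0.0, at_params, 0.0, frame)
        center = lambda r: (np.mean(r.E_plus) + np.mean(r.E_minus)) / 2
        assert center(at) > center(gc)


class TestClosedFormGap:
    def test_agrees_with_quadratic_roots_everywhere(self, gc_params, frame, rng):
        # gamma below the first closure (~0.29 eV at q = q*): gap always open
        for _ in range(20):
            gamma = float(rng.uniform(0.0, 0.25))
            q = float(rng.uniform(0.0, frame.qstar))
            res = hx.carrier_bands(np.array([0.0]), q, gc_params, gamma, frame)
            closed = hx.bandgap_closed_form(gc_params, gamma, q, frame)
            assert res.gap_kappa0 == pytest.approx(closed, abs=1e-10)

    def test_closed_gap_is_flagged(self, gc_params, frame):
        res = hx.carrier_bands(np.array([0.0]), 0.0, gc_params, 1.0, frame)
        assert res.gap_closed

    def test_semimetal_returns_zero(self, gc_params, frame):
        assert hx.bandgap_closed_form(gc_params, 5.0, 0.0, frame) == 0.0


class TestTransferMatrix:
    @pytest.mark.parametrize("E", [-0.5, -0.275, 0.4, 1.7])
    def test_unimodular(self, gc_params, frame, E):
        m = hx.transfer_matrix(E, 0.0, gc_params, 0.0, frame)
        assert np.linalg.det(m) == pytest.approx(1.0, abs=1e-12)

    def test_half_trace_bounded_exactly_on_bands(self, gc_params, frame):
        res = hx.carrier_bands(kappa_grid(frame, 51), 0.0, gc_params, 0.0, frame)
        for E in np.concatenate([res.E_plus, res.E_minus]):
            m = hx.transfer_matrix(float(E), 0.0, gc_params, 0.0, frame)
            assert abs(np.trace(m) / 2) <= 1.0 + 1e-9

    def test_half_trace_is_pm_one_at_band_edges(self, gc_params, frame):
        res = hx.carrier_bands(np.array([0.0, math.pi / frame.h0]), 0.0, gc_params, 0.0, frame)
        for E in (res.E_plus[0], res.E_minus[0], res.E_plus[-1], res.E_minus[-1]):
            m = hx.transfer_matrix(float(E), 0.0, gc_params, 0.0, frame)
            assert abs(np.trace(m) / 2) == pytest.approx(1.0, abs=1e-9)

    def test_pole_rejected(self, gc_params, frame):
        with pytest.raises(ValueError):
            hx.transfer_matrix(0.0, 0.0, gc_params, 0.0, frame)


class TestChebyshevPower:
    def test_first_power_is_identity_operation(self):
        m = np.array([[1.3, -1.0], [1.0, 0.0]])
        assert np.allclose(hx.chebyshev_power(m, 1), m)

    @pytest.mark.parametrize("trace_half", [0.3, 0.99, 1.7])
    def test_matches_brute_force_product(self, trace_half):
        """Chebyshev evaluation of M^N equals repeated multiplication,
        inside the band, near the edge and in the hyperbolic regime."""
        m = np.array([[2 * trace_half, -1.0], [1.0, 0.0]])
        brute = np.linalg.matrix_power(m, 8)
        cheb = hx.chebyshev_power(m, 8)
        assert np.max(np.abs(cheb - brute)) < 1e-10 * max(1.0, np.max(np.abs(brute)))

    def test_degenerate_band_edge(self):
        m = np.array([[2.0, -1.0], [1.0, 0.0]])  # x = 1 exactly
        got = hx.chebyshev_power(m, 6)
        assert np.allclose(got, np.linalg.matrix_power(m, 6), atol=1e-9)

    def test_non_unimodular_rejected(self):
        with pytest.raises(ValueError):
            hx.chebyshev_power(np.diag([2.0, 1.0]), 3)


class TestFiniteChainDispersion:
    def test_band_edges_invert_to_zone_points(self, gc_params, frame):
        res = hx.carrier_bands(np.array([0.0, math.pi / frame.h0]), 0.0, gc_params, 0.0, frame)
        kappa, allowed = hx.finite_chain_dispersion(
            [res.E_plus[0], res.E_plus[-1]], 0.0, gc_params, 0.0, frame
        )
        assert allowed.all()
        assert kappa[0] == pytest.approx(0.0, abs=1e-4)
        assert kappa[1] == pytest.approx(math.pi / frame.h0, rel=1e-6)

    def test_allowed_set_equals_carrier_bands(self, gc_params, frame):
        res = hx.carrier_bands(kappa_grid(frame, 301), 0.0, gc_params, 0.0, frame)
        E = np.linspace(res.E_minus.min() - 0.02, res.E_plus.max() + 0.02, 1500)
        _, allowed = hx.finite_chain_dispersion(E, 0.0, gc_params, 0.0, frame)
        in_bands = (
            (E >= res.E_minus.min() - 1e-9) & (E <= res.E_minus.max() + 1e-9)
        ) | ((E >= res.E_plus.min() - 1e-9) & (E <= res.E_plus.max() + 1e-9))
        assert np.array_equal(allowed, in_bands)

    def test_gap_energies_are_evanescent(self, gc_params, frame):
        res = hx.carrier_bands(kappa_grid(frame), 0.0, gc_params, 0.0, frame)
        E_gap = (res.E_minus.max() + res.E_plus.min()) / 2
        lhs, tr8 = hx.ring_trace_check(E_gap, 0.0, 8, gc_params, 0.0)
        _, tr16 = hx.ring_trace_check(E_gap, 0.0, 16, gc_params, 0.0)
        assert math.isnan(lhs)
        assert abs(tr16) > abs(tr8) > 1.0

    def test_ring_trace_consistency_in_band(self, gc_params, frame):
        res = hx.carrier_bands(kappa_grid(frame, 5), 0.0, gc_params, 0.0, frame)
        E = float(res.E_plus[2])
        lhs, rhs = hx.ring_trace_check(E, 0.0, 12, gc_params, 0.0)
        assert lhs == pytest.approx(rhs, abs=1e-6)


class TestGammaScan:
    def test_endpoint_matches_table(self, gc_params, frame):
        df, closures = hx.gamma_scan(gc_params, np.linspace(0.0, 12.0, 121), 0.0, frame)
        assert df.gap_meV.iloc[0] == pytest.approx(80.3, rel=0.01)

    def test_closure_points_solve_radicand(self, gc_params, frame):
        e = gc_params.electronic
        df, closures = hx.gamma_scan(gc_params, np.linspace(0.0, 12.0, 481), 0.0, frame)
        assert len(closures) >= 1
        for g in closures:
            lhs = (3 * e.t0 + 2 * e.a_xy - g) ** 2
            rhs = 8 * (2 * e.b_xy - 1) * e.tP**2
            assert lhs == pytest.approx(rhs, rel=1e-8)
        # semiconductor below the first closure, semimetal above it
        assert df[df.gamma_eV < closures[0]].gap_meV.min() > 0
        inside = df[(df.gamma_eV > closures[0] + 0.05) & (df.gamma_eV < 12.0)]
        assert np.allclose(inside.gap_meV, 0.0)

    def test_gap_continuous_in_gamma(self, gc_params, frame):
        # sqrt-type closure: steepest step ~ sqrt(66.8 * dgamma) eV near the
        # transition, ~7 meV for this grid spacing
        df, _ = hx.gamma_scan(gc_params, np.linspace(0.0, 1.0, 400), 0.0, frame)
        assert np.max(np.abs(np.diff(df.gap_meV))) < 10.0
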