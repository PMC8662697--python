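import numpy as np
import pytest
from hypothesis import given, strategies as st

import hepatocal as hc
from hepatocal.calcium import (
    CALIBRATED_STIMULUS, calcium_rhs, gap_junction_flux, ip3_rhs, ip3r_rhs,
    receptor_rhs, single_cell_trajectory,
)
from hepatocal.params import CalciumParams, InitialConditions


# ---------------------------------------------------------------------------
# straight-line oracle: the four rate laws written out term by term,
# independent of the package implementation
# ---------------------------------------------------------------------------

def oracle_rates(state, H, p, CaT, G_ij, ip3_left, ip3_right):
    r, IP3, CaI, g = state
    k_r, k_IP3 = p.k_r_i[7], p.k_IP3_i[7]
    dr = k_r * (1 - r) - p.k_d * r - p.k_Hr * H * r
    coupling = 0.0
    for nb in (ip3_left, ip3_right):
        if nb is not None:
            coupling += G_ij * (IP3 - nb)
    dIP3 = (k_IP3 * H * r / (p.k_cat + r)) * (CaI / (CaI + p.k3)) - p.D * IP3 - coupling
    dCaI = (1 - g) * (p.A * IP3**4 / (p.k1 + IP3)**4 + p.L) * (CaT - CaI) \
        - p.B * CaI**2 / (p.k2**2 + CaI**2)
    dg = p.E * CaI**4 * (1 - g) - p.F
    return dr, dIP3, dCaI, dg


class TestRateLaws:
    def test_receptor_balance_examples(self):
        # fully free receptors, no hormone: only nonspecific binding drains
        assert receptor_rhs(1.0, 0.0, 0.5, 0.34, 1.0) == pytest.approx(-0.34)
        # hormone-free steady state of the linear receptor ODE
        r_star = 0.5 / (0.5 + 0.34)
        assert receptor_rhs(r_star, 0.0, 0.5, 0.34, 1.0) == pytest.approx(0.0, abs=1e-15)
        # empty receptor pool refills at the recycling rate
        assert receptor_rhs(0.0, 7.3, 0.5, 0.34, 1.0) == pytest.approx(0.5)

    def test_receptor_domain_errors(self):
        with pytest.raises(ValueError):
            receptor_rhs(1.2, 0.0, 0.5, 0.34, 1.0)
        with pytest.raises(ValueError):
            receptor_rhs(0.5, -1.0, 0.5, 0.34, 1.0)

    def test_ip3_synthesis_gated_by_calcium_and_stimulus(self):
        p = CalciumParams()
        # closed Ca feedback gate: pure decay plus coupling
        out = ip3_rhs(0.4, 0.5, 0.0, 5.0, 0.55, p.k_cat, p.k3, p.D,
                      coupling=0.1)
        assert out == pytest.approx(-p.D * 0.4 - 0.1)
        # no stimulus: synthesis vanishes
        out = ip3_rhs(0.4, 0.5, 1.0, 0.0, 0.55, p.k_cat, p.k3, p.D, coupling=0.0)
        assert out == pytest.approx(-p.D * 0.4)

    def test_equilibrated_junctions_carry_no_flux(self):
        IP3 = np.full(15, 0.37)
        assert np.all(gap_junction_flux(IP3, 5.0) == 0.0)
        assert np.all(gap_junction_flux(np.linspace(0, 1, 15), 0.0) == 0.0)

    def test_store_release_examples(self):
        # fully bound IP3R blocks release entirely
        out = calcium_rhs(0.5, 500.2, 1.0, 2.0, 0.2, 1.0, 0.00015, 0.082, 0.15)
        assert out == pytest.approx(-0.082 * 0.25 / (0.15**2 + 0.25))
        # empty store: no release, pump still removes Ca
        out = calcium_rhs(500.2, 500.2, 0.0, 2.0, 0.2, 1.0, 0.00015, 0.082, 0.15)
        assert out <= 0.0
        # hand-evaluated nominal point: CaI = k2, IP3 = 0, g = 0
        out = calcium_rhs(0.15, 500.2, 0.0, 0.0, 0.2, 1.0, 0.00015, 0.082, 0.15)
        assert out == pytest.approx(0.00015 * (500.2 - 0.15) - 0.082 / 2, rel=1e-12)

    def test_store_overflow_rejected(self):
        with pytest.raises(ValueError):
            calcium_rhs(501.0, 500.2, 0.5, 0.1, 0.2, 1.0, 0.00015, 0.082, 0.15)

    def test_ip3r_inactivation_examples(self):
        assert ip3r_rhs(1.0, 5.0, 1.0, 0.01) == pytest.approx(-0.01)
        assert ip3r_rhs(0.3, 0.0, 1.0, 0.01) == pytest.approx(-0.01)
        # steady state at CaI = 1 µM
        g_star = 1 - 0.01 / 1.0
        assert ip3r_rhs(g_star, 1.0, 1.0, 0.01) == pytest.approx(0.0, abs=1e-14)

    def test_rhs_matches_straight_line_oracle_on_random_states(self, rng):
        p = CalciumParams()
        CaT = 500.2
        for _ in range(100):
            r = rng.uniform(0, 1)
            IP3 = rng.uniform(0, 3)
            CaI = rng.uniform(0, 5)
            g = rng.uniform(0, 1)
            H = rng.uniform(0, 10)
            G_ij = rng.choice([0.0, 2.5, 5.0])
            left, right = rng.uniform(0, 3, size=2)
            want = oracle_rates((r, IP3, CaI, g), H, p, CaT, G_ij, left, right)
            got = (
                receptor_rhs(r, H, p.k_r_i[7], p.k_d, p.k_Hr),
                ip3_rhs(IP3, r, CaI, H, p.k_IP3_i[7], p.k_cat, p.k3, p.D,
                        coupling=G_ij * (IP3 - left) + G_ij * (IP3 - right)),
                calcium_rhs(CaI, CaT, g, IP3, p.A, p.k1, p.L, p.B, p.k2),
                ip3r_rhs(g, CaI, p.E, p.F),
            )
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)


class TestGapJunctionCoupling:
    @given(st.lists(st.floats(0, 5, allow_nan=False), min_size=2, max_size=20),
           st.sampled_from([0.5, 2.5, 5.0]))
    def test_pairwise_fluxes_conserve_total_ip3(self, values, gij):
        flux = gap_junction_flux(np.array(values), gij)
        assert abs(flux.sum()) < 1e-9 * max(1.0, np.abs(values).max())

    def test_pairwise_fluxes_are_antisymmetric(self):
        IP3 = np.array([0.1, 0.9, 0.4])
        gij = 5.0
        # pair (0,1): flux out of 0 equals flux into 1 from that pair
        f01 = gij * (IP3[0] - IP3[1])
        f12 = gij * (IP3[1] - IP3[2])
        flux = gap_junction_flux(IP3, gij)
        assert flux[0] == pytest.approx(f01)
        assert flux[1] == pytest.approx(-f01 + f12)
        assert flux[2] == pytest.approx(-f12)

    def test_chain_ends_have_single_neighbor(self):
        IP3 = np.array([1.0, 0.0, 0.0, 0.0])
        flux = gap_junction_flux(IP3, 2.5)
        assert flux[0] == pytest.approx(2.5)      # only exchanges with cell 2
        assert flux[-1] == pytest.approx(0.0)


class TestSingleCell:
    def test_unstimulated_cell_never_spikes(self):
        t, s = single_cell_trajectory(H=0.0, t_end=2000.0)
        spikes = hc.detect_spikes(t, s["CaI"])
        assert len(spikes) == 0

    def test_calibrated_stimulus_yields_sustained_spiking(self):
        t, s = single_cell_trajectory(H=CALIBRATED_STIMULUS, t_end=1500.0)
        spikes = hc.detect_spikes(t, s["CaI"])
        assert len(spikes) >= 10

    def test_states_remain_in_invariant_ranges(self):
        t, s = single_cell_trajectory(H=CALIBRATED_STIMULUS, t_end=1000.0)
        tol = 1e-6
        assert np.all(s["r"] >= -tol) and np.all(s["r"] <= 1 + tol)
        assert np.all(s["g"] >= -tol) and np.all(s["g"] <= 1 + tol)
        assert np.all(s["IP3"] >= -tol)
        assert np.all(s["CaI"] >= -tol)
        assert np.all(s["CaI"] <= InitialConditions().CaT0 + tol)

    def test_negative_stimulus_rejected(self):
        with pytest.raises(ValueError):
            single_cell_trajectory(H=-1.0, t_end=10.0)
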