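"""Ca2+ handling: K_SERCA factor, SERCA pump, buffers, conservation."""

import numpy as np
import pytest

from mouseatria import core
from mouseatria.calcium import (CaMKIIState, SercaParams, camkii_activation,
                                compartment_fluxes, k_serca, serca_flux)

from conftest import total_cell_ca


class TestKSerca:
    def test_midpoint_is_exactly_half(self):
        assert k_serca(0.0167) == pytest.approx(0.5, abs=1e-12)

    def test_limit_at_zero_phosphorylation(self):
        assert k_serca(0.0) == pytest.approx(0.0, abs=1e-10)

    def test_double_midpoint_value(self):
        # direct evaluation: 1 / ((1/2)^12 + 1)
        assert k_serca(0.0334) == pytest.approx(1.0 / (0.5 ** 12 + 1.0),
                                                rel=1e-6)

    def test_bounded_on_a_grid(self):
        # [0, 1) mathematically; the top end rounds to 1.0 in floats
        for ph in np.linspace(0.0, 1.0, 101):
            assert 0.0 <= k_serca(ph) <= 1.0
        assert k_serca(0.05) < 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            k_serca(-0.1)


class TestSercaFlux:
    @pytest.fixture(scope="class")
    def serca(self, params):
        return SercaParams.from_model(params)

    def test_forward_only_when_sr_empty(self, serca):
        assert serca_flux(1e-4, 0.0, serca, 0.2) > 0.0

    def test_strictly_increasing_in_camkii_factor(self, serca):
        ks = np.linspace(0.0, 0.99, 12)
        js = [serca_flux(3e-4, 0.5, serca, k) for k in ks]
        assert np.all(np.diff(js) > 0.0)

    def test_leak_back_bounded_when_sr_dominates(self, serca):
        j = serca_flux(1e-6, 3.0, serca, 0.0)
        assert -serca.v_max * 2.0 < j < 0.0

    def test_invalid_concentrations_rejected(self, serca):
        with pytest.raises(ValueError):
            serca_flux(0.0, 0.5, serca, 0.1)


class TestCaMKII:
    def test_activation_decays_at_diastolic_calcium(self, params):
        state = CaMKIIState(act=0.5, ph_plb=0.05)
        for _ in range(10000):  # 10 s at diastolic cleft Ca2+
            state = camkii_activation(1e-4, state, 1.0, params)
        assert state.act < 0.05

    def test_fractions_stay_in_unit_interval(self, params):
        state = CaMKIIState(act=0.0, ph_plb=0.0)
        for _ in range(2000):
            state = camkii_activation(0.5, state, 1.0, params)
            assert 0.0 <= state.act <= 1.0
            assert 0.0 <= state.ph_plb <= 1.0

    def test_invalid_state_rejected(self, params):
        with pytest.raises(ValueError):
            camkii_activation(1e-4, CaMKIIState(act=1.5), 1.0, params)


class TestConservation:
    def test_total_ca_constant_under_closed_sarcolemma(self, params,
                                                       warm_state):
        """With all sarcolemmal Ca2+ pathways blocked, total cell Ca2+
        (free + buffered + SR, volume weighted) is conserved."""
        blocked = params.with_block({"ICaL": 1.0, "INCX": 1.0,
                                     "IPMCA": 1.0, "ICab": 1.0})
        t, ymat, final, _ = core.integrate_segments(
            warm_state.y.copy(), blocked, [(10000.0, {"stim": 0.0})],
            grid=100.0)
        before = total_cell_ca(warm_state.y, blocked)
        after = total_cell_ca(final.y, blocked)
        assert abs(after - before) / before < 1e-9

    def test_sr_and_cytosol_reference_conversion(self, params, beat_05hz):
        """SR- and cytosol-referenced release differ exactly by the
        volume-fraction ratio (pure unit conversion)."""
        v = params.volumes()
        j_cyto = beat_05hz.fluxes["J_rel"]
        j_sr = j_cyto * (v["cyto"] / v["SR"])
        assert np.allclose(j_sr * (v["SR"] / v["cyto"]), j_cyto)
        assert j_sr.max() / j_cyto.max() == pytest.approx(
            v["cyto"] / v["SR"], rel=1e-12)


def test_compartment_fluxes_wrapper_is_mass_conserving(params):
    conc = {"Ca_i": 1e-4, "Ca_SL": 1.2e-4, "Ca_cleft": 2e-4, "Ca_SR": 0.55}
    fluxes = {"J_up": 1e-5, "J_rel": 2e-4, "J_leak": 1e-6}
    d = compartment_fluxes(conc, fluxes, params)
    v = params.volumes()
    # no sarcolemmal flux supplied -> compartmental changes must cancel
    total = (d["Ca_i"] * v["cyto"] + d["Ca_SL"] * v["SL"]
             + d["Ca_cleft"] * v["cleft"] + d["Ca_SR"] * v["SR"])
    assert total == pytest.approx(0.0, abs=1e-18)


def test_fdar_direction_of_plb_phosphorylation(params, steady_05hz,
                                               steady_2hz):
    """Faster pacing leaves more CaMKII activity and PLB phosphorylation."""
    assert steady_2hz["CaMKII_act"] > steady_05hz["CaMKII_act"]
    assert steady_2hz["Ph_PLB"] >= steady_05hz["Ph_PLB"]
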