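"""Sarcolemmal current formulations: reversal, rectification, pumps."""

import numpy as np
import pytest

from mouseatria import membrane as mb
from mouseatria.constants import f_over_rt


def ek(params, k_i=140.0):
    return mb.nernst(1, k_i, params["K_o"], params.temperature)


class TestNernst:
    def test_equal_concentrations_give_zero(self):
        assert mb.nernst(1, 5.4, 5.4, 37.0) == 0.0

    def test_potassium_hand_value(self):
        # (RT/F) ln(5.4/140) at 37 C, evaluated by hand: about -87.0 mV
        assert mb.nernst(1, 140.0, 5.4, 37.0) == pytest.approx(-87.0, abs=0.1)

    def test_chloride_shift_direction(self):
        # raising internal Cl- at fixed bath makes E_Cl less negative
        e8 = mb.nernst(-1, 8.0, 150.0, 37.0)
        e14 = mb.nernst(-1, 14.0, 150.0, 37.0)
        assert e8 < e14 < 0.0

    def test_zero_valence_rejected(self):
        with pytest.raises(ValueError):
            mb.nernst(0, 1.0, 1.0, 37.0)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            mb.nernst(1, 0.0, 5.4, 37.0)


class TestIss:
    def test_zero_gate_gives_zero(self, params):
        assert mb.iss_current(0.0, 30.0, -87.0, params["g_ss"], 1.0) == 0.0

    def test_zero_at_reversal(self, params):
        assert mb.iss_current(0.5, -87.0, -87.0, params["g_ss"], 1.0) == 0.0

    def test_slow_monotone_activation_no_inactivation(self, params):
        """Step response rises monotonically over 500 ms, no decay."""
        x_inf, tau = mb.iss_gate(30.0, 1.0)
        t = np.linspace(0.0, 500.0, 501)
        x0 = mb.iss_gate(-80.0, 1.0)[0]
        x = x_inf + (x0 - x_inf) * np.exp(-t / tau)
        i = np.array([mb.iss_current(xx, 30.0, -87.0, params["g_ss"], 1.0)
                      for xx in x])
        assert np.all(np.diff(i) >= -1e-12)
        assert tau > 20.0  # activation is slow


class TestIK1:
    def test_zero_at_reversal(self, params):
        assert mb.ik1_current(-87.0, -87.0, 5.4, params["g_K1"]) == 0.0

    def test_reverses_sign_across_ek(self, params):
        below = mb.ik1_current(-100.0, -87.0, 5.4, params["g_K1"])
        above = mb.ik1_current(-60.0, -87.0, 5.4, params["g_K1"])
        assert below < 0.0 < above

    def test_strong_inward_rectification(self, params):
        """|I| at -150 exceeds |I| at -40 under fixed concentrations."""
        i_neg = mb.ik1_current(-150.0, -87.0, 5.4, params["g_K1"])
        i_dep = mb.ik1_current(-40.0, -87.0, 5.4, params["g_K1"])
        assert abs(i_neg) > abs(i_dep)

    def test_normalisation_anchor(self, params):
        """Normalising the I-V at -100 mV maps that point to one."""
        volts = np.arange(-150.0, -39.0, 10.0)
        iv = np.array([mb.ik1_current(v, -87.0, 5.4, params["g_K1"])
                       for v in volts])
        norm = iv / iv[volts.tolist().index(-100.0)]
        assert norm[volts.tolist().index(-100.0)] == 1.0


class TestIKb:
    def test_zero_at_reversal(self, params):
        assert mb.ikb_current(-87.0, -87.0, params["g_Kb"]) == 0.0

    def test_monotone_iv(self, params):
        volts = np.linspace(-120.0, 60.0, 181)
        iv = [mb.ikb_current(v, -87.0, params["g_Kb"]) for v in volts]
        assert np.all(np.diff(iv) > -1e-12)

    def test_saturating_conductance_at_depolarised_potentials(self, params):
        g60 = mb.ikb_current(60.0, -87.0, params["g_Kb"]) / (60.0 + 87.0)
        g50 = mb.ikb_current(50.0, -87.0, params["g_Kb"]) / (50.0 + 87.0)
        assert g60 == pytest.approx(g50, rel=0.05)


class TestPumpsExchangers:
    def test_inak_vanishes_without_internal_sodium(self, params):
        frt = f_over_rt(37.0)
        i = mb.inak_current(-80.0, 1e-6, 5.4, 140.0, params.I_NaK_max,
                            11.0, 1.5, frt)
        assert i == pytest.approx(0.0, abs=1e-12)

    def test_inak_monotone_in_sodium(self, params):
        frt = f_over_rt(37.0)
        vals = [mb.inak_current(-80.0, na, 5.4, 140.0, params.I_NaK_max,
                                11.0, 1.5, frt) for na in (5.0, 10.0, 20.0)]
        assert vals[0] < vals[1] < vals[2]

    def test_ncx_reverses_sign_across_its_reversal(self, params):
        frt = f_over_rt(37.0)
        args = (10.8, 1e-4, 140.0, 1.8, params["k_NCX"], 0.35, 0.27,
                params["Kd_act_NCX"], frt)
        i_neg = mb.incx_current(-80.0, *args)
        i_pos = mb.incx_current(60.0, *args)
        assert i_neg < 0.0 < i_pos

    def test_pmca_saturates(self, params):
        lo = mb.ipmca_current(1e-4, params["I_PMCA_max"], params["Km_PMCA"])
        hi = mb.ipmca_current(1.0, params["I_PMCA_max"], params["Km_PMCA"])
        assert 0.0 < lo < hi <= params["I_PMCA_max"]


def test_inal_conductance_is_parent_times_1_68(params):
    assert params.g_NaL == pytest.approx(
        params["g_NaL_parent"] * 1.68, rel=1e-12)


def test_inak_max_is_parent_times_0_6(params):
    assert params.I_NaK_max == pytest.approx(
        params["I_NaK_max_parent"] * 0.6, rel=1e-12)


def test_kach_closed_without_acetylcholine(params):
    assert mb.ikach_current(-50.0, -87.0, 0.0, params["g_KACh"]) == 0.0


def test_chloride_currents_zero_at_reversal(params):
    e_cl = mb.nernst(-1, 8.0, 150.0, 37.0)
    assert mb.iclca_current(e_cl, e_cl, 1e-3, params["g_ClCa"], 0.01) == 0.0
    assert mb.iclb_current(e_cl, e_cl, params["g_Clb"]) == 0.0
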