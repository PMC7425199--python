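"""Protocol engine: drug registry, clamps, caffeine, S1S2, ion clamp."""

import numpy as np
import pytest

from mouseatria import core, protocols
from mouseatria.analysis import ap_features, iv_summary
from mouseatria.protocols import (ProtocolSpec, caffeine_transient,
                                  clamp_ion, drug_to_block,
                                  recovery_from_inactivation,
                                  run_channel_clamp,
                                  steady_state_inactivation)


class TestDrugRegistry:
    @pytest.mark.parametrize("drug,dose,expected", [
        ("4-AP", "50uM", {"Ito": 0.16, "IKur": 0.70}),
        ("4-AP", "100uM", {"Ito": 0.30, "IKur": 1.00}),
        ("E-4031", "5uM", {"IKr": 1.00}),
        ("TEA", "5mM", {"Iss": 0.55, "IKur": 0.00}),
    ])
    def test_registered_mappings_exact(self, drug, dose, expected):
        assert drug_to_block(drug, dose).block == expected

    def test_unregistered_dose_rejected_with_supported_list(self):
        with pytest.raises(KeyError, match="supported"):
            drug_to_block("4-AP", "1mM")

    def test_micro_sign_dose_normalised(self):
        assert drug_to_block("4-AP", "100μM").block["IKur"] == 1.0

    def test_block_applies_to_parameters(self, params):
        blocked = drug_to_block("E-4031", "5uM").apply(params)
        assert blocked.keep("IKr") == 0.0
        assert params.keep("IKr") == 1.0  # original untouched


class TestProtocolSpec:
    def test_json_round_trip(self):
        spec = ProtocolSpec(kind="vclamp", holding=-75.0,
                            levels=(-70, 0, 50), step_duration=500.0)
        back = ProtocolSpec.from_json(spec.to_json())
        assert back == spec

    def test_empty_step_family_rejected(self):
        with pytest.raises(ValueError):
            ProtocolSpec(kind="vclamp", levels=())

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ProtocolSpec(kind="zap")


class TestChannelClamp:
    def test_zero_conductance_family_is_all_zero(self, params):
        p0 = params.with_block({"Ito": 1.0})
        steps = run_channel_clamp("Ito", ProtocolSpec(
            kind="vclamp", holding=-75.0, levels=(-30.0, 30.0),
            step_duration=100.0), p0)
        assert all(s.peak == 0.0 for s in steps)

    def test_recovery_fraction_monotone_and_complete(self, params):
        _, frac = recovery_from_inactivation(
            "Ito", params, (20.0, 50.0, 100.0, 300.0, 1500.0))
        assert np.all(np.diff(frac) > -1e-9)
        assert frac[-1] == pytest.approx(1.0, abs=0.02)

    def test_ss_inactivation_is_monotone_sigmoid(self, params):
        lv, avail = steady_state_inactivation(
            "Ito", params, tuple(range(-90, 1, 10)))
        assert avail[0] == pytest.approx(1.0, abs=0.01)
        assert avail[-1] < 0.3
        # monotone non-increasing within a small numerical slack
        assert np.all(np.diff(avail) < 1e-3)

    def test_ikr_tail_nonnegative_and_saturating(self, params):
        steps = run_channel_clamp("IKr", ProtocolSpec(
            kind="vclamp", holding=-40.0,
            levels=tuple(range(-40, 41, 10)), step_duration=1000.0,
            tail_level=-40.0, tail_duration=500.0), params)
        volts, tails = iv_summary(steps, mode="tail")
        assert np.all(tails >= 0.0)
        assert tails[-1] == pytest.approx(tails[-2], rel=0.02)


class TestCaffeine:
    @pytest.fixture(scope="class")
    def dump(self, params, steady_05hz):
        return caffeine_transient(steady_05hz, params, duration=6000.0)

    def test_sr_nonincreasing_with_serca_blocked(self, dump):
        assert np.all(np.diff(dump.concentrations["Ca_SR"]) <= 1e-12)

    def test_caffeine_peak_exceeds_twitch_peak(self, params, steady_05hz,
                                               beat_05hz, dump):
        assert (dump.concentrations["Ca_i"].max()
                > beat_05hz.concentrations["Ca_i"].max())

    def test_fractional_release_in_unit_interval(self, beat_05hz, dump):
        dia = beat_05hz.concentrations["Ca_i"][0]
        twitch = beat_05hz.concentrations["Ca_i"].max() - dia
        total = dump.concentrations["Ca_i"].max() - dia
        assert 0.0 < twitch / total < 1.0


class TestS1S2:
    @pytest.fixture(scope="class")
    def curve(self, params, steady_2hz):
        return protocols.s1s2_restitution(
            params, s1_cl=130.0, s2_list=(80.0, 130.0, 400.0, 1200.0),
            s1_count=12, state0=steady_2hz)

    def test_apd30_shortens_at_short_coupling(self, curve):
        apd = dict(curve)
        assert apd[80.0] < apd[1200.0]

    def test_plateau_at_long_intervals(self, curve):
        apd = dict(curve)
        assert apd[1200.0] == pytest.approx(apd[400.0], rel=0.25)

    def test_all_test_beats_captured_here(self, curve):
        assert all(np.isfinite(a) for _, a in curve)


class TestIonClamp:
    def test_species_validated(self):
        with pytest.raises(ValueError):
            clamp_ion("Mg_i", 1.0)

    def test_clamped_species_is_frozen(self, params, warm_state):
        proto = clamp_ion("K_i", 140.0)
        y = warm_state.y.copy()
        y[core.IKI] = 140.0
        segs, runtime = protocols.expand_segments(
            ProtocolSpec(kind="ion_clamp", clamp_species="K_i", cl=200.0),
            params, 400.0)
        t, ymat, final, _ = core.integrate_segments(
            y, params, segs, runtime_base=runtime)
        assert np.allclose(ymat[core.IKI], 140.0, atol=1e-9)
        assert proto.clamp_value == 140.0

    def test_clamp_at_free_running_value_changes_nothing(self, params,
                                                         warm_state):
        """Clamping a species at its current value leaves one beat
        unchanged to solver tolerance."""
        free = core.pace_beats(warm_state, params, 500.0, 1, record=False)
        clamped = core.pace_beats(warm_state, params, 500.0, 1,
                                  record=False,
                                  runtime_base={"clamp": ("K_i",)})
        assert np.abs(free.V - clamped.V).max() < 0.2


class TestDeterminism:
    def test_identical_runs_are_bitwise_identical(self, params, warm_state):
        a = core.pace_beats(warm_state, params, 500.0, 1)
        b = core.pace_beats(warm_state, params, 500.0, 1)
        assert np.array_equal(a.V, b.V)
        for name in a.currents:
            assert np.array_equal(a.currents[name], b.currents[name])
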