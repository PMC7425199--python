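"""Whole-cell assembly: derivatives, integration, pacing, state handling."""

import json

import numpy as np
import pytest

from mouseatria import ModelParameters, core
from mouseatria.analysis import ap_features


class TestDerivatives:
    def test_fully_blocked_cell_with_stimulus_gives_10_mV_per_ms(
            self, warm_state):
        """C dV/dt = -(sum I); with every current blocked and a -10 pA/pF
        stimulus the membrane charges at exactly +10 mV/ms."""
        p = ModelParameters.default()
        p = p.with_block({name: 1.0 for name in
                          ("INa", "INaL", "ICaL", "Ito", "IKur", "IKr",
                           "Iss", "IK1", "IKb", "IKACh", "IKCa", "IClCa",
                           "INaK", "INCX", "IPMCA", "ICab", "INab",
                           "IClb")})
        dy = core.derivatives(warm_state, p, stim=-10.0)
        assert dy[core.IV] == pytest.approx(10.0, abs=1e-9)

    def test_occupancy_derivative_blocks_sum_to_zero(self, params,
                                                     warm_state):
        """Probability conservation: each Markov block's derivatives sum
        to zero for any state."""
        rng = np.random.default_rng(7)
        y = warm_state.y.copy()
        y[core.IV] = -20.0
        for sl in core.OCC_SLICES.values():
            occ = rng.random(sl.stop - sl.start)
            y[sl] = occ / occ.sum()
        dy = core.derivatives(core.ModelState(y), params, stim=0.0)
        for sl in core.OCC_SLICES.values():
            assert abs(dy[sl].sum()) < 1e-12

    def test_stimulus_is_booked_as_potassium(self, params, warm_state):
        dy0 = core.derivatives(warm_state, params, stim=0.0)
        dy1 = core.derivatives(warm_state, params, stim=-10.0)
        # K+ influx from the stimulus raises dK_i/dt; Na and Cl untouched
        assert dy1[core.IKI] > dy0[core.IKI]
        assert dy1[core.INAI] == pytest.approx(dy0[core.INAI], rel=1e-12)
        assert dy1[core.ICLI] == pytest.approx(dy0[core.ICLI], rel=1e-12)

    def test_nonfinite_component_is_named(self, params, warm_state):
        y = warm_state.y.copy()
        y[core.IV] = 1e9  # absurd voltage overflows a rate
        with pytest.raises((FloatingPointError, ValueError)):
            core.derivatives(core.ModelState(y), params, t=0.0,
                             stim=float("nan"))

    def test_species_resolved_currents_reproduce_total(self, beat_05hz):
        """Bookkeeping identity: K+, Na+, Cl- and Ca2+ resolved currents
        sum to the total ionic current used in dV/dt."""
        c = beat_05hz.currents
        i_k = (c["Ito"] + c["IKur"] + c["IKr"] + c["Iss"] + c["IK1"]
               + c["IKb"] + c["IKACh"] + c["IKCa"] - 2.0 * c["INaK"])
        i_na = (c["INa"] + c["INaL"] + c["INab"] + 3.0 * c["INaK"]
                + 3.0 * c["INCX"])
        i_cl = c["IClCa"] + c["IClb"]
        i_ca = c["ICaL"] + c["ICab"] + c["IPMCA"] - 2.0 * c["INCX"]
        total = sum(c[n] for n in c if n != "Istim")
        assert np.allclose(i_k + i_na + i_cl + i_ca, total, atol=1e-10)


class TestIntegration:
    def test_time_grid_strictly_increasing_and_aligned(self, beat_05hz):
        assert np.all(np.diff(beat_05hz.t) > 0)
        for trace in beat_05hz.currents.values():
            assert trace.shape == beat_05hz.t.shape

    def test_occupancy_conservation_along_the_trajectory(self, beat_05hz):
        for sl in core.OCC_SLICES.values():
            sums = beat_05hz.states[sl].sum(axis=0)
            assert np.abs(sums - 1.0).max() < 1e-6

    def test_solver_tolerance_convergence(self, params, steady_05hz):
        """Halving rtol/atol changes APD_90 of a beat by < 0.1 ms."""
        feats = {}
        for rtol in (1e-6, 5e-7):
            res = core.pace_beats(steady_05hz, params, 1000.0, 1,
                                  rtol=rtol, record=False)
            feats[rtol] = ap_features(res, require_beat=False).APD_90
        assert abs(feats[1e-6] - feats[5e-7]) < 0.1

    def test_output_grid_independence(self, params, steady_05hz):
        """0.1 vs 0.05 ms sampling: AP features within 0.05 ms / 0.1 mV."""
        a = ap_features(core.pace_beats(steady_05hz, params, 1000.0, 1,
                                        grid=0.1, record=False),
                        require_beat=False)
        b = ap_features(core.pace_beats(steady_05hz, params, 1000.0, 1,
                                        grid=0.05, record=False),
                        require_beat=False)
        assert abs(a.APD_90 - b.APD_90) < 0.05
        assert abs(a.APD_50 - b.APD_50) < 0.05
        assert abs(a.RMP - b.RMP) < 0.1
        assert abs(a.OS - b.OS) < 0.1

    def test_invalid_span_and_tolerances_rejected(self, params, warm_state):
        with pytest.raises(ValueError):
            core.integrate(warm_state, params, None, -1.0)
        with pytest.raises(ValueError):
            core.integrate(warm_state, params, None, 10.0, rtol=-1e-6)


class TestPacing:
    def test_pace_to_steady_state_converges_and_flags(self, params):
        state, info = core.pace_to_steady_state(params, 1000.0,
                                                max_beats=40)
        assert info["converged"]
        assert info["beats"] <= 40
        state.check_invariants()

    def test_nonconvergence_is_flagged_not_raised(self, params):
        _, info = core.pace_to_steady_state(params, 1000.0, max_beats=2,
                                            tol=1e-12)
        assert info["converged"] is False

    def test_cycle_length_floor_enforced(self, params):
        with pytest.raises(ValueError):
            core.pace_to_steady_state(params, 50.0)

    def test_beat_returns_to_rest_before_next_stimulus(self, params,
                                                       warm_state):
        """1-Hz pacing: V comes back within 1 mV of the pre-stimulus
        resting potential before the next beat."""
        res = core.pace_beats(warm_state, params, 1000.0, 2, record=False)
        v0 = res.V[0]
        k = np.searchsorted(res.t, 1000.0) - 1
        assert abs(res.V[k] - v0) < 1.0


class TestModelState:
    def test_json_round_trip_is_identity(self, warm_state, tmp_path):
        path = tmp_path / "state.json"
        warm_state.to_json(path)
        back = core.ModelState.from_json(str(path))
        assert np.array_equal(back.y, warm_state.y)

    def test_invariant_checker_rejects_bad_occupancy(self, warm_state):
        bad = warm_state.copy()
        bad.y[core.SL_ICAL] = 0.5
        with pytest.raises(ValueError, match="ICaL"):
            bad.check_invariants()

    def test_invariant_checker_rejects_nonpositive_concentration(
            self, warm_state):
        bad = warm_state.copy()
        bad.y[core.ICAI] = -1e-5
        with pytest.raises(ValueError, match="Ca_i"):
            bad.check_invariants()

    def test_renormalize_restores_conservation(self, warm_state):
        drifted = warm_state.copy()
        drifted.y[core.SL_RYR] *= 1.0 + 1e-6
        drifted.renormalize()
        drifted.check_invariants()

    def test_snapshot_carries_model_digest(self, params, warm_state):
        doc = json.loads(warm_state.to_json(model_digest=params.digest()))
        assert doc["format"].startswith("mouseatria-state")
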