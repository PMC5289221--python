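import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tlgate as tg
from tlgate.model import CellState, DnaState


class TestTetramerPropensity:
    @pytest.mark.parametrize("n, kflip, kd, expected", [
        (0, 0.4, 10.0, 0.0),
        (3, 0.4, 10.0, 0.0),                       # no tetramer below 4
        (4, 0.4, 10.0, 0.4 * 24 / 15464),          # hand evaluation
        (10, 0.4, 10.0, 0.4 * 5040 / 41240),       # hand evaluation
    ])
    def test_reference_values(self, n, kflip, kd, expected):
        assert tg.tetramer_propensity(n, kflip, kd) == pytest.approx(expected)

    def test_saturates_at_kflip(self):
        assert tg.tetramer_propensity(10**6, 0.4, 10.0) == pytest.approx(
            0.4, rel=1e-4)

    @pytest.mark.parametrize("bad", [-1, 2.5, True])
    def test_rejects_non_count(self, bad):
        with pytest.raises(ValueError):
            tg.tetramer_propensity(bad, 0.4, 10.0)

    def test_rejects_bad_kd(self):
        with pytest.raises(ValueError):
            tg.tetramer_propensity(5, 0.4, 0.0)

    @given(n=st.integers(min_value=0, max_value=5000),
           kd=st.floats(min_value=0.5, max_value=500),
           kflip=st.floats(min_value=0.0, max_value=10))
    @settings(max_examples=200, derandomize=True)
    def test_bounded_and_monotone(self, n, kd, kflip):
        a = tg.tetramer_propensity(n, kflip, kd)
        assert 0.0 <= a < kflip or (kflip == 0 and a == 0)
        assert tg.tetramer_propensity(n + 1, kflip, kd) >= a
        if n >= 4 and kflip > 0:
            assert a > 0.0


class TestRateParams:
    def test_initial_preset(self):
        p = tg.RateParams.preset("initial")
        assert (p.kprodA, p.kprodB, p.kdeg) == (50.0, 50.0, 0.3)
        assert p.kflipA == p.kflipB == p.kflipB_exc == 0.4
        assert p.kleakA == p.kleakB == 0.0
        assert p.KdA == p.KdB == 10.0

    def test_revised_preset(self):
        p = tg.RateParams.preset("revised")
        assert (p.kflipA, p.kflipB) == (0.2, 0.3)
        assert p.kleakA == pytest.approx(0.01 * p.kprodA)
        assert p.kleakB == pytest.approx(0.02 * p.kprodB)

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="initial"):
            tg.RateParams.preset("bogus")

    def test_excision_rate_defaults_to_kflipB(self):
        p = tg.RateParams(kflipB=0.25)
        assert p.kflipB_exc == 0.25
        slow = p.replace(kflipB_exc=0.1)  # the alpha1 < alpha2 = alpha3 variant
        assert slow.kflipB_exc == 0.1 and slow.kflipB == 0.25

    def test_replace_recouples_excision(self):
        p = tg.RateParams.preset("initial").replace(kflipB=0.3)
        assert p.kflipB_exc == 0.3

    def test_validation(self):
        with pytest.raises(ValueError):
            tg.RateParams(kdeg=-0.1)
        with pytest.raises(ValueError):
            tg.RateParams(KdA=0.0)

    def test_json_yaml_roundtrip(self):
        p = tg.RateParams.preset("revised")
        assert tg.RateParams.from_json(p.to_json()) == p
        assert tg.RateParams.from_yaml(p.to_yaml()) == p
        flat = json.loads(p.to_json())
        assert set(flat) == {"kprodA", "kprodB", "kleakA", "kleakB", "kdeg",
                             "kflipA", "kflipB", "kflipB_exc", "KdA", "KdB"}

    def test_from_dict_rejects_unknown_keys(self):
        with pytest.raises(ValueError, match="unknown"):
            tg.RateParams.from_dict({"kprodA": 50, "bogus": 1})


class TestInductionProfile:
    def test_step_pair(self):
        prof = tg.InductionProfile.step_pair(3.0)
        assert prof.u_a(0.0) == 1.0 and prof.u_b(0.0) == 0.0
        assert prof.u_b(2.999) == 0.0 and prof.u_b(3.0) == 1.0
        ba = tg.InductionProfile.step_pair(3.0, order="ba")
        assert ba.u_b(0.0) == 1.0 and ba.u_a(1.0) == 0.0

    def test_pulse_b(self):
        prof = tg.InductionProfile.pulse_b(2.0, 1.5)
        assert prof.u_a(100.0) == 1.0
        assert prof.u_b(1.9) == 0.0
        assert prof.u_b(2.0) == 1.0
        assert prof.u_b(3.5) == 0.0  # half-open [2, 3.5)
        empty = tg.InductionProfile.pulse_b(2.0, 0.0)
        assert empty.intervals_b == ()

    def test_invalid_intervals(self):
        with pytest.raises(ValueError):
            tg.InductionProfile(intervals_a=((1.0, 1.0),))
        with pytest.raises(ValueError):
            tg.InductionProfile(intervals_a=((0.0, 2.0), (1.0, 3.0)))
        with pytest.raises(ValueError):
            tg.InductionProfile.step_pair(-1.0)

    def test_segments_cover_horizon(self):
        prof = tg.InductionProfile.pulse_b(2.0, 1.5)
        seg_ends, ua, ub = prof.segments(10.0)
        assert seg_ends[-1] == 10.0
        assert np.all(np.diff(seg_ends) > 0)
        assert list(ub) == [0.0, 1.0, 0.0]
        assert list(ua) == [1.0, 1.0, 1.0]

    def test_breakpoints_sorted_finite(self):
        prof = tg.InductionProfile.pulse_b(2.0, 1.5)
        bk = prof.breakpoints(10.0)
        assert list(bk) == [2.0, 3.5]

    def test_serialization_roundtrip(self):
        for prof in (tg.InductionProfile.step_pair(2.5),
                     tg.InductionProfile.pulse_b(1.0, 0.5),
                     tg.InductionProfile.none()):
            assert tg.InductionProfile.from_json(prof.to_json()) == prof
            assert tg.InductionProfile.from_yaml(prof.to_yaml()) == prof


class TestTransitionRates:
    def test_absorbing_empty_cell(self, initial_params):
        prof = tg.InductionProfile.none()
        cell = CellState(DnaState.S_b, 0, 0)
        assert tg.transition_rates(cell, initial_params, prof, 1.0) == []

    def test_revised_both_on(self, revised_params):
        prof = tg.InductionProfile.step_pair(0.0)
        cell = CellState(DnaState.S_a, 5, 4)
        rates = {tuple(t): r for t, r in
                 tg.transition_rates(cell, revised_params, prof, 1.0)}
        assert rates[(DnaState.S_a, 6, 4)] == pytest.approx(50.5)
        assert rates[(DnaState.S_a, 5, 5)] == pytest.approx(51.0)
        assert rates[(DnaState.S_a, 4, 4)] == pytest.approx(1.5)
        assert rates[(DnaState.S_a, 5, 3)] == pytest.approx(1.2)
        assert rates[(DnaState.S_ab, 5, 4)] == pytest.approx(0.3 * 24 / 15464)
        assert len(rates) == 5

    def test_subtetramer_no_flip(self, initial_params):
        prof = tg.InductionProfile.step_pair(0.0, order="ba")
        cell = CellState(DnaState.S_o, 0, 3)
        targets = [t.dna for t, _ in
                   tg.transition_rates(cell, initial_params, prof, 1.0)]
        assert DnaState.S_b not in targets and DnaState.S_a not in targets

    def test_no_exit_from_absorbing_states(self, revised_params):
        prof = tg.InductionProfile.step_pair(0.0)
        for dna in (DnaState.S_b, DnaState.S_ab):
            for t, _ in tg.transition_rates(CellState(dna, 20, 20),
                                            revised_params, prof, 5.0):
                assert t.dna == dna
                assert t.intA >= 0 and t.intB >= 0

    def test_excision_equals_conversion_by_default(self, initial_params):
        prof = tg.InductionProfile.step_pair(0.0)
        a1 = dict((t.dna, r) for t, r in tg.transition_rates(
            CellState(DnaState.S_o, 0, 8), initial_params, prof, 1.0)
        )[DnaState.S_b]
        a3 = dict((t.dna, r) for t, r in tg.transition_rates(
            CellState(DnaState.S_a, 0, 8), initial_params, prof, 1.0)
        )[DnaState.S_ab]
        assert a1 == pytest.approx(a3)
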