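import math

import numpy as np
import pytest
from scipy import stats

import tlgate as tg
from tlgate.model import DnaState


class TestSimulateCell:
    def test_null_process(self):
        p = tg.RateParams(kprodA=0, kprodB=0, kleakA=0, kleakB=0, kdeg=0,
                          kflipA=0, kflipB=0)
        tr = tg.simulate_cell(p, tg.InductionProfile.step_pair(0.0), 10.0,
                              seed=1)
        assert tr.events == []
        assert tr.final_state == tg.CellState(DnaState.S_o, 0, 0)

    def test_determinism(self, initial_params):
        prof = tg.InductionProfile.pulse_b(1.0, 2.0)
        a = tg.simulate_cell(initial_params, prof, 8.0, seed=42)
        b = tg.simulate_cell(initial_params, prof, 8.0, seed=42)
        assert a.events == b.events
        c = tg.simulate_cell(initial_params, prof, 8.0, seed=43)
        assert c.events != a.events

    def test_birth_death_stationary_mean(self):
        # flips off: IntA is a birth-death chain, mean kprodA/kdeg = 166.7
        p = tg.RateParams(kflipA=0, kflipB=0)
        tr = tg.simulate_cell(p, tg.InductionProfile.a_only(), 400.0, seed=3)
        ts = [0.0] + [t for t, _ in tr.events] + [400.0]
        states = [tr.initial_state] + [s for _, s in tr.events]
        t0, acc = 100.0, 0.0
        for i, s in enumerate(states):
            lo, hi = max(ts[i], t0), ts[i + 1]
            if hi > lo:
                acc += s.intA * (hi - lo)
        mean = acc / (400.0 - t0)
        assert mean == pytest.approx(50.0 / 0.3, rel=0.05)
        assert all(s.dna == DnaState.S_o for _, s in tr.events)

    def test_event_guard(self, initial_params):
        with pytest.raises(RuntimeError, match="guard"):
            tg.simulate_cell(initial_params,
                             tg.InductionProfile.step_pair(0.0), 30.0,
                             seed=0, max_events=50)

    def test_trajectory_invariants(self, initial_params):
        prof = tg.InductionProfile.step_pair(2.0)
        tr = tg.simulate_cell(initial_params, prof, 30.0, seed=7)
        times = tr.times
        assert np.all(np.diff(times) > 0) and times[-1] <= 30.0
        # DNA path respects the transition graph and visits states once
        allowed = {DnaState.S_o: {DnaState.S_a, DnaState.S_b},
                   DnaState.S_a: {DnaState.S_ab}}
        dna_path = [tr.initial_state.dna]
        for _, s in tr.events:
            if s.dna != dna_path[-1]:
                assert s.dna in allowed.get(dna_path[-1], set())
                dna_path.append(s.dna)
        assert len(dna_path) == len(set(dna_path))

    def test_exponential_waiting_times(self):
        # frozen state: no degradation/flips, a on -> pure birth at rate 50;
        # inter-event times must be Exp(50)
        p = tg.RateParams(kdeg=0, kflipA=0, kflipB=0)
        tr = tg.simulate_cell(p, tg.InductionProfile.a_only(), 20.0, seed=11)
        waits = np.diff([0.0] + [t for t, _ in tr.events])
        assert len(waits) > 500
        ks = stats.kstest(waits, "expon", args=(0, 1 / 50.0))
        assert ks.pvalue > 0.01


class TestSimulatePopulation:
    def test_single_cell_population(self, initial_params):
        prof = tg.InductionProfile.step_pair(0.0)
        ens = tg.simulate_population(initial_params, prof, t_end=5.0,
                                     n_cells=1, seed=0)
        assert ens.n_cells == 1
        assert len(ens.trajectories) == 1

    def test_determinism_and_seed_sensitivity(self, initial_params):
        prof = tg.InductionProfile.step_pair(1.0)
        a = tg.simulate_population(initial_params, prof, t_end=10.0,
                                   n_cells=200, seed=1)
        b = tg.simulate_population(initial_params, prof, t_end=10.0,
                                   n_cells=200, seed=1)
        assert np.array_equal(a.finals, b.finals)
        assert np.array_equal(a.flip_times, b.flip_times, equal_nan=True)
        c = tg.simulate_population(initial_params, prof, t_end=10.0,
                                   n_cells=200, seed=2)
        assert not np.array_equal(a.finals, c.finals)

    def test_conservation_and_absorption(self, initial_params):
        prof = tg.InductionProfile.step_pair(2.0)
        grid = np.linspace(0, 26, 53)
        ens = tg.simulate_population(initial_params, prof, t_end=26.0,
                                     n_cells=2000, seed=3, grid=grid)
        dna = ens.dna_at(grid)
        fr = np.stack([(dna == s).mean(axis=0) for s in range(4)], axis=1)
        assert np.allclose(fr.sum(axis=1), 1.0)
        # S_o fraction is non-increasing; absorbing fractions non-decreasing
        assert np.all(np.diff(fr[:, 0]) <= 1e-12)
        assert np.all(np.diff(fr[:, 2]) >= -1e-12)
        assert np.all(np.diff(fr[:, 3]) >= -1e-12)

    def test_breakpoint_split_equivalence(self, initial_params):
        """Splitting a constant-rate interval at an artificial breakpoint
        must not change the sampled distribution (resampling exactness)."""
        whole = tg.InductionProfile(intervals_a=((0.0, math.inf),),
                                    intervals_b=((0.0, math.inf),))
        split = tg.InductionProfile(intervals_a=((0.0, 5.0), (5.0, math.inf)),
                                    intervals_b=((0.0, math.inf),))
        e1 = tg.simulate_population(initial_params, whole, t_end=12.0,
                                    n_cells=4000, seed=9)
        e2 = tg.simulate_population(initial_params, split, t_end=12.0,
                                    n_cells=4000, seed=10)
        f1, f2 = e1.final_fractions(), e2.final_fractions()
        se = np.sqrt(f1 * (1 - f1) / 4000 + f2 * (1 - f2) / 4000)
        assert np.all(np.abs(f1 - f2) <= 3 * np.maximum(se, 1e-4))

    def test_default_horizons(self):
        assert tg.default_t_end(tg.InductionProfile.step_pair(3.0)) == 30.0
        assert tg.default_t_end(tg.InductionProfile.pulse_b(2.0, 1.5)) == 27.5

    def test_grid_validation(self, initial_params):
        prof = tg.InductionProfile.step_pair(0.0)
        with pytest.raises(ValueError):
            tg.simulate_population(initial_params, prof, t_end=5.0,
                                   n_cells=10, seed=0, grid=[0.0, 6.0])
        with pytest.raises(ValueError):
            tg.simulate_population(initial_params, prof, t_end=5.0,
                                   n_cells=0, seed=0)

    def test_event_guard_names_cell(self, initial_params):
        with pytest.raises(RuntimeError, match="cell"):
            tg.simulate_population(initial_params,
                                   tg.InductionProfile.step_pair(0.0),
                                   t_end=30.0, n_cells=3, seed=0,
                                   max_events=50)
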