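"""Exact stochastic simulation of gate trajectories and cell ensembles.

Sample paths of the continuous-time Markov chain are generated with the
Gillespie direct method.  Induction profiles make the propensities
piecewise-constant in time; within each inter-breakpoint segment the rates
are constant, and a waiting time that would overshoot the next breakpoint is
discarded and resampled from the breakpoint, which is exact by
memorylessness of the exponential distribution.

Two implementations share the same reaction system:

* :func:`simulate_cell` is a plain-Python reference sampler that records the
  full event list of a single cell (every birth, death and flip).
* :func:`simulate_population` runs a numba-compiled kernel over many cells,
  recording per-cell DNA-flip events, integrase counts on a user grid, and
  final states.  This is the engine behind all population-scale analyses.

Both start from ``(S_o, 0, 0)`` and are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
from numba import njit

from .model import (CellState, DnaState, InductionProfile, RateParams,
                    transition_rates)

__all__ = [
    "Trajectory",
    "Ensemble",
    "simulate_cell",
    "simulate_population",
    "default_t_end",
]

MAX_EVENTS_DEFAULT = 10_000_000

# Parameter vector layout shared with the numba kernel.
_P_FIELDS = ("kprodA", "kprodB", "kleakA", "kleakB", "kdeg",
             "kflipA", "kflipB", "kflipB_exc", "KdA", "KdB")


def _params_vector(params: RateParams) -> np.ndarray:
    return np.array([getattr(params, f) for f in _P_FIELDS], dtype=np.float64)


@njit(cache=True)
def _alpha(n, kflip, kd):
    if n < 4:
        return 0.0
    x = float(n)
    p1 = x
    p2 = x * (x - 1.0)
    p3 = p2 * (x - 2.0)
    p4 = p3 * (x - 3.0)
    return kflip * p4 / (kd**4 + kd**3 * p1 + kd**2 * p2 + kd * p3 + p4)


@njit(cache=True)
def _sim_one(seed, seg_ends, ua, ub, p, grid, dna_row, a_row, b_row,
             flip_t, flip_d, flip_a, flip_b, max_events):
    """Simulate one cell; fill grid rows and flip records in place.

    Returns (status, n_flips, dna, a, b); status 0 = ok, 1 = event guard hit.
    """
    np.random.seed(seed)
    kprodA, kprodB, kleakA, kleakB, kdeg = p[0], p[1], p[2], p[3], p[4]
    kflipA, kflipB, kflipB_exc, kdA, kdB = p[5], p[6], p[7], p[8], p[9]

    t = 0.0
    dna = 0
    a = 0
    b = 0
    seg = 0
    nseg = seg_ends.size
    gi = 0
    ng = grid.size
    nflips = 0
    nev = 0

    while seg < nseg:
        gA = kprodA * ua[seg] + kleakA
        gB = kprodB * ub[seg] + kleakB
        r_da = kdeg * a
        r_db = kdeg * b
        r2 = 0.0
        r1 = 0.0
        r3 = 0.0
        if dna == 0:
            r2 = _alpha(a, kflipA, kdA)
            r1 = _alpha(b, kflipB_exc, kdB)
        elif dna == 1:
            r3 = _alpha(b, kflipB, kdB)
        total = gA + gB + r_da + r_db + r1 + r2 + r3

        if total <= 0.0:
            t_new = seg_ends[seg]
        else:
            tau = -math.log(np.random.random()) / total
            t_new = t + tau

        if t_new >= seg_ends[seg]:
            # overshoot: advance to the breakpoint and resample there
            t_new = seg_ends[seg]
            while gi < ng and grid[gi] < t_new:
                dna_row[gi] = dna
                a_row[gi] = a
                b_row[gi] = b
                gi += 1
            t = t_new
            seg += 1
            continue

        # an event fires at t_new; grid points strictly before it see the
        # pre-event state (state at grid time g is the state after the last
        # event <= g)
        while gi < ng and grid[gi] < t_new:
            dna_row[gi] = dna
            a_row[gi] = a
            b_row[gi] = b
            gi += 1
        t = t_new
        nev += 1
        if nev > max_events:
            return 1, nflips, dna, a, b

        u = np.random.random() * total
        if u < gA:
            a += 1
        elif u < gA + gB:
            b += 1
        elif u < gA + gB + r_da:
            a -= 1
        elif u < gA + gB + r_da + r_db:
            b -= 1
        elif u < gA + gB + r_da + r_db + r2:
            dna = 1
            flip_t[nflips] = t
            flip_d[nflips] = 1
            flip_a[nflips] = a
            flip_b[nflips] = b
            nflips += 1
        elif u < gA + gB + r_da + r_db + r2 + r1:
            dna = 2
            flip_t[nflips] = t
            flip_d[nflips] = 2
            flip_a[nflips] = a
            flip_b[nflips] = b
            nflips += 1
        else:
            dna = 3
            flip_t[nflips] = t
            flip_d[nflips] = 3
            flip_a[nflips] = a
            flip_b[nflips] = b
            nflips += 1

    while gi < ng:
        dna_row[gi] = dna
        a_row[gi] = a
        b_row[gi] = b
        gi += 1
    return 0, nflips, dna, a, b


@njit(cache=True)
def _sim_population_kernel(seeds, seg_ends, ua, ub, p, grid, max_events):
    n = seeds.size
    ng = grid.size
    dna_grid = np.zeros((n, ng), dtype=np.int8)
    a_grid = np.zeros((n, ng), dtype=np.int32)
    b_grid = np.zeros((n, ng), dtype=np.int32)
    flip_t = np.full((n, 2), np.nan)
    flip_d = np.zeros((n, 2), dtype=np.int8)
    flip_a = np.zeros((n, 2), dtype=np.int32)
    flip_b = np.zeros((n, 2), dtype=np.int32)
    n_flips = np.zeros(n, dtype=np.int8)
    finals = np.zeros((n, 3), dtype=np.int64)
    bad = -1
    for i in range(n):
        status, nf, dna, a, b = _sim_one(
            seeds[i], seg_ends, ua, ub, p, grid,
            dna_grid[i], a_grid[i], b_grid[i],
            flip_t[i], flip_d[i], flip_a[i], flip_b[i], max_events)
        if status != 0:
            bad = i
            break
        n_flips[i] = nf
        finals[i, 0] = dna
        finals[i, 1] = a
        finals[i, 2] = b
    return (bad, dna_grid, a_grid, b_grid, flip_t, flip_d, flip_a, flip_b,
            n_flips, finals)


@dataclass
class Trajectory:
    """A single cell's sample path.

    ``events`` is the ordered list of ``(time, CellState after event)``
    pairs.  When ``full`` is False the trajectory records only DNA-flip
    events (with the integrase counts at the moment of the flip), which is
    all that population-fraction analyses need.
    """

    events: list
    t_end: float
    seed: int
    full: bool = True
    initial_state: CellState = CellState(DnaState.S_o, 0, 0)

    def __post_init__(self):
        times = [t for t, _ in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if times and times[-1] > self.t_end:
            raise ValueError("event beyond t_end")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.events])

    @property
    def final_state(self) -> CellState:
        return self.events[-1][1] if self.events else self.initial_state

    def state_at(self, t: float) -> CellState:
        """State after the last event at or before ``t``."""
        if not self.full:
            raise ValueError("state_at requires a fully recorded trajectory; "
                             "use dna_at for flip-only records")
        state = self.initial_state
        for et, s in self.events:
            if et > t:
                break
            state = s
        return state

    def dna_at(self, t: float) -> DnaState:
        dna = self.initial_state.dna
        for et, s in self.events:
            if et > t:
                break
            if s.dna != dna:
                dna = s.dna
        return DnaState(dna)


def default_t_end(profile: InductionProfile) -> float:
    """Default simulation horizon for a profile.

    Step events (all intervals open-ended) run to 30 h, the end-point
    measurement time used for step experiments; profiles containing a finite
    pulse run 24 h past the last finite interval endpoint, mirroring the
    post-pulse outgrowth.
    """
    finite_ends = [e for s, e in profile.intervals_a + profile.intervals_b
                   if math.isfinite(e)]
    if finite_ends:
        return max(finite_ends) + 24.0
    return 30.0


def simulate_cell(params: RateParams, profile: InductionProfile,
                  t_end: float, seed: int,
                  max_events: int = MAX_EVENTS_DEFAULT) -> Trajectory:
    """Exact sample path of one cell, recording every event.

    This is the reference (pure-Python) sampler; identical arguments yield
    an identical trajectory.  Raises ``RuntimeError`` if more than
    ``max_events`` events fire (runaway-rate guard).
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    rng = np.random.default_rng(seed)
    seg_ends, ua, ub = profile.segments(t_end)
    state = CellState(DnaState.S_o, 0, 0)
    t = 0.0
    events: list[tuple[float, CellState]] = []
    seg = 0
    nev = 0
    while seg < len(seg_ends):
        # freeze the profile inside the segment: evaluate at the segment start
        seg_start = 0.0 if seg == 0 else seg_ends[seg - 1]
        reactions = transition_rates(state, params, profile, seg_start)
        total = sum(r for _, r in reactions)
        if total <= 0:
            t = seg_ends[seg]
            seg += 1
            continue
        tau = -math.log(rng.random()) / total
        if t + tau >= seg_ends[seg]:
            t = seg_ends[seg]
            seg += 1
            continue
        t = t + tau
        nev += 1
        if nev > max_events:
            raise RuntimeError(
                f"event-count guard exceeded ({max_events} events) at t={t:.3g} h")
        u = rng.random() * total
        acc = 0.0
        for target, r in reactions:
            acc += r
            if u < acc:
                state = target
                break
        else:  # numerical edge: attribute to the last reaction
            state = reactions[-1][0]
        events.append((t, state))
    return Trajectory(events=events, t_end=float(t_end), seed=int(seed),
                      full=True)


@dataclass
class Ensemble:
    """A population of independent single-cell simulations.

    Stores, per cell, the DNA-flip events (time and target state, at most
    two per cell), the final ``(dna, intA, intB)``, and the DNA state and
    integrase counts sampled on ``grid``.
    """

    params: RateParams
    profile: InductionProfile
    t_end: float
    n_cells: int
    seed: int
    grid: np.ndarray
    dna_grid: np.ndarray  # (n_cells, len(grid)) int8
    a_grid: np.ndarray    # (n_cells, len(grid)) int32
    b_grid: np.ndarray
    flip_times: np.ndarray   # (n_cells, 2), NaN-padded
    flip_targets: np.ndarray  # (n_cells, 2) int8
    flip_counts_a: np.ndarray  # (n_cells, 2) IntA count at each flip
    flip_counts_b: np.ndarray
    n_flips: np.ndarray
    finals: np.ndarray       # (n_cells, 3) int64

    @property
    def final_dna(self) -> np.ndarray:
        return self.finals[:, 0]

    def final_fractions(self) -> np.ndarray:
        """Fractions of cells per DNA state at t_end, ordered as DnaState."""
        return np.bincount(self.final_dna, minlength=4) / self.n_cells

    def dna_at(self, times) -> np.ndarray:
        """DNA state (int codes) of every cell at each time; shape (n, nt)."""
        t = np.atleast_1d(np.asarray(times, dtype=float))[None, :]
        ft = np.where(np.isnan(self.flip_times), np.inf, self.flip_times)
        dna = np.zeros((self.n_cells, t.shape[1]), dtype=np.int8)
        for k in (0, 1):
            hit = t >= ft[:, k:k + 1]
            dna = np.where(hit, self.flip_targets[:, k:k + 1], dna)
        return dna

    @property
    def trajectories(self) -> list[Trajectory]:
        """Per-cell DNA-flip trajectories (lazily constructed)."""
        out = []
        for i in range(self.n_cells):
            events = []
            for k in range(int(self.n_flips[i])):
                events.append((float(self.flip_times[i, k]),
                               CellState(DnaState(int(self.flip_targets[i, k])),
                                         int(self.flip_counts_a[i, k]),
                                         int(self.flip_counts_b[i, k]))))
            out.append(Trajectory(events=events, t_end=self.t_end,
                                  seed=int(self.seed), full=False))
        return out


def _cell_seeds(seed: int, n_cells: int) -> np.ndarray:
    """Deterministic per-cell RNG seeds derived from (seed, cell index)."""
    state = np.random.SeedSequence(int(seed)).generate_state(n_cells)
    return state.astype(np.int64)


def simulate_population(params: RateParams, profile: InductionProfile,
                        t_end: float | None = None, n_cells: int = 5000,
                        seed: int = 0, grid=None,
                        max_events: int = MAX_EVENTS_DEFAULT) -> Ensemble:
    """Simulate ``n_cells`` independent trajectories (numba-compiled SSA).

    Parameters
    ----------
    t_end : float, optional
        Horizon in hours; defaults to :func:`default_t_end` of the profile.
    grid : array-like, optional
        Times at which to record per-cell DNA states and integrase counts;
        defaults to ``[t_end]`` only.  DNA fractions at arbitrary times can
        always be reconstructed from the stored flip events.
    """
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    if t_end is None:
        t_end = default_t_end(profile)
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    if grid is None:
        grid = np.array([float(t_end)])
    grid = np.asarray(grid, dtype=float)
    if grid.size and (grid.min() < 0 or grid.max() > t_end):
        raise ValueError("grid must lie within [0, t_end]")

    seg_ends, ua, ub = profile.segments(t_end)
    p = _params_vector(params)
    seeds = _cell_seeds(seed, n_cells)
    (bad, dna_grid, a_grid, b_grid, flip_t, flip_d, flip_a, flip_b,
     n_flips, finals) = _sim_population_kernel(seeds, seg_ends, ua, ub, p,
                                               grid, int(max_events))
    if bad >= 0:
        raise RuntimeError(
            f"event-count guard exceeded ({max_events} events) in cell {bad}")
    return Ensemble(params=params, profile=profile, t_end=float(t_end),
                    n_cells=int(n_cells), seed=int(seed), grid=grid,
                    dna_grid=dna_grid, a_grid=a_grid, b_grid=b_grid,
                    flip_times=flip_t, flip_targets=flip_d,
                    flip_counts_a=flip_a, flip_counts_b=flip_b,
                    n_flips=n_flips, finals=finals)
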