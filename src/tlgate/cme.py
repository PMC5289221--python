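"""Non-stochastic solutions of the gate model, used to validate the SSA.

Three independent routes are provided:

* :func:`solve_truncated_cme` integrates the chemical master equation on the
  truncated state space {S_o, S_a, S_b, S_ab} x {0..capA} x {0..capB}.
  Births at the copy-number cap are redirected into a single absorbing
  overflow bucket whose probability is reported as the truncation mass
  defect, so the returned DNA marginals are rigorous lower bounds.
* :func:`conditional_dna_solution` is the exact closed form of the linear
  4-state DNA chain when the flip propensities are frozen constants.
* :func:`verify_marginal_ode` checks an SSA ensemble against the
  population-level marginal ODE, in which the DNA-flip rates appear as
  conditional expectations of the propensities given the current DNA state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp
from scipy.sparse.linalg import expm_multiply

from .model import InductionProfile, RateParams
from .ssa import Ensemble

__all__ = [
    "MarginalTrajectory",
    "solve_truncated_cme",
    "conditional_dna_solution",
    "verify_marginal_ode",
    "ResidualReport",
]

MASS_DEFECT_THRESHOLD = 1e-3


@dataclass
class MarginalTrajectory:
    """DNA-state marginals on a time grid, with the truncation mass defect."""

    times: np.ndarray
    probs: np.ndarray        # (nt, 4): P(S_o), P(S_a), P(S_b), P(S_ab)
    mass_defect: np.ndarray  # (nt,)
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        total = self.probs.sum(axis=1) + self.mass_defect
        if np.any(self.probs < -1e-9) or np.any(np.abs(total - 1.0) > 1e-6):
            raise ValueError("marginal probabilities do not conserve mass")


def _alpha_vec(n: np.ndarray, kflip: float, kd: float) -> np.ndarray:
    x = n.astype(float)
    p1 = x
    p2 = x * (x - 1)
    p3 = p2 * (x - 2)
    p4 = p3 * (x - 3)
    out = kflip * p4 / (kd**4 + kd**3 * p1 + kd**2 * p2 + kd * p3 + p4)
    out[n < 4] = 0.0
    return out


def _build_generators(params: RateParams, capA: int, capB: int):
    """Sparse generator pieces: A = A_fixed + gammaA*A_bA + gammaB*A_bB.

    A[to, from] convention, columns summing to zero; the last index is the
    overflow bucket receiving births at either cap.
    """
    nA, nB = capA + 1, capB + 1
    nstates = 4 * nA * nB
    over = nstates  # overflow index
    dim = nstates + 1

    def idx(d, i, j):
        return (d * nA + i) * nB + j

    a_counts = np.arange(nA)
    b_counts = np.arange(nB)
    alpha2 = _alpha_vec(a_counts, params.kflipA, params.KdA)
    alpha1 = _alpha_vec(b_counts, params.kflipB_exc, params.KdB)
    alpha3 = _alpha_vec(b_counts, params.kflipB, params.KdB)

    rows_f, cols_f, vals_f = [], [], []

    def add(mat, to, frm, rate):
        rows, cols, vals = mat
        rows.append(to)
        cols.append(frm)
        vals.append(rate)
        rows.append(frm)
        cols.append(frm)
        vals.append(-rate)

    fixed = (rows_f, cols_f, vals_f)
    for d in range(4):
        for i in range(nA):
            for j in range(nB):
                s = idx(d, i, j)
                if i > 0:
                    add(fixed, idx(d, i - 1, j), s, params.kdeg * i)
                if j > 0:
                    add(fixed, idx(d, i, j - 1), s, params.kdeg * j)
                if d == 0:
                    if alpha2[i] > 0:
                        add(fixed, idx(1, i, j), s, alpha2[i])
                    if alpha1[j] > 0:
                        add(fixed, idx(2, i, j), s, alpha1[j])
                elif d == 1:
                    if alpha3[j] > 0:
                        add(fixed, idx(3, i, j), s, alpha3[j])

    rows_a, cols_a, vals_a = [], [], []
    birthA = (rows_a, cols_a, vals_a)
    for d in range(4):
        for i in range(nA):
            for j in range(nB):
                s = idx(d, i, j)
                to = idx(d, i + 1, j) if i < capA else over
                add(birthA, to, s, 1.0)

    rows_b, cols_b, vals_b = [], [], []
    birthB = (rows_b, cols_b, vals_b)
    for d in range(4):
        for i in range(nA):
            for j in range(nB):
                s = idx(d, i, j)
                to = idx(d, i, j + 1) if j < capB else over
                add(birthB, to, s, 1.0)

    def tocsr(mat):
        rows, cols, vals = mat
        return sp.csr_matrix((vals, (rows, cols)), shape=(dim, dim))

    return tocsr(fixed), tocsr(birthA), tocsr(birthB), dim, idx, over


def solve_truncated_cme(params: RateParams, profile: InductionProfile,
                        t_end: float, capA: int = 40, capB: int = 40,
                        grid=None,
                        defect_threshold: float = MASS_DEFECT_THRESHOLD,
                        init_counts: tuple = (0, 0)) -> MarginalTrajectory:
    """Forward-integrate the truncated master equation.

    The action of the (piecewise-constant-in-time) generator is propagated
    with Krylov matrix exponentials segment by segment, so there is no ODE
    tolerance to tune.  Caps of at least ~3x the stationary mean copy number
    keep the mass defect negligible; a defect above ``defect_threshold`` is
    recorded as a warning on the result.

    ``init_counts`` sets the initial integrase copy numbers (default (0, 0),
    the standard initial condition); with production and degradation zeroed
    this clamps the counts, which is useful for cross-checks against the
    frozen-propensity closed form.
    """
    if capA < 1 or capB < 1:
        raise ValueError("caps must be >= 1")
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if grid is None:
        grid = np.linspace(0.0, t_end, 121)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or grid.min() < 0 or grid.max() > t_end:
        raise ValueError("grid must be non-empty and within [0, t_end]")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")

    A_fixed, A_bA, A_bB, dim, idx, over = _build_generators(params, capA, capB)
    seg_ends, ua, ub = profile.segments(t_end)

    i0, j0 = int(init_counts[0]), int(init_counts[1])
    if not (0 <= i0 <= capA and 0 <= j0 <= capB):
        raise ValueError("init_counts must lie within the caps")
    v = np.zeros(dim)
    v[idx(0, i0, j0)] = 1.0

    nA, nB = capA + 1, capB + 1
    probs = np.zeros((grid.size, 4))
    defect = np.zeros(grid.size)

    def record(k, vec):
        block = vec[:4 * nA * nB].reshape(4, nA * nB)
        probs[k] = np.maximum(block.sum(axis=1), 0.0)
        defect[k] = max(vec[over], 0.0)

    t_cur = 0.0
    gi = 0
    if grid[0] == 0.0:
        record(0, v)
        gi = 1
    for seg in range(seg_ends.size):
        gA = params.kprodA * ua[seg] + params.kleakA
        gB = params.kprodB * ub[seg] + params.kleakB
        A = (A_fixed + gA * A_bA + gB * A_bB).tocsc()
        seg_end = seg_ends[seg]
        while gi < grid.size and grid[gi] <= seg_end + 1e-12:
            dt = grid[gi] - t_cur
            if dt > 0:
                v = expm_multiply(A * dt, v)
            record(gi, v)
            t_cur = grid[gi]
            gi += 1
        if seg_end > t_cur:
            v = expm_multiply(A * (seg_end - t_cur), v)
            t_cur = seg_end

    warnings = []
    if defect.max() > defect_threshold:
        warnings.append(
            f"truncation mass defect {defect.max():.3g} exceeds "
            f"{defect_threshold:g}; increase capA/capB")
    return MarginalTrajectory(times=grid, probs=probs, mass_defect=defect,
                              warnings=warnings)


def conditional_dna_solution(a1: float, a2: float, a3: float, t: float):
    """Exact DNA-chain marginals for frozen flip propensities.

    Solves the linear chain S_o -> S_a -> S_ab with the competing branch
    S_o -> S_b, at constant rates a2 (S_o->S_a), a1 (S_o->S_b) and
    a3 (S_a->S_ab), starting from S_o.  Returns (P_So, P_Sa, P_Sb, P_Sab).
    """
    if a1 < 0 or a2 < 0 or a3 < 0 or t < 0:
        raise ValueError("rates and t must be >= 0")
    lam = a1 + a2
    p_o = math.exp(-lam * t)
    if lam == 0.0:
        return (1.0, 0.0, 0.0, 0.0)
    p_b = a1 / lam * (1.0 - p_o)
    if abs(lam - a3) < 1e-12 * max(lam, a3, 1.0):
        p_a = a2 * t * math.exp(-a3 * t)
    else:
        p_a = a2 * (math.exp(-a3 * t) - math.exp(-lam * t)) / (lam - a3)
    p_ab = 1.0 - p_o - p_a - p_b
    # guard rounding at the boundary
    p_ab = min(max(p_ab, 0.0), 1.0)
    return (p_o, p_a, p_b, p_ab)


@dataclass
class ResidualReport:
    """Discrepancy between ensemble fractions and the marginal ODE."""

    times: np.ndarray
    empirical: np.ndarray   # (nt, 4)
    predicted: np.ndarray   # (nt, 4)
    max_residual: np.ndarray  # per-state max |empirical - predicted|
    tol: np.ndarray
    passed: bool
    notes: list = field(default_factory=list)


def verify_marginal_ode(ensemble: Ensemble, grid=None, tol=None
                        ) -> ResidualReport:
    """Self-consistency check of an ensemble against the marginal ODE.

    The population-level dynamics of the DNA-state probabilities obey a
    linear ODE whose flip rates are the conditional expectations of the
    propensities given the DNA state, e.g. E_t[alpha2(IntA) | S_o].  These
    expectations are estimated from the ensemble's recorded integrase counts
    on its grid, the ODE is integrated forward, and the per-state maximum
    discrepancy against the empirical fractions is reported.  The default
    tolerance is three Monte-Carlo standard errors per state, where the
    error model combines the pointwise binomial error of the empirical
    fractions with the accumulated effect of the hazard-estimation noise on
    the integrated prediction.

    The ensemble must have been simulated with a time grid
    (``simulate_population(..., grid=...)``) fine enough to resolve the
    transient; a practical minimum is ~500 cells and ~50 grid points.
    """
    grid = ensemble.grid if grid is None else np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValueError("ensemble grid too coarse for the ODE check")
    if grid is not ensemble.grid and not np.array_equal(grid, ensemble.grid):
        raise ValueError("grid must equal the ensemble's recorded grid")

    p = ensemble.params
    n = ensemble.n_cells
    dna = ensemble.dna_grid
    a_counts = ensemble.a_grid
    b_counts = ensemble.b_grid

    nt = grid.size
    emp = np.zeros((nt, 4))
    h1 = np.zeros(nt)  # E[alpha1(IntB) | S_o]
    h2 = np.zeros(nt)  # E[alpha2(IntA) | S_o]
    h3 = np.zeros(nt)  # E[alpha3(IntB) | S_a]
    se_h1 = np.zeros(nt)
    se_h2 = np.zeros(nt)
    se_h3 = np.zeros(nt)
    notes = []
    cap = max(int(a_counts.max()), int(b_counts.max()), 4) + 1
    al2 = _alpha_vec(np.arange(cap), p.kflipA, p.KdA)
    al1 = _alpha_vec(np.arange(cap), p.kflipB_exc, p.KdB)
    al3 = _alpha_vec(np.arange(cap), p.kflipB, p.KdB)
    for k in range(nt):
        d = dna[:, k]
        emp[k] = np.bincount(d, minlength=4) / n
        in_o = d == 0
        in_a = d == 1
        if in_o.any():
            m = in_o.sum()
            v2 = al2[a_counts[in_o, k]]
            v1 = al1[b_counts[in_o, k]]
            h2[k] = v2.mean()
            h1[k] = v1.mean()
            se_h2[k] = v2.std() / math.sqrt(m)
            se_h1[k] = v1.std() / math.sqrt(m)
        elif emp[k, 0] > 0:
            notes.append(f"empty S_o conditioning set at t={grid[k]:.3g}")
        if in_a.any():
            v3 = al3[b_counts[in_a, k]]
            h3[k] = v3.mean()
            se_h3[k] = v3.std() / math.sqrt(in_a.sum())

    def rates(t):
        return (np.interp(t, grid, h1), np.interp(t, grid, h2),
                np.interp(t, grid, h3))

    def rhs(t, y):
        r1, r2, r3 = rates(t)
        return [-(r1 + r2) * y[0],
                r2 * y[0] - r3 * y[1],
                r1 * y[0],
                r3 * y[1]]

    sol = solve_ivp(rhs, (grid[0], grid[-1]), [1.0, 0.0, 0.0, 0.0],
                    t_eval=grid, rtol=1e-8, atol=1e-10, method="RK45")
    if not sol.success:
        raise RuntimeError(f"marginal-ODE integration failed: {sol.message}")
    pred = sol.y.T
    resid = np.abs(emp - pred).max(axis=0)

    if tol is None:
        # binomial error of the empirical fractions ...
        se_frac = np.sqrt(np.clip(emp * (1 - emp), 0.25 / n, None) / n)
        # ... plus the hazard-estimation noise accumulated by the integration:
        # d(resid)/dt picks up se_h * (occupancy of the source state)
        from scipy.integrate import cumulative_trapezoid

        flux_err = ((se_h1 + se_h2) * emp[:, 0] + se_h3 * emp[:, 1])
        se_pred = cumulative_trapezoid(flux_err, grid, initial=0.0)
        se_tot = np.sqrt(se_frac**2 + se_pred[:, None]**2)
        tol = 3.0 * se_tot.max(axis=0) + 2.0 / n
    tol = np.broadcast_to(np.asarray(tol, dtype=float), (4,)).copy()
    passed = bool(np.all(resid <= tol))
    return ResidualReport(times=grid, empirical=emp, predicted=pred,
                          max_residual=resid, tol=tol, passed=passed,
                          notes=notes)
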