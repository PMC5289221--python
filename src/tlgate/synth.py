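"""Synthetic stand-ins for the wet-lab measurements.

The gate's analyses consume per-condition population fractions and
two-channel flow-cytometry events.  This module emulates both from the
stochastic model itself, layering the dominant noise sources of a real
experiment on top of the simulated fractions:

* finite sampling — observed state counts are drawn multinomially at the
  number of cells a cytometer actually measures;
* replicate-to-replicate variability — a log-normal multiplicative
  perturbation of the flipping rates per biological replicate;
* growth bias — non-fluorescent states (S_o, S_b) grow slightly faster than
  differentiated cells, applied as a deterministic exponential reweighting
  of the final fractions over the run duration (the single-cell chain itself
  is untouched);
* fluorescence overlap — per-state log-normal RFP/GFP intensities, including
  a residual-RFP subpopulation of S_ab cells that have not yet diluted the
  red reporter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .analysis import FRACTION_COLUMNS, make_fraction_rows
from .model import InductionProfile, RateParams
from .ssa import simulate_population

__all__ = [
    "NoiseModel",
    "FluorModel",
    "CytometryTable",
    "generate_fraction_dataset",
    "generate_cytometry_events",
    "gate_quadrants",
]

_STATES = ["S_o", "S_a", "S_b", "S_ab"]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement / biological noise applied to simulated fractions.

    Attributes
    ----------
    n_sampled_cells : int or None
        Events measured per population (multinomial sampling); ``None``
        means the infinite-sample limit (raw simulated fractions).  Default
        10^6, the order measured per population on the cytometer.
    replicates : int
        Biological replicates per condition.
    replicate_cv : float
        Coefficient of variation of the single log-normal multiplicative
        factor applied to all flipping rates of a replicate (overall
        recombination efficiency varying between biological replicates).
        The default 10% is an assumption, not a measured value.
    growth_bias : mapping state name -> relative growth rate (h^-1), or None
        Exponential reweighting of final fractions over the run duration,
        emulating the growth advantage of non-fluorescent states.
    """

    n_sampled_cells: int | None = 1_000_000
    replicates: int = 3
    replicate_cv: float = 0.10
    growth_bias: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.n_sampled_cells is not None and self.n_sampled_cells < 1:
            raise ValueError("n_sampled_cells must be >= 1 or None")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(n_sampled_cells=None, replicates=1, replicate_cv=0.0,
                   growth_bias=None)


def _perturb_params(params: RateParams, cv: float,
                    rng: np.random.Generator) -> RateParams:
    if cv <= 0:
        return params
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    # one mean-1 log-normal factor per replicate, shared by all flips
    f = math.exp(rng.normal(-sigma * sigma / 2, sigma))
    return params.replace(kflipA=params.kflipA * f,
                          kflipB=params.kflipB * f,
                          kflipB_exc=params.kflipB_exc * f)


def _reweight_growth(fractions: np.ndarray, growth_bias, duration: float
                     ) -> np.ndarray:
    if growth_bias is None:
        return fractions
    w = np.array([math.exp(float(growth_bias.get(s, 0.0)) * duration)
                  for s in _STATES])
    out = fractions * w
    return out / out.sum()


def _profile_for(entry):
    """Design entry -> (profile, event, dt, pw_b).

    Entries are either ``(order, dt)`` with order in {"ab", "ba"} for step
    pairs, or ``(dt, pw_b)`` numeric pairs for pulse conditions.
    """
    first, second = entry
    if isinstance(first, str):
        profile = InductionProfile.step_pair(float(second), order=first)
        return profile, f"E_{first}", float(second), math.inf
    dt, pw = float(first), float(second)
    profile = InductionProfile.pulse_b(dt, pw)
    return profile, ("E_ab" if pw > 0 else "E_a"), dt, pw


def generate_fraction_dataset(params: RateParams, design: Sequence,
                              noise: NoiseModel | None = None,
                              n_cells: int = 500, seed: int = 0,
                              t_end: float | None = None) -> pd.DataFrame:
    """Noisy per-condition, per-replicate fraction table.

    For every design condition and replicate: perturb the flipping rates
    (replicate_cv), simulate an ensemble of ``n_cells`` trajectories, apply
    the optional growth-bias reweighting over the run duration, then draw
    the observed state counts multinomially at ``n_sampled_cells``.  Fully
    reproducible from ``seed``.
    """
    if not design:
        raise ValueError("design must be non-empty")
    if noise is None:
        noise = NoiseModel()
    root = np.random.SeedSequence(int(seed))
    children = root.spawn(len(design) * noise.replicates)
    rows = []
    k = 0
    for ci, entry in enumerate(design):
        profile, event, dt, pw = _profile_for(entry)
        te = t_end
        if te is None:
            te = (dt + 24.0) if math.isinf(pw) else (dt + pw + 24.0)
        for rep in range(noise.replicates):
            ss = children[k]
            k += 1
            rng = np.random.default_rng(ss)
            rep_params = _perturb_params(params, noise.replicate_cv, rng)
            sim_seed = int(ss.generate_state(1)[0] & 0x7FFFFFFF)
            ens = simulate_population(rep_params, profile, t_end=te,
                                      n_cells=n_cells, seed=sim_seed)
            fr = ens.final_fractions()
            fr = _reweight_growth(fr, noise.growth_bias, te)
            if noise.n_sampled_cells is not None:
                counts = rng.multinomial(noise.n_sampled_cells, fr)
                fr = counts / noise.n_sampled_cells
                n_obs = noise.n_sampled_cells
            else:
                n_obs = n_cells
            row = make_fraction_rows(fr, te, n_obs,
                                     condition=f"cond{ci}_dt{dt:g}_pw{pw:g}",
                                     event=event, dt=dt, pw_b=pw)
            row["replicate"] = rep
            rows.append(row)
    return pd.concat(rows, ignore_index=True)[FRACTION_COLUMNS + ["replicate"]]


@dataclass(frozen=True)
class FluorModel:
    """Per-state log-normal intensity model for the two channels.

    ``off_mean``/``on_mean`` are channel intensities (a.u.) for silent and
    expressing states; ``cv`` the log-normal coefficient of variation.
    Gating thresholds default to the geometric midpoint between the on and
    off means.  ``residual_rfp_prob`` is the probability that an S_ab cell
    still carries RFP above threshold (slow reporter dilution after the
    S_a -> S_ab transition); the < 3% seen experimentally motivates the
    default.
    """

    off_mean: float = 100.0
    on_mean: float = 1000.0
    cv: float = 0.3
    residual_rfp_prob: float = 0.03

    @property
    def thresholds(self) -> tuple:
        thr = math.sqrt(self.off_mean * self.on_mean)
        return (thr, thr)  # (RFP, GFP)

    def channel_means(self, state: str) -> tuple:
        """(RFP mean, GFP mean) for a DNA state."""
        table = {
            "S_o": (self.off_mean, self.off_mean),
            "S_a": (self.on_mean, self.off_mean),
            "S_b": (self.off_mean, self.off_mean),
            "S_ab": (self.off_mean, self.on_mean),
        }
        if state not in table:
            raise KeyError(f"fluorescence model missing state {state!r}")
        return table[state]


@dataclass
class CytometryTable:
    """Flow-cytometry-like events plus the gate thresholds."""

    events: pd.DataFrame  # columns: condition, replicate, rfp, gfp
    rfp_threshold: float
    gfp_threshold: float


def generate_cytometry_events(fractions, n_events: int,
                              fluor_model: FluorModel | None = None,
                              seed: int = 0) -> CytometryTable:
    """Simulate two-channel events from one fraction-table row.

    Each event draws a hidden DNA state from the row's fractions, then RFP
    and GFP intensities from that state's log-normal model.  S_ab events
    carry residual RFP (drawn from the "on" distribution) with probability
    ``residual_rfp_prob``.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if fluor_model is None:
        fluor_model = FluorModel()
    fr = np.array([fractions[f"fraction_{s}"] for s in _STATES], dtype=float)
    if abs(fr.sum() - 1.0) > 1e-6:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    states = rng.choice(4, size=n_events, p=fr / fr.sum())
    sigma = math.sqrt(math.log(1.0 + fluor_model.cv ** 2))

    rfp_mu = np.empty(n_events)
    gfp_mu = np.empty(n_events)
    for si, s in enumerate(_STATES):
        m_r, m_g = fluor_model.channel_means(s)
        mask = states == si
        rfp_mu[mask] = m_r
        gfp_mu[mask] = m_g
    # residual RFP on a fraction of S_ab cells
    ab_mask = states == 3
    if ab_mask.any() and fluor_model.residual_rfp_prob > 0:
        residual = rng.random(n_events) < fluor_model.residual_rfp_prob
        rfp_mu[ab_mask & residual] = fluor_model.on_mean

    rfp = np.exp(rng.normal(np.log(rfp_mu) - sigma**2 / 2, sigma))
    gfp = np.exp(rng.normal(np.log(gfp_mu) - sigma**2 / 2, sigma))
    df = pd.DataFrame({
        "condition": fractions.get("condition", "sample"),
        "replicate": fractions.get("replicate", 0),
        "rfp": rfp,
        "gfp": gfp,
    })
    thr_r, thr_g = fluor_model.thresholds
    return CytometryTable(events=df, rfp_threshold=thr_r, gfp_threshold=thr_g)


def gate_quadrants(table: CytometryTable) -> dict:
    """Quadrant fractions and the derived (R, G) readouts.

    Q1 = GFP only, Q2 = both, Q3 = RFP only, Q4 = neither; the quadrants
    partition every event.  G = Q1 + Q2 (all GFP-positive cells count as
    S_ab) and R = Q3.
    """
    ev = table.events
    r_pos = ev["rfp"].to_numpy() > table.rfp_threshold
    g_pos = ev["gfp"].to_numpy() > table.gfp_threshold
    n = len(ev)
    if n == 0:
        raise ValueError("no events to gate")
    q1 = float((~r_pos & g_pos).sum()) / n
    q2 = float((r_pos & g_pos).sum()) / n
    q3 = float((r_pos & ~g_pos).sum()) / n
    q4 = float((~r_pos & ~g_pos).sum()) / n
    return {"Q1": q1, "Q2": q2, "Q3": q3, "Q4": q4,
            "R": q3, "G": q1 + q2}
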