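"""Inversion of population fractions into event timing.

Given a calibration design — populations exposed to a matrix of inducer
separation times ∆t and b-pulse widths PW_b, each yielding an RFP fraction
R (S_a cells) and a GFP fraction G (S_ab cells) — two functions are fitted:

* ``PW_b(R)``: because the a-first branch total depends only on the b-pulse
  width (R is approximately ∆t-independent), R values are pooled over ∆t per
  PW_b and a monotone piecewise-cubic interpolant maps R back to PW_b.
* ``∆t(G, PW_b)``: a low-order polynomial least-squares surface in G and
  PW_b, trained only on conditions in which the b pulse actually occurred
  (PW_b > 0).  All PW_b = 0 conditions are physically identical — inducer b
  is never added, so their nominal ∆t labels are design artifacts and carry
  no timing information.

Estimation of an unknown event first inverts R into an estimated pulse
width, then feeds (G, PW_b_hat) into the surface.  Predictions are clamped
to the calibration design range; extrapolation is refused and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "CalibrationSurface",
    "EventEstimate",
    "ResolutionReport",
    "fit_surface",
    "estimate_event",
    "build_lookup",
    "resolution_analysis",
]


class EventEstimate(NamedTuple):
    pw_b: float
    dt: float
    clamped: bool


def _poly_features(g, p, degree):
    g = np.asarray(g, dtype=float)
    p = np.asarray(p, dtype=float)
    cols = [np.ones_like(g)]
    for total in range(1, degree + 1):
        for i in range(total + 1):
            cols.append(g ** (total - i) * p ** i)
    return np.stack(cols, axis=-1)


@dataclass
class CalibrationSurface:
    """Fitted inversion functions and their training diagnostics."""

    r_knots: np.ndarray          # pooled mean R per PW_b, ascending in R
    pw_knots: np.ndarray         # matching PW_b values (descending)
    dt_coeffs: np.ndarray        # polynomial surface coefficients
    dt_degree: int
    pw_range: tuple              # clamping range for PW_b predictions (h)
    dt_range: tuple              # clamping range for ∆t predictions (h)
    r_domain: tuple              # R range covered by the calibration
    g_domain: tuple
    residuals: pd.DataFrame = field(repr=False, default=None)
    _pchip: PchipInterpolator = field(repr=False, default=None)

    def __post_init__(self):
        if self._pchip is None:
            self._pchip = PchipInterpolator(self.r_knots, self.pw_knots,
                                            extrapolate=False)

    # --- the two fitted functions ---------------------------------------
    def pwb_of_R(self, R):
        """Estimated pulse width (h) from an RFP fraction; clamped + flagged.

        Returns ``(pw_b, clamped)`` for scalar input, or arrays for array
        input.  R below the calibration range maps to the maximum design
        pulse width, R above it to the minimum.
        """
        R = np.asarray(R, dtype=float)
        scalar = R.ndim == 0
        R = np.atleast_1d(R)
        lo, hi = self.r_domain
        clamped = (R < lo) | (R > hi)
        pw = self._pchip(np.clip(R, lo, hi))
        pw = np.clip(pw, *self.pw_range)
        if scalar:
            return float(pw[0]), bool(clamped[0])
        return pw, clamped

    def dt_of_G_pwb(self, G, pw_b):
        """Estimated ∆t (h) from a GFP fraction and a pulse width."""
        X = _poly_features(G, pw_b, self.dt_degree)
        dt = X @ self.dt_coeffs
        raw = np.asarray(dt, dtype=float)
        clamped = (raw < self.dt_range[0]) | (raw > self.dt_range[1])
        out = np.clip(raw, *self.dt_range)
        if out.ndim == 0:
            return float(out), bool(clamped)
        return out, clamped


def fit_surface(calib: pd.DataFrame, dt_degree: int = 2,
                monotone_tol: float = 0.05) -> CalibrationSurface:
    """Fit the inversion functions from a calibration fraction table.

    ``calib`` must hold final fractions over a (∆t, PW_b) design with at
    least 3 distinct values of each (replicate rows welcome).  The pooled
    mean R per PW_b must be monotone non-increasing within ``monotone_tol``
    (isotonic adjustment beyond it raises, advising larger n_cells).
    """
    needed = {"dt", "pw_b", "fraction_S_a", "fraction_S_ab"}
    if not needed <= set(calib.columns):
        raise ValueError(f"calibration table needs columns {sorted(needed)}")
    pws = np.sort(calib["pw_b"].unique())
    dts = np.sort(calib["dt"].unique())
    if pws.size < 3 or dts.size < 3:
        raise ValueError("calibration design needs >= 3 distinct PW_b and "
                         ">= 3 distinct dt values")

    # --- PW_b(R): pool R over dt, enforce monotone, monotone cubic fit ---
    pooled = calib.groupby("pw_b")["fraction_S_a"].mean().sort_index()
    r_mean = pooled.to_numpy()
    # isotonic projection onto non-increasing sequences (PAVA on -r)
    r_iso = -_pava(-r_mean)
    adjustment = np.abs(r_iso - r_mean).max()
    if adjustment > monotone_tol:
        raise ValueError(
            f"pooled R vs PW_b is non-monotone beyond tolerance "
            f"(max adjustment {adjustment:.3f} > {monotone_tol}); "
            "increase n_cells per calibration condition")
    pw_vals = pooled.index.to_numpy(dtype=float)
    # collapse ties in R so the interpolation abscissa is strictly increasing
    r_knots, pw_knots = [], []
    k = 0
    while k < len(r_iso):
        j = k
        while j + 1 < len(r_iso) and r_iso[j + 1] == r_iso[k]:
            j += 1
        r_knots.append(r_iso[k])
        pw_knots.append(pw_vals[k:j + 1].mean())
        k = j + 1
    r_knots = np.array(r_knots[::-1])   # ascending R
    pw_knots = np.array(pw_knots[::-1])
    if r_knots.size < 2:
        raise ValueError("degenerate calibration: R does not vary with PW_b")

    # --- ∆t(G, PW_b): polynomial least squares on the pulsed rows --------
    pulsed = calib[calib["pw_b"] > 0]
    if pulsed["pw_b"].nunique() < 2:
        raise ValueError("calibration design needs >= 2 distinct PW_b > 0 "
                         "values to fit the ∆t surface")
    G = pulsed["fraction_S_ab"].to_numpy(dtype=float)
    P = pulsed["pw_b"].to_numpy(dtype=float)
    y = pulsed["dt"].to_numpy(dtype=float)
    X = _poly_features(G, P, dt_degree)
    coeffs, *_ = np.linalg.lstsq(X, y, rcond=None)

    pw_range = (float(pws.min()), float(pws.max()))
    dt_range = (float(dts.min()), float(dts.max()))
    surface = CalibrationSurface(
        r_knots=r_knots, pw_knots=pw_knots, dt_coeffs=coeffs,
        dt_degree=dt_degree, pw_range=pw_range, dt_range=dt_range,
        r_domain=(float(r_knots.min()), float(r_knots.max())),
        g_domain=(float(G.min()), float(G.max())))

    # training diagnostics (pulsed conditions: ∆t is defined only there)
    R = pulsed["fraction_S_a"].to_numpy(dtype=float)
    pw_hat, _ = surface.pwb_of_R(R)
    dt_hat, _ = surface.dt_of_G_pwb(G, pw_hat)
    surface.residuals = pd.DataFrame({
        "dt": y, "pw_b": P, "R": R, "G": G,
        "pw_b_hat": pw_hat, "dt_hat": dt_hat,
        "pw_b_resid": pw_hat - P, "dt_resid": dt_hat - y,
    })
    return surface


def _pava(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: isotonic (non-decreasing) L2 projection."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    vals, wts = [], []
    for i in range(n):
        vals.append(y[i])
        wts.append(1.0)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v = (vals[-2] * wts[-2] + vals[-1] * wts[-1]) / (wts[-2] + wts[-1])
            w = wts[-2] + wts[-1]
            vals = vals[:-2] + [v]
            wts = wts[:-2] + [w]
    out = np.empty(n)
    pos = 0
    for v, w in zip(vals, wts):
        out[pos:pos + int(w)] = v
        pos += int(w)
    return out


def estimate_event(R: float, G: float,
                   surface: CalibrationSurface) -> EventEstimate:
    """Convert measured (R, G) fractions into (PW_b, ∆t) estimates.

    ``PW_b_hat = PW_b(R)``, then ``∆t_hat = ∆t(G, PW_b_hat)``; both are
    clamped to the calibration design range and the estimate is flagged if
    any clamping occurred.
    """
    if not (0 <= R <= 1 and 0 <= G <= 1):
        raise ValueError("R and G must be fractions in [0, 1]")
    pw, c1 = surface.pwb_of_R(float(R))
    dt, c2 = surface.dt_of_G_pwb(float(G), pw)
    return EventEstimate(pw_b=pw, dt=dt, clamped=bool(c1 or c2))


def build_lookup(surface: CalibrationSurface,
                 mesh_step: float = 0.05) -> pd.DataFrame:
    """Rectangular (R, G) reference mesh of estimated (PW_b, ∆t) values."""
    if mesh_step <= 0:
        raise ValueError("mesh_step must be > 0")
    r_lo, r_hi = surface.r_domain
    g_lo, g_hi = surface.g_domain
    rs = np.arange(r_lo, r_hi + mesh_step / 2, mesh_step)
    gs = np.arange(g_lo, g_hi + mesh_step / 2, mesh_step)
    rows = []
    for g in gs:
        for r in rs:
            est = estimate_event(float(np.clip(r, 0, 1)),
                                 float(np.clip(g, 0, 1)), surface)
            rows.append({"R": r, "G": g, "pw_b": est.pw_b, "dt": est.dt,
                         "clamped": est.clamped})
    return pd.DataFrame(rows)


@dataclass
class ResolutionReport:
    """Per-true-value mean, SD and count of the estimates."""

    pw_b: pd.DataFrame
    dt: pd.DataFrame

    def sd_at(self, which: str, truth: float) -> float:
        tab = getattr(self, which)
        row = tab[np.isclose(tab["truth"], truth)]
        if row.empty:
            raise KeyError(f"no {which} group at truth={truth}")
        return float(row["sd"].iloc[0])


def resolution_analysis(truths: Sequence, estimates: Sequence
                        ) -> ResolutionReport:
    """Group (PW_b, ∆t) estimates by their true values.

    ``truths`` and ``estimates`` are equal-length sequences of
    ``(pw_b, dt)`` pairs.  SD is the sample standard deviation (ddof=1;
    0 for singleton groups).
    """
    truths = list(truths)
    estimates = list(estimates)
    if not truths:
        raise ValueError("empty input")
    if len(truths) != len(estimates):
        raise ValueError("truths and estimates must have equal length")
    df = pd.DataFrame({
        "pw_true": [t[0] for t in truths],
        "dt_true": [t[1] for t in truths],
        "pw_est": [e[0] for e in estimates],
        "dt_est": [e[1] for e in estimates],
    })

    def summarize(true_col, est_col):
        g = df.groupby(true_col)[est_col]
        out = pd.DataFrame({
            "truth": list(g.groups),
            "mean": g.mean().to_numpy(),
            "sd": g.std(ddof=1).fillna(0.0).to_numpy(),
            "count": g.count().to_numpy(),
        })
        return out.sort_values("truth", ignore_index=True)

    return ResolutionReport(pw_b=summarize("pw_true", "pw_est"),
                            dt=summarize("dt_true", "dt_est"))
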