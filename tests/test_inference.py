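import numpy as np
import pandas as pd
import pytest

import tlgate as tg


def _noiseless_calib(dts=(0, 2, 4, 6), pws=(0, 2, 4, 6)):
    """Deterministic synthetic calibration table with clean structure:
    R decays with PW_b, G grows with both ∆t and PW_b."""
    rows = []
    for dt in dts:
        for pw in pws:
            r = 0.9 * np.exp(-0.5 * pw) + 0.05
            g = 0.05 + 0.09 * dt + 0.35 * (1 - np.exp(-0.5 * pw))
            rows.append({"condition": f"{dt}_{pw}", "event": "E_ab",
                         "dt": float(dt), "pw_b": float(pw), "time": 30.0,
                         "fraction_S_a": r, "fraction_S_ab": g,
                         "fraction_S_b": 1 - r - g, "fraction_S_o": 0.0,
                         "n_cells": 1000})
    return pd.DataFrame(rows)


class TestFitSurface:
    def test_monotone_pwb_of_R(self, calib_surface):
        """PW_b(R) is non-increasing over a dense grid of its domain."""
        lo, hi = calib_surface.r_domain
        rs = np.linspace(lo, hi, 200)
        pw, _ = calib_surface.pwb_of_R(rs)
        assert np.all(np.diff(pw) <= 1e-9)

    def test_round_trip_on_clean_training_data(self):
        calib = _noiseless_calib()
        surface = tg.fit_surface(calib)
        pulsed = surface.residuals
        assert np.abs(pulsed["pw_b_resid"]).max() < 0.3
        assert np.abs(pulsed["dt_resid"]).max() < 0.6

    def test_degenerate_design_rejected(self):
        calib = _noiseless_calib(pws=(2,))
        with pytest.raises(ValueError, match=">= 3 distinct"):
            tg.fit_surface(calib)

    def test_non_monotone_pooled_R_rejected(self):
        calib = _noiseless_calib()
        # wreck the R ordering far beyond any tolerance
        calib.loc[calib["pw_b"] == 4.0, "fraction_S_a"] = 0.95
        with pytest.raises(ValueError, match="n_cells"):
            tg.fit_surface(calib)


class TestEstimateEvent:
    def test_anchor_point(self, calib_table, calib_surface):
        """The PW_b = 0 calibration mean maps back to (≈0, small ∆t)."""
        base = calib_table[calib_table["pw_b"] == 0.0]
        est = tg.estimate_event(base["fraction_S_a"].mean(),
                                base["fraction_S_ab"].mean(), calib_surface)
        assert est.pw_b == pytest.approx(0.0, abs=0.25)
        assert est.dt <= 1.0
        assert not est.clamped

    def test_low_R_clamps_to_max_pulse(self, calib_surface):
        est = tg.estimate_event(0.0, 0.5, calib_surface)
        assert est.pw_b == calib_surface.pw_range[1]
        assert est.clamped

    def test_input_validation(self, calib_surface):
        with pytest.raises(ValueError):
            tg.estimate_event(1.5, 0.5, calib_surface)

    def test_round_trip_held_out_conditions(self, revised_params,
                                            calib_surface):
        """Held-out conditions (off the calibration grid) are recovered with
        errors consistent with the training residual scale."""
        design = [(1.5, 1.5), (2.5, 3.5)]
        table = tg.generate_fraction_dataset(
            revised_params, design, noise=tg.NoiseModel.noiseless(),
            n_cells=2000, seed=50)
        for _, row in table.iterrows():
            est = tg.estimate_event(row["fraction_S_a"],
                                    row["fraction_S_ab"], calib_surface)
            assert est.pw_b == pytest.approx(row["pw_b"], abs=0.75)
            assert est.dt == pytest.approx(row["dt"], abs=1.0)


class TestBuildLookup:
    def test_shape_and_consistency(self, calib_surface):
        lk = tg.build_lookup(calib_surface, mesh_step=0.2)
        r_nodes = lk["R"].nunique()
        g_nodes = lk["G"].nunique()
        assert len(lk) == r_nodes * g_nodes
        row = lk.iloc[7]
        est = tg.estimate_event(min(row["R"], 1.0), min(row["G"], 1.0),
                                calib_surface)
        assert row["pw_b"] == pytest.approx(est.pw_b)
        assert row["dt"] == pytest.approx(est.dt)

    def test_monotone_columns(self, calib_surface):
        """Within each G row of the mesh, PW_b predictions are
        non-increasing in R."""
        lk = tg.build_lookup(calib_surface, mesh_step=0.1)
        for _, gdf in lk.groupby("G"):
            pw = gdf.sort_values("R")["pw_b"].to_numpy()
            assert np.all(np.diff(pw) <= 1e-9)

    def test_rejects_bad_step(self, calib_surface):
        with pytest.raises(ValueError):
            tg.build_lookup(calib_surface, mesh_step=0.0)


class TestResolutionAnalysis:
    def test_hand_example(self):
        truths = [(1.0, 2.0)] * 3
        ests = [(0.9, 2.0), (1.0, 2.0), (1.1, 2.0)]
        rep = tg.resolution_analysis(truths, ests)
        assert rep.pw_b["mean"].iloc[0] == pytest.approx(1.0)
        assert rep.pw_b["sd"].iloc[0] == pytest.approx(0.1)
        assert rep.dt["sd"].iloc[0] == 0.0

    def test_perfect_estimates(self):
        truths = [(1.0, 1.0), (2.0, 3.0), (1.0, 1.0)]
        rep = tg.resolution_analysis(truths, truths)
        assert (rep.pw_b["sd"] == 0).all()
        assert (rep.dt["sd"] == 0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tg.resolution_analysis([], [])
        with pytest.raises(ValueError):
            tg.resolution_analysis([(1, 1)], [])

    def test_resolution_degrades_with_pulse_width(self, calib_table,
                                                  calib_surface):
        """Recovery uncertainty of PW_b grows (weakly) from short pulses to
        the saturated end of the design range."""
        truths, ests = [], []
        for _, row in calib_table.iterrows():
            e = tg.estimate_event(row["fraction_S_a"], row["fraction_S_ab"],
                                  calib_surface)
            truths.append((row["pw_b"], row["dt"]))
            ests.append((e.pw_b, e.dt))
        rep = tg.resolution_analysis(truths, ests)
        sd = rep.pw_b.set_index("truth")["sd"]
        assert sd[1.0] < sd[4.0:].max()
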