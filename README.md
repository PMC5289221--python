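# tlgate

Stochastic modeling and event inference for a two-integrase **temporal logic
gate** — an engineered bacterial circuit that records the *order* and
*timing* of two transient chemical signals in the DNA of a cell population.

## The problem

A single-copy DNA cassette is acted on by two serine integrases, intA and
intB, each induced by its own chemical input (a, b). Because integrase
recombination is irreversible (attB/attP sites become inert attL/attR), the
cassette moves through a one-way state graph:

```
            α2 (intA)          α3 (intB)
    S_o ───────────────▶ S_a ───────────▶ S_ab     "a then b" record
     │
     │  α1 (intB)
     └─────────────────▶ S_b                        "b first" dead end
```

A single cell therefore commits to one of the absorbing states, but a
*population* of cells does more: because each cell switches stochastically,
the final population fractions of the four states encode the inducer order,
the separation time ∆t between the two inputs, and the width PW_b of a
transient b pulse. The package is written for synthetic-biology modelers who
want to simulate such gates, calibrate them, and decode measured fluorescent
population fractions (R = RFP ≈ S_a cells, G = GFP ≈ S_ab cells) back into
event timing.

## The model

Each cell is a continuous-time Markov chain over `(DNA, IntA, IntB)` with
integrase production γ\* = kprod\*·u\*(t) + kleak\*, first-order
degradation/dilution δ = kdeg, and DNA-flip propensities that require a
tetramer and saturate in the monomer count n:

    α(n) = kflip · n(n−1)(n−2)(n−3) /
           (Kd⁴ + Kd³n + Kd²n(n−1) + Kd·n(n−1)(n−2) + n(n−1)(n−2)(n−3))

Ensembles of exact Gillespie sample paths (numba-compiled, ~10⁷ events/s on
one core) are validated against a truncated chemical-master-equation solver,
a frozen-propensity closed form, and a marginal-ODE self-consistency check.
On top of the simulator sit the population analyses (∆t scans, pulse
matrices, the ∆t90 detection limit), the MSE grid fit of the flipping rates,
the calibration-surface inversion PW_b(R) and ∆t(G, PW_b), and a
synthetic-data generator that emulates noisy measured fraction tables and
two-channel flow-cytometry events. See `docs/methods.md` for the full
account.

## Worked example

```python
import tlgate as tg

params = tg.RateParams.preset("revised")

# 1. How does the population record "a then b, 3 h apart"?
ens = tg.simulate_population(params, tg.InductionProfile.step_pair(3.0),
                             t_end=27.0, n_cells=5000, seed=42)
fo, fa, fb, fab = ens.final_fractions()
print(f"E_ab, dt=3 h:  S_o={fo:.3f}  S_a={fa:.3f}  S_b={fb:.3f}  S_ab={fab:.3f}")

# 2. Detection limit of the separation time
scan = tg.scan_dt(params, "ab", dts=range(11), n_cells=3000, seed=42)
curve = dict(zip(scan["dt"], scan["fraction_S_ab"]))
print("dt90 (relative):", round(tg.dt90(curve, mode="relative"), 2), "h")

# 3. Calibrate an inversion surface on synthetic noisy data and decode
#    an unknown sample
design = [(dt, pw) for dt in range(7) for pw in range(7)]
calib = tg.generate_fraction_dataset(params, design, noise=tg.NoiseModel(),
                                     n_cells=500, seed=42)
surface = tg.fit_surface(calib)
unknown = tg.generate_fraction_dataset(params, [(2.0, 1.5)],
                                       noise=tg.NoiseModel(replicates=1),
                                       n_cells=500, seed=7)
row = unknown.iloc[0]
est = tg.estimate_event(row["fraction_S_a"], row["fraction_S_ab"], surface)
print(f"true (PW_b, dt) = (1.5, 2.0) h;  R={row['fraction_S_a']:.3f}, "
      f"G={row['fraction_S_ab']:.3f}  ->  estimated "
      f"(PW_b, dt) = ({est.pw_b:.2f}, {est.dt:.2f}) h")
```

prints

```
E_ab, dt=3 h:  S_o=0.000  S_a=0.001  S_b=0.353  S_ab=0.646
dt90 (relative): 6.57 h
true (PW_b, dt) = (1.5, 2.0) h;  R=0.260, G=0.372  ->  estimated (PW_b, dt) = (1.37, 2.55) h
```

Reading the output: after an a-then-b event with ∆t = 3 h, 64.6% of cells
carry the S_ab record and the rest were captured by the b-first branch —
the fraction itself encodes ∆t. The relative ∆t90 says separation times up
to ~6.6 h are resolvable before the response saturates. In the last step a
noisy "unknown" population (one biological replicate, multinomially sampled,
replicate-perturbed flipping rates) is decoded from its (R, G) coordinates
alone to within ~0.1 h in pulse width and ~0.6 h in separation time.

A command-line interface mirrors the library:

```bash
tlgate simulate --preset revised --mode pulse --dt 2 --pw-b 2 --out run/
tlgate scan-dt --preset initial --order ab --dts 0,1,2,3,4,5
tlgate synth --preset revised --out calib.csv
tlgate infer --calib calib.csv --samples samples.csv --out inferred/
tlgate validate            # SSA vs master-equation oracle suite
```

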