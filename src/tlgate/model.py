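"""Core domain types and reaction system of the two-integrase temporal logic gate.

The gate is a single-copy DNA cassette that can be in one of four states:

* ``S_o``  — the original configuration,
* ``S_a``  — after integrase A has flipped its target region,
* ``S_b``  — after integrase B has excised the cassette from ``S_o`` (a dead end),
* ``S_ab`` — after integrase B has acted on ``S_a`` (the "a then b" record).

``S_b`` and ``S_ab`` are absorbing: serine integrases recombine attB/attP
sites into attL/attR products they can no longer act on, so there are no
reverse transitions.  Each cell is described by the tuple
``(DNA state, IntA monomer count, IntB monomer count)``; integrases are
produced (induced plus leak), degrade/dilute with first-order kinetics, and
flip DNA with a propensity that saturates in the monomer count because four
monomers (a tetramer) are required at the recombination synapse.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, fields, replace
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "DnaState",
    "RateParams",
    "InductionProfile",
    "CellState",
    "tetramer_propensity",
    "transition_rates",
]


class DnaState(enum.IntEnum):
    """The four cassette configurations, ordered S_o, S_a, S_b, S_ab."""

    S_o = 0
    S_a = 1
    S_b = 2
    S_ab = 3

    @property
    def is_absorbing(self) -> bool:
        return self in (DnaState.S_b, DnaState.S_ab)


class CellState(NamedTuple):
    """One cell's Markov-chain state: (DNA state, IntA count, IntB count)."""

    dna: DnaState
    intA: int
    intB: int


def _require_count(n, name: str = "n") -> int:
    """Validate a non-negative integer molecule count and return it as int."""
    if isinstance(n, bool):
        raise ValueError(f"{name} must be an integer count, got bool")
    if isinstance(n, (int, np.integer)):
        ni = int(n)
    elif isinstance(n, float) and n.is_integer():
        ni = int(n)
    else:
        raise ValueError(f"{name} must be an integer count, got {n!r}")
    if ni < 0:
        raise ValueError(f"{name} must be >= 0, got {ni}")
    return ni


def tetramer_propensity(n, kflip: float, Kd: float) -> float:
    """DNA-flip propensity for an integrase present at ``n`` monomers.

    Recombination requires a tetramer (two dimers) at the synapse, with no
    binding cooperativity, so the propensity is ``kflip`` times the
    probability-like saturation fraction built from falling factorials::

        kflip * n(n-1)(n-2)(n-3) /
            (Kd^4 + Kd^3 n + Kd^2 n(n-1) + Kd n(n-1)(n-2) + n(n-1)(n-2)(n-3))

    It is exactly 0 for ``n < 4``, strictly increasing for ``n >= 4`` and
    approaches ``kflip`` as ``n`` grows.

    Parameters
    ----------
    n : int
        Monomer copy number (>= 0).
    kflip : float
        Flipping rate if the tetramer is formed, in h^-1 (>= 0).
    Kd : float
        Monomer dissociation constant, in molecules (> 0).
    """
    ni = _require_count(n)
    if kflip < 0:
        raise ValueError(f"kflip must be >= 0, got {kflip}")
    if Kd <= 0:
        raise ValueError(f"Kd must be > 0, got {Kd}")
    if ni < 4:
        return 0.0
    x = float(ni)
    p1 = x
    p2 = x * (x - 1.0)
    p3 = p2 * (x - 2.0)
    p4 = p3 * (x - 3.0)
    return kflip * p4 / (Kd**4 + Kd**3 * p1 + Kd**2 * p2 + Kd * p3 + p4)


@dataclass(frozen=True)
class RateParams:
    """Kinetic constants of the gate.

    Copy-number rates are molecules per hour in a fixed unit cell volume
    (1 um^3), so monomer counts are dimensionless integers.

    Attributes
    ----------
    kprodA, kprodB : float
        Induced production rates (molecules/h per cell).
    kleakA, kleakB : float
        Basal (leaky) production rates (molecules/h per cell).  Leak is
        additive: under induction the production rate is ``kprod + kleak``.
    kdeg : float
        First-order degradation/dilution rate (h^-1), shared by both
        integrases.
    kflipA : float
        Flipping rate constant for S_o -> S_a (h^-1).
    kflipB : float
        Flipping rate constant for S_a -> S_ab (h^-1).
    kflipB_exc : float or None
        Flipping rate constant for the excision S_o -> S_b (h^-1).  Defaults
        to ``kflipB``; setting it lower reproduces the variant in which the
        excision transition is slower than the two inversions.
    KdA, KdB : float
        Monomer dissociation constants (molecules).
    """

    kprodA: float = 50.0
    kprodB: float = 50.0
    kleakA: float = 0.0
    kleakB: float = 0.0
    kdeg: float = 0.3
    kflipA: float = 0.4
    kflipB: float = 0.4
    kflipB_exc: float | None = None
    KdA: float = 10.0
    KdB: float = 10.0

    def __post_init__(self):
        if self.kflipB_exc is None:
            object.__setattr__(self, "kflipB_exc", float(self.kflipB))
        for name in ("kprodA", "kprodB", "kleakA", "kleakB", "kdeg",
                     "kflipA", "kflipB", "kflipB_exc"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name in ("KdA", "KdB"):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")

    @classmethod
    def preset(cls, name: str) -> "RateParams":
        """Return a named parameter preset.

        ``"initial"``
            The symmetric exploratory set: kprodA = kprodB = 50, kdeg = 0.3,
            kflipA = kflipB = 0.4, no leak, KdA = KdB = 10.
        ``"revised"``
            The data-constrained set: kflipA = 0.2, kflipB = 0.3,
            kleakA = 1% of kprodA, kleakB = 2% of kprodB, others as initial.
        """
        if name == "initial":
            return cls()
        if name == "revised":
            return cls(kflipA=0.2, kflipB=0.3, kleakA=0.01 * 50.0,
                       kleakB=0.02 * 50.0)
        raise ValueError(
            f"unknown preset {name!r}; valid presets are 'initial', 'revised'")

    def replace(self, **kwargs) -> "RateParams":
        """Return a copy with the given fields replaced."""
        if "kflipB" in kwargs and "kflipB_exc" not in kwargs:
            # keep the default coupling unless the excision rate was pinned
            if self.kflipB_exc == self.kflipB:
                kwargs["kflipB_exc"] = None
        return replace(self, **kwargs)

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "RateParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown RateParams keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "RateParams":
        return cls.from_dict(json.loads(s))

    def to_yaml(self) -> str:
        import yaml

        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, s: str) -> "RateParams":
        import yaml

        return cls.from_dict(yaml.safe_load(s))


def _validate_intervals(iv: Sequence[Sequence[float]], name: str):
    out = []
    prev_end = -math.inf
    for pair in iv:
        start, end = float(pair[0]), float(pair[1])
        if not start < end:
            raise ValueError(f"{name}: interval [{start}, {end}) is empty")
        if start < 0:
            raise ValueError(f"{name}: interval start {start} < 0")
        if start < prev_end:
            raise ValueError(f"{name}: intervals overlap or are unsorted")
        prev_end = end
        out.append((start, end))
    return tuple(out)


@dataclass(frozen=True)
class InductionProfile:
    """Piecewise-constant on/off schedules for the two inducers.

    Each channel is a sorted tuple of non-overlapping half-open intervals
    ``[start, end)`` during which that inducer is present; ``end`` may be
    ``math.inf`` for a step input that is never removed.
    """

    intervals_a: tuple[tuple[float, float], ...] = ()
    intervals_b: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "intervals_a",
                           _validate_intervals(self.intervals_a, "intervals_a"))
        object.__setattr__(self, "intervals_b",
                           _validate_intervals(self.intervals_b, "intervals_b"))

    # --- constructors ---------------------------------------------------
    @classmethod
    def step_pair(cls, dt: float, order: str = "ab") -> "InductionProfile":
        """Two overlapping steps separated by ``dt`` hours.

        For ``order="ab"`` inducer a is on from t=0 and inducer b from t=dt;
        for ``order="ba"`` the channels are swapped.  The first inducer stays
        on after the second arrives.
        """
        if dt < 0:
            raise ValueError(f"dt must be >= 0, got {dt}")
        first = ((0.0, math.inf),)
        second = ((float(dt), math.inf),)
        if order == "ab":
            return cls(intervals_a=first, intervals_b=second)
        if order == "ba":
            return cls(intervals_a=second, intervals_b=first)
        raise ValueError(f"order must be 'ab' or 'ba', got {order!r}")

    @classmethod
    def pulse_b(cls, dt: float, pw_b: float) -> "InductionProfile":
        """Constant reference inducer a with a finite pulse of b.

        Inducer a is on for all t >= 0; inducer b is on during
        ``[dt, dt + pw_b)``.  ``pw_b = 0`` yields an empty b channel.
        """
        if dt < 0 or pw_b < 0:
            raise ValueError("dt and pw_b must be >= 0")
        b = () if pw_b == 0 else ((float(dt), float(dt) + float(pw_b)),)
        return cls(intervals_a=((0.0, math.inf),), intervals_b=b)

    @classmethod
    def a_only(cls) -> "InductionProfile":
        """Inducer a on from t=0 forever; no inducer b (an E_a event)."""
        return cls(intervals_a=((0.0, math.inf),), intervals_b=())

    @classmethod
    def none(cls) -> "InductionProfile":
        return cls()

    # --- evaluation -----------------------------------------------------
    @staticmethod
    def _indicator(intervals, t: float) -> float:
        for start, end in intervals:
            if start <= t < end:
                return 1.0
            if t < start:
                return 0.0
        return 0.0

    def u_a(self, t: float) -> float:
        """Indicator of inducer a presence at time t."""
        return self._indicator(self.intervals_a, t)

    def u_b(self, t: float) -> float:
        """Indicator of inducer b presence at time t."""
        return self._indicator(self.intervals_b, t)

    def breakpoints(self, t_end: float | None = None) -> np.ndarray:
        """Sorted unique finite interval endpoints, optionally within (0, t_end)."""
        pts = set()
        for start, end in self.intervals_a + self.intervals_b:
            pts.add(start)
            if math.isfinite(end):
                pts.add(end)
        arr = np.array(sorted(pts), dtype=float)
        if t_end is not None:
            arr = arr[(arr > 0) & (arr < t_end)]
        else:
            arr = arr[arr > 0]
        return arr

    def segments(self, t_end: float):
        """Piecewise-constant decomposition of [0, t_end).

        Returns ``(seg_ends, ua, ub)`` where segment i covers
        ``[seg_ends[i-1], seg_ends[i])`` (with an implicit 0 start) and
        ``ua[i]``/``ub[i]`` are the channel indicators on that segment.
        """
        if t_end <= 0:
            raise ValueError(f"t_end must be > 0, got {t_end}")
        bk = self.breakpoints(t_end)
        seg_ends = np.append(bk, float(t_end))
        starts = np.concatenate(([0.0], bk))
        ua = np.array([self.u_a(s) for s in starts])
        ub = np.array([self.u_b(s) for s in starts])
        return seg_ends, ua, ub

    # --- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        def enc(ivs):
            return [[s, None if math.isinf(e) else e] for s, e in ivs]

        return {"intervals_a": enc(self.intervals_a),
                "intervals_b": enc(self.intervals_b)}

    @classmethod
    def from_dict(cls, d: dict) -> "InductionProfile":
        known = {"intervals_a", "intervals_b"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown InductionProfile keys: {sorted(unknown)}")

        def dec(ivs):
            return tuple((float(s), math.inf if e is None else float(e))
                         for s, e in ivs)

        return cls(intervals_a=dec(d.get("intervals_a", ())),
                   intervals_b=dec(d.get("intervals_b", ())))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "InductionProfile":
        return cls.from_dict(json.loads(s))

    def to_yaml(self) -> str:
        import yaml

        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, s: str) -> "InductionProfile":
        import yaml

        return cls.from_dict(yaml.safe_load(s))


def transition_rates(cell: CellState, params: RateParams,
                     profile: InductionProfile, t: float):
    """Enabled reactions from ``cell`` at time ``t``.

    Returns a list of ``(target CellState, rate h^-1)`` pairs for reactions
    with strictly positive rate: integrase births (induced + leak) and
    first-order deaths, plus the DNA flips enabled from the current state.
    Flips do not change the integrase counts.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    dna, a, b = DnaState(cell.dna), _require_count(cell.intA, "intA"), \
        _require_count(cell.intB, "intB")
    out: list[tuple[CellState, float]] = []

    gA = params.kprodA * profile.u_a(t) + params.kleakA
    gB = params.kprodB * profile.u_b(t) + params.kleakB
    if gA > 0:
        out.append((CellState(dna, a + 1, b), gA))
    if gB > 0:
        out.append((CellState(dna, a, b + 1), gB))
    if a > 0 and params.kdeg > 0:
        out.append((CellState(dna, a - 1, b), params.kdeg * a))
    if b > 0 and params.kdeg > 0:
        out.append((CellState(dna, a, b - 1), params.kdeg * b))

    if dna == DnaState.S_o:
        a2 = tetramer_propensity(a, params.kflipA, params.KdA)
        if a2 > 0:
            out.append((CellState(DnaState.S_a, a, b), a2))
        a1 = tetramer_propensity(b, params.kflipB_exc, params.KdB)
        if a1 > 0:
            out.append((CellState(DnaState.S_b, a, b), a1))
    elif dna == DnaState.S_a:
        a3 = tetramer_propensity(b, params.kflipB, params.KdB)
        if a3 > 0:
            out.append((CellState(DnaState.S_ab, a, b), a3))
    # S_b and S_ab are absorbing: no DNA transitions out.
    return out
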