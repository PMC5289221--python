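"""Run configuration: a serializable description of a simulation run."""

from __future__ import annotations

from dataclasses import dataclass

from .model import InductionProfile, RateParams

__all__ = ["RunConfig", "profile_from_spec", "params_from_spec"]

_PROFILE_KEYS = {"kind", "dt", "pw_b", "order", "intervals_a", "intervals_b"}


def profile_from_spec(spec) -> InductionProfile:
    """Build an induction profile from a config mapping.

    ``kind`` selects the constructor: ``step`` (fields dt, order),
    ``pulse`` (dt, pw_b), ``a_only``, ``none``, or ``explicit``
    (intervals_a / intervals_b lists, end null = open-ended).
    """
    if isinstance(spec, InductionProfile):
        return spec
    unknown = set(spec) - _PROFILE_KEYS
    if unknown:
        raise ValueError(f"unknown profile keys: {sorted(unknown)}")
    kind = spec.get("kind", "step")
    if kind == "step":
        return InductionProfile.step_pair(float(spec.get("dt", 0.0)),
                                          order=spec.get("order", "ab"))
    if kind == "pulse":
        return InductionProfile.pulse_b(float(spec.get("dt", 0.0)),
                                        float(spec.get("pw_b", 0.0)))
    if kind == "a_only":
        return InductionProfile.a_only()
    if kind == "none":
        return InductionProfile.none()
    if kind == "explicit":
        return InductionProfile.from_dict(
            {k: spec.get(k, []) for k in ("intervals_a", "intervals_b")})
    raise ValueError(f"unknown profile kind {spec.get('kind')!r}")


def params_from_spec(spec) -> RateParams:
    """Rate parameters from a preset name or a flat mapping."""
    if isinstance(spec, RateParams):
        return spec
    if isinstance(spec, str):
        return RateParams.preset(spec)
    return RateParams.from_dict(dict(spec))


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulation run bit-for-bit."""

    params: RateParams
    profile: InductionProfile
    n_cells: int = 5000
    t_end: float | None = None
    seed: int = 0
    grid_points: int = 121
    outdir: str = "."

    _KEYS = ("params", "profile", "n_cells", "t_end", "seed", "grid_points",
             "outdir")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(cls._KEYS)
        if unknown:
            raise ValueError(f"invalid config keys: {sorted(unknown)}")
        kwargs = dict(d)
        kwargs["params"] = params_from_spec(d.get("params", "initial"))
        kwargs["profile"] = profile_from_spec(d.get("profile", {"kind": "step"}))
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(text) or {})

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "profile": {"kind": "explicit", **self.profile.to_dict()},
            "n_cells": self.n_cells,
            "t_end": self.t_end,
            "seed": self.seed,
            "grid_points": self.grid_points,
            "outdir": self.outdir,
        }

    def to_yaml(self) -> str:
        import yaml

        return yaml.safe_dump(self.to_dict(), sort_keys=False)
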