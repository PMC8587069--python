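"""Anatomical and physiological parameter registry for the 65-node body.

The passive body is discretised into 16 segments (head, chest, back, pelvis,
paired shoulders, arms, hands, thighs, legs, feet), each with four concentric
tissue layers (core, muscle, fat, skin), plus a central blood compartment —
65 nodes.  Clothed segments carry two further clothing layers (inner and
outer fabric surface), handled by :mod:`thermoclo.clothing`.

Defaults ship as a structured-text fixture (``data/body.toml``): published
segment areas, heights and set-point temperatures, plus Stolwijk-style node
capacities, basal rates and conductances reconstructed from standard tissue
properties (see the fixture header and docs/methods.md).  Everything is
overridable through the same key structure.
"""

from __future__ import annotations

import copy
import json
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .control import ActiveControlParams, N_SEGMENTS

N_TISSUE_LAYERS = 4
LAYER_NAMES = ("core", "muscle", "fat", "skin", "inner_clothing", "outer_clothing")
WH_TO_J = 3600.0  # capacities configured in W h/degC, held internally in J/K

__all__ = [
    "ConfigError", "ValidationError",
    "BodySegment", "NodeParams", "BodyRegistry", "BodyState",
    "load_default_body", "initial_state",
    "N_SEGMENTS", "N_TISSUE_LAYERS", "LAYER_NAMES",
]


class ConfigError(ValueError):
    """Raised for malformed configuration input (names the offending key)."""


class ValidationError(ValueError):
    """Raised when a registry or state violates a structural invariant."""


@dataclass(frozen=True)
class BodySegment:
    """One body segment: areas (m^2), height (m) and whether it is clothed."""

    index: int          # 1-based
    name: str
    A_n: float          # skin surface area
    A_cl: float         # clothing surface area
    H: float            # segment height
    clothed: bool

    def __post_init__(self) -> None:
        if not (self.A_cl >= self.A_n > 0.0):
            raise ValidationError(
                f"segment {self.index} ({self.name}): require A_cl >= A_n > 0")
        if self.H <= 0.0:
            raise ValidationError(f"segment {self.index}: height must be > 0")
        if not self.clothed and self.A_cl != self.A_n:
            raise ValidationError(
                f"segment {self.index}: bare segments must have A_cl == A_n")


@dataclass(frozen=True)
class NodeParams:
    """Per-node parameters (SI): capacity J/K, basal heat W, blood and
    inter-layer conductances W/K, set-point degC."""

    C: float
    Q_basal: float
    BF_basal: float
    D_cond: float       # conductance to the next-outer layer; 0 for skin
    T_set: float


class BodyRegistry:
    """Validated container for all passive-body parameters.

    Array attributes (numpy, segment-major, 0-based internally):
    ``A_n, A_cl, H, clothed`` (16,), ``C, Q_basal, BF_basal, T_set`` (16, 4),
    ``D_cond`` (16, 3), ``clothing_T_init`` (16, 2).  Capacities are stored
    in J/K.  ``node(i, j)`` gives a 1-based :class:`NodeParams` view.
    """

    def __init__(self, config: dict):
        self._config = copy.deepcopy(config)
        try:
            segs = config["segments"]
            blood = config["blood"]
            control = config["control"]
        except KeyError as exc:
            raise ConfigError(f"missing configuration block: {exc}") from None
        if len(segs) != N_SEGMENTS:
            raise ValidationError(
                f"registry must have exactly {N_SEGMENTS} segments, got {len(segs)}")
        order = sorted(segs, key=lambda s: s["index"])
        if [s["index"] for s in order] != list(range(1, N_SEGMENTS + 1)):
            raise ValidationError("segment indices must be exactly 1..16")
        self.segments: tuple[BodySegment, ...] = tuple(
            BodySegment(index=s["index"], name=s["name"], A_n=s["a_n"],
                        A_cl=s["a_cl"], H=s["height"], clothed=s["clothed"])
            for s in order)
        def grab(key, width):
            out = np.empty((N_SEGMENTS, width))
            for k, s in enumerate(order):
                vals = s[key]
                if len(vals) != width:
                    raise ConfigError(
                        f"segment {s['index']}: '{key}' must have {width} entries")
                out[k] = vals
            return out
        self.C = grab("c_whK", 4) * WH_TO_J
        self.Q_basal = grab("q_basal", 4)
        self.BF_basal = grab("bf_basal", 4)
        self.D_cond = grab("d_cond", 3)
        self.T_set = grab("t_set", 4)
        self.clothing_T_init = grab("t_init_clothing", 2)
        self.A_n = np.array([s.A_n for s in self.segments])
        self.A_cl = np.array([s.A_cl for s in self.segments])
        self.H = np.array([s.H for s in self.segments])
        self.clothed = np.array([s.clothed for s in self.segments], dtype=bool)
        self.blood_capacity = float(blood["capacity_whK"]) * WH_TO_J
        self.blood_T_set = float(blood["t_set"])
        self.control = ActiveControlParams(
            **{k: (np.asarray(v, dtype=float) if isinstance(v, list) else v)
               for k, v in control.items()})
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if np.any(self.C <= 0.0) or self.blood_capacity <= 0.0:
            raise ValidationError("all node heat capacities must be positive")
        if np.any(self.Q_basal < 0.0):
            raise ValidationError("basal metabolic rates must be non-negative")
        if np.any(self.BF_basal < 0.0):
            raise ValidationError("basal blood-flow conductances must be non-negative")
        if np.any(self.D_cond <= 0.0):
            raise ValidationError("inter-layer conductances must be positive for layers 1-3")
        if np.any(self.T_set < 30.0) or np.any(self.T_set > 38.0):
            raise ValidationError("set-point temperatures must lie within [30, 38] degC")

    # -- accessors -------------------------------------------------------
    def node(self, i: int, j: int) -> NodeParams:
        """1-based (segment, layer) access to per-node parameters."""
        if not (1 <= i <= N_SEGMENTS and 1 <= j <= N_TISSUE_LAYERS):
            raise IndexError(f"node ({i}, {j}) out of range")
        k, l = i - 1, j - 1
        d = self.D_cond[k, l] if l < 3 else 0.0
        return NodeParams(C=self.C[k, l], Q_basal=self.Q_basal[k, l],
                          BF_basal=self.BF_basal[k, l], D_cond=d,
                          T_set=self.T_set[k, l])

    def segment_by_name(self, name: str) -> BodySegment:
        for s in self.segments:
            if s.name.lower() == name.lower():
                return s
        raise KeyError(name)

    @property
    def total_basal(self) -> float:
        return float(self.Q_basal.sum())

    @property
    def total_area(self) -> float:
        return float(self.A_n.sum())

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        """The configuration mapping (original units); JSON round-trips
        reproduce every parameter bit-exactly."""
        return copy.deepcopy(self._config)

    @classmethod
    def from_dict(cls, config: dict) -> "BodyRegistry":
        return cls(config)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "BodyRegistry":
        return cls(json.loads(text))


@dataclass
class BodyState:
    """Full temperature state: ``T`` (16, 6) degC (tissue layers 1-4 plus the
    two clothing layers; clothing entries of bare segments simply mirror the
    skin and are inert), blood temperature and elapsed time (s)."""

    T: np.ndarray
    T_blood: float
    t: float = 0.0

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        if self.T.shape != (N_SEGMENTS, 6):
            raise ValidationError(f"state T must be (16, 6), got {self.T.shape}")
        self.check_finite()

    def check_finite(self) -> None:
        bad = ~np.isfinite(self.T) | (self.T < -50.0) | (self.T > 60.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"temperature out of sanity range at segment {i+1}, layer {j+1}")
        if not np.isfinite(self.T_blood) or not (-50.0 < self.T_blood < 60.0):
            raise ValidationError("blood temperature out of sanity range")

    def temperature(self, i: int, j: int) -> float:
        """1-based (segment, layer in 1..6) accessor."""
        return float(self.T[i - 1, j - 1])

    def copy(self) -> "BodyState":
        return BodyState(T=self.T.copy(), T_blood=self.T_blood, t=self.t)


def _deep_merge(base: dict, override: dict, path: str = "") -> dict:
    """Merge override into base, rejecting keys that do not already exist."""
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in out:
            raise ConfigError(f"unknown configuration key: '{here}'")
        if isinstance(out[key], dict) and isinstance(val, dict):
            out[key] = _deep_merge(out[key], val, here)
        else:
            out[key] = copy.deepcopy(val)
    return out


def _default_config() -> dict:
    with resources.files("thermoclo.data").joinpath("body.toml").open("rb") as fh:
        return tomllib.load(fh)


def load_default_body(config_override: dict | str | Path | None = None) -> BodyRegistry:
    """Build the default registry, optionally overridden.

    ``config_override`` may be a nested mapping mirroring the fixture
    structure (``{"blood": {"t_set": ...}, "control": {...}, ...}``; segment
    overrides replace the whole ``segments`` list) or a path to a TOML file
    with the same structure.  Unknown keys raise :class:`ConfigError`.
    """
    cfg = _default_config()
    if config_override is not None:
        if isinstance(config_override, (str, Path)):
            with open(config_override, "rb") as fh:
                config_override = tomllib.load(fh)
        if not isinstance(config_override, dict):
            raise ConfigError("config override must be a mapping or a TOML path")
        cfg = _deep_merge(cfg, config_override)
    return BodyRegistry(cfg)


def initial_state(registry: BodyRegistry) -> BodyState:
    """State with every node at its set-point and the clothing layers at
    their tabulated initial temperatures; t = 0."""
    T = np.empty((N_SEGMENTS, 6))
    T[:, :4] = registry.T_set
    T[:, 4:6] = registry.clothing_T_init
    return BodyState(T=T, T_blood=registry.blood_T_set, t=0.0)
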