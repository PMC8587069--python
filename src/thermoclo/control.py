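"""Active thermoregulation: sweating, vasomotor adjustment and shivering.

The body's regulatory ("active") system is driven by deviations of node
temperatures from their set-points.  The controller follows the classical
Stolwijk structure: a central drive from the head-core (hypothalamic) error
plus an integrated skin signal, distributed over segments by fixed weights,
with a local Q10-style skin-temperature multiplier on sweating.  The paper
lineage of this model family specifies only the set-points, never the
controller equations, so every gain here is configurable and a
``passive_only`` switch reduces the model to its passive heat-transfer
equations (useful for oracle tests).

All control laws are continuous in the state (clamps via max(x, 0)), so the
assembled ODE right-hand side is continuous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_SEGMENTS = 16

__all__ = [
    "ActiveControlParams",
    "ControlSignals",
    "error_signals",
    "sweat_rate",
    "vasomotor",
    "shivering",
]


@dataclass
class ActiveControlParams:
    """Controller gains and distribution weights.

    Gains are in W/K (sweating, shivering) or W/K of skin-blood conductance
    per K of error (dilation); constriction gains are 1/K.  The four weight
    vectors are dimensionless and each sums to 1.
    """

    sweat_gain_core: float = 190.0
    sweat_gain_skin: float = 20.0
    dilation_gain_core: float = 75.0
    dilation_gain_skin: float = 5.0
    constriction_gain_core: float = 0.5
    constriction_gain_skin: float = 0.05
    shiver_gain: float = 20.0
    shiver_max: float = 350.0
    q10_coefficient: float = 10.0
    bf_skin_min: float = 0.05
    work_bf_coupling: float = 1.0
    skin_weights: np.ndarray = field(
        default_factory=lambda: np.full(N_SEGMENTS, 1.0 / N_SEGMENTS))
    sweat_distribution: np.ndarray = field(
        default_factory=lambda: np.full(N_SEGMENTS, 1.0 / N_SEGMENTS))
    dilation_distribution: np.ndarray = field(
        default_factory=lambda: np.full(N_SEGMENTS, 1.0 / N_SEGMENTS))
    work_distribution: np.ndarray = field(
        default_factory=lambda: np.full(N_SEGMENTS, 1.0 / N_SEGMENTS))
    passive_only: bool = False

    def __post_init__(self) -> None:
        for name in ("skin_weights", "sweat_distribution",
                     "dilation_distribution", "work_distribution"):
            w = np.asarray(getattr(self, name), dtype=float)
            if w.shape != (N_SEGMENTS,):
                raise ValueError(f"{name} must have {N_SEGMENTS} entries")
            if np.any(w < 0):
                raise ValueError(f"{name} entries must be non-negative")
            if abs(float(w.sum()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {w.sum()!r})")
            setattr(self, name, w)
        for name in ("sweat_gain_core", "sweat_gain_skin", "dilation_gain_core",
                     "dilation_gain_skin", "constriction_gain_core",
                     "constriction_gain_skin", "shiver_gain", "shiver_max",
                     "q10_coefficient", "bf_skin_min", "work_bf_coupling"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class ControlSignals:
    """Error signals: per-node deviations plus integrated skin signals.

    ``err`` is T(i,j) - T_set(i,j) in K for the four tissue layers;
    ``warm``/``cold`` are the weight-integrated positive/negative parts of
    the skin errors; ``err_head_core`` is the hypothalamic drive.
    """

    err: np.ndarray           # (16, 4), K
    warm: float               # K
    cold: float               # K
    err_head_core: float      # K


def error_signals(state, registry) -> ControlSignals:
    """Compute per-node error signals and the integrated skin signals.

    The warm (cold) signal is the skin-sensor-weighted sum of positive
    (negative) skin-layer errors; for a uniform offset only one of the two
    is non-zero.
    """
    err = np.asarray(state.T)[:, :4] - registry.T_set
    w = registry.control.skin_weights
    skin_err = err[:, 3]
    warm = float(np.sum(w * np.maximum(skin_err, 0.0)))
    cold = float(np.sum(w * np.maximum(-skin_err, 0.0)))
    return ControlSignals(err=err, warm=warm, cold=cold,
                          err_head_core=float(err[0, 0]))


def sweat_rate(signals: ControlSignals, params: ActiveControlParams,
               E_max: np.ndarray) -> np.ndarray:
    """Per-segment evaporative sweat rate, W, clamped to [0, E_max(i)].

    Whole-body command = gain_core * head-core error + gain_skin * (warm -
    cold) skin signal, zero when non-positive; distributed over segments by
    the sweat weights and modulated by a local 2^(err_skin/q10) factor.
    """
    E_max = np.asarray(E_max, dtype=float)
    if params.passive_only:
        return np.zeros_like(E_max)
    drive = (params.sweat_gain_core * signals.err_head_core
             + params.sweat_gain_skin * (signals.warm - signals.cold))
    if drive <= 0.0:
        return np.zeros_like(E_max)
    local = 2.0 ** (signals.err[:, 3] / params.q10_coefficient)
    e_sw = params.sweat_distribution * drive * local
    return np.clip(e_sw, 0.0, np.maximum(E_max, 0.0))


def vasomotor(signals: ControlSignals, params: ActiveControlParams,
              bf_skin_basal: np.ndarray) -> np.ndarray:
    """Skin-blood heat-exchange conductance per segment, W/K.

    flow = (basal + dilation share) / (1 + constriction drive), with a small
    positive floor so skin never thermally detaches from the blood pool.
    Monotone non-decreasing in the warm drive.
    """
    bf_skin_basal = np.asarray(bf_skin_basal, dtype=float)
    if params.passive_only:
        return bf_skin_basal.copy()
    dil = (params.dilation_gain_core * max(signals.err_head_core, 0.0)
           + params.dilation_gain_skin * signals.warm)
    con = (params.constriction_gain_core * max(-signals.err_head_core, 0.0)
           + params.constriction_gain_skin * signals.cold)
    bf = (bf_skin_basal + params.dilation_distribution * dil) / (1.0 + con)
    return np.maximum(bf, params.bf_skin_min)


def shivering(signals: ControlSignals, params: ActiveControlParams) -> np.ndarray:
    """Added metabolic heat from shivering per segment, W (to muscle layer).

    Stolwijk-form product of the core cold error and the integrated cold
    skin signal, bounded by the configured maximum, distributed like work.
    """
    if params.passive_only:
        return np.zeros(N_SEGMENTS)
    total = params.shiver_gain * max(-signals.err_head_core, 0.0) * signals.cold
    total = min(total, params.shiver_max)
    return params.work_distribution * total
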