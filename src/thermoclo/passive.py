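"""Passive-system heat balances: tissue layers and the central blood pool.

Each tissue node obeys C dT/dt = (metabolic heat) - (exchange with blood)
+ (conduction from the next-inner layer) - (conduction to the next-outer
layer), with respiration debited from the chest core and evaporative plus
sensible skin losses debited from the skin layer.  The central blood pool
integrates the node<->blood exchanges: C_b dT_b/dt = sum B(i,j).

The functions here are pure: they combine a state with precomputed fluxes;
assembling those fluxes from the controller and the clothing model is the
simulator's job.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .body import N_SEGMENTS, N_TISSUE_LAYERS, BodyRegistry, BodyState

CHEST = 1  # 0-based index of the chest segment (respiration sink)

__all__ = ["TissueFluxes", "conduction", "blood_exchange", "respiration_loss",
           "tissue_derivatives", "blood_derivative", "CHEST"]


@dataclass
class TissueFluxes:
    """Per-node flux bundle, W.

    ``Q``: metabolic production (16, 4); ``B``: node->blood exchange (16, 4),
    positive when the node loses heat to blood; ``D``: conduction from layer
    j to j+1 (16, 3), positive outward; ``RES``: respiratory loss (chest
    core); ``E_skin``: evaporative skin loss (16,); ``Q_skin_out``: sensible
    skin->clothing-or-environment flux (16,).
    """

    Q: np.ndarray
    B: np.ndarray
    D: np.ndarray
    RES: float
    E_skin: np.ndarray
    Q_skin_out: np.ndarray

    def __post_init__(self) -> None:
        if self.Q.shape != (N_SEGMENTS, N_TISSUE_LAYERS):
            raise ValueError("Q must be (16, 4)")
        if self.B.shape != (N_SEGMENTS, N_TISSUE_LAYERS):
            raise ValueError("B must be (16, 4)")
        if self.D.shape != (N_SEGMENTS, 3):
            raise ValueError("D must be (16, 3)")
        if self.RES < 0.0:
            raise ValueError("respiratory loss must be non-negative")


def conduction(T_inner, T_outer, D_cond):
    """Inter-layer conduction D_cond (T_inner - T_outer), W; positive outward."""
    D = np.asarray(D_cond, dtype=float)
    if np.any(D < 0.0):
        raise ValueError("conductance must be non-negative")
    out = D * (np.asarray(T_inner, dtype=float) - np.asarray(T_outer, dtype=float))
    return float(out) if np.ndim(out) == 0 else out


def blood_exchange(T_node, T_blood, BF):
    """Node->blood exchange BF (T_node - T_blood), W; positive when the node
    loses heat to the blood pool."""
    BF = np.asarray(BF, dtype=float)
    if np.any(BF < 0.0):
        raise ValueError("blood-flow conductance must be non-negative")
    out = BF * (np.asarray(T_node, dtype=float) - T_blood)
    return float(out) if np.ndim(out) == 0 else out


def respiration_loss(M_total: float, T_a: float, p_a: float) -> float:
    """Sensible + latent respiratory loss, W, debited from the chest core.

    Standard correlation RES = 0.0014 M (34 - T_a) + 0.0173 M (5.87 - p_a)
    with M in W and p_a in kPa, clamped at 0 (it vanishes at saturated 34
    degC inspired air).
    """
    if M_total < 0.0:
        raise ValueError("metabolic rate must be non-negative")
    res = 0.0014 * M_total * (34.0 - T_a) + 0.0173 * M_total * (5.87 - p_a)
    return max(res, 0.0)


def tissue_derivatives(state: BodyState, fluxes: TissueFluxes,
                       registry: BodyRegistry) -> np.ndarray:
    """d/dt of the tissue temperatures T(i, 1..4), K/s, shape (16, 4).

    Core:   C dT/dt = Q - B - D(1) - RES
    Muscle: C dT/dt = Q - B + D(1) - D(2)
    Fat:    C dT/dt = Q - B + D(2) - D(3)
    Skin:   C dT/dt = Q - B + D(3) - Q_skin_out - E
    """
    net = fluxes.Q - fluxes.B
    net[:, 0] -= fluxes.D[:, 0]
    net[CHEST, 0] -= fluxes.RES
    net[:, 1] += fluxes.D[:, 0] - fluxes.D[:, 1]
    net[:, 2] += fluxes.D[:, 1] - fluxes.D[:, 2]
    net[:, 3] += fluxes.D[:, 2] - fluxes.Q_skin_out - fluxes.E_skin
    return net / registry.C


def blood_derivative(state: BodyState, fluxes: TissueFluxes,
                     registry: BodyRegistry) -> float:
    """d/dt of the central blood temperature: sum of all B(i,j) over C_blood."""
    return float(fluxes.B.sum() / registry.blood_capacity)
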