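"""Pointwise two-state EVB algebra.

An elementary reaction step is modelled as a 2x2 valence-bond Hamiltonian
whose diagonal elements are the reactant (U1) and product (U2) force-field
energies and whose constant off-diagonal element h12 couples the two states.
The adiabatic ground state is the lower eigenvalue

    Eg = ((U1 + U2) - sqrt((U1 - U2)^2 + 4 h12^2)) / 2

and the squared components of the normalised ground-state eigenvector,
c1^2 + c2^2 = 1, measure the reactant/product character at a configuration.
The gas-phase shift delta_alpha is a constant added to the raw product-state
force-field energy at ingestion (U2 = U2_raw + delta_alpha), encoding the
heat-of-formation difference between the two bonding patterns.

All energies are in kcal/mol, temperatures in kelvin; the generalized
reaction coordinate is the energy gap dU = U1 - U2 (reactant minus product).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateStateError, InvalidInputError

#: Gas constant in kcal/(mol K).
R_GAS = 1.987204e-3


@dataclass(frozen=True)
class EVBParameters:
    """The two calibration constants of a two-state EVB model.

    Parameters
    ----------
    h12 : float
        Off-diagonal coupling (kcal/mol), constant, >= 0.
    delta_alpha : float
        Gas-phase shift added to the product state (kcal/mol), any sign.
    """

    h12: float
    delta_alpha: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.h12) and math.isfinite(self.delta_alpha)):
            raise InvalidInputError("EVB parameters must be finite")
        if self.h12 < 0.0:
            raise InvalidInputError(f"h12 must be >= 0, got {self.h12}")

    def shifted(self, dh12: float = 0.0, ddelta_alpha: float = 0.0) -> "EVBParameters":
        """Return a copy with h12 and delta_alpha shifted by the given amounts."""
        return EVBParameters(self.h12 + dh12, self.delta_alpha + ddelta_alpha)


@dataclass(frozen=True)
class DiabaticPoint:
    """Diabatic energies at one configuration; ``u2`` already includes delta_alpha."""

    u1: float
    u2: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.u1) and math.isfinite(self.u2)):
            raise InvalidInputError("diabatic energies must be finite")

    @property
    def gap(self) -> float:
        """Energy gap dU = u1 - u2, the generalized reaction coordinate."""
        return self.u1 - self.u2


@dataclass(frozen=True)
class StateWeights:
    """Squared ground-state eigenvector components (c1^2, c2^2), summing to 1."""

    c1_sq: float
    c2_sq: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.c1_sq <= 1.0 and 0.0 <= self.c2_sq <= 1.0):
            raise InvalidInputError("state weights must lie in [0, 1]")
        if abs(self.c1_sq + self.c2_sq - 1.0) > 1e-9:
            raise InvalidInputError("state weights must sum to 1")

    @classmethod
    def from_c1_sq(cls, c1_sq: float) -> "StateWeights":
        return cls(c1_sq, 1.0 - c1_sq)


def _check_finite(*arrays) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise InvalidInputError("non-finite diabatic energy")


def ground_state_energy(u1, u2, h12):
    """Lower eigenvalue of the 2x2 EVB Hamiltonian (vectorised).

    Parameters
    ----------
    u1, u2 : array_like
        Diabatic energies (kcal/mol); ``u2`` must already include delta_alpha.
    h12 : float
        Constant off-diagonal coupling (kcal/mol).

    Returns
    -------
    ndarray or float
        Eg <= min(u1, u2), with equality iff h12 = 0.
    """
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    _check_finite(u1, u2, h12)
    eg = 0.5 * ((u1 + u2) - np.hypot(u1 - u2, 2.0 * h12))
    return eg if eg.ndim else float(eg)

def state_coefficients(u1, u2, h12):
    """Squared components of the normalised ground-state eigenvector.

    For delta = u2 - u1,

        c1^2 = (1 + delta / sqrt(delta^2 + 4 h12^2)) / 2,   c2^2 = 1 - c1^2.

    Raises
    ------
    DegenerateStateError
        If h12 = 0 and u1 = u2 anywhere (eigenvector undefined).
    """
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    _check_finite(u1, u2, h12)
    delta = u2 - u1
    if h12 == 0.0 and np.any(delta == 0.0):
        raise DegenerateStateError(
            "state coefficients undefined for h12 = 0 with u1 = u2"
        )
    c1_sq = 0.5 * (1.0 + delta / np.hypot(delta, 2.0 * h12))
    c2_sq = 1.0 - c1_sq
    if c1_sq.ndim:
        return c1_sq, c2_sq
    return StateWeights(float(c1_sq), float(c2_sq))


def ground_state_weights(point: DiabaticPoint, par: EVBParameters) -> StateWeights:
    """StateWeights at a single diabatic point (scalar convenience wrapper)."""
    return state_coefficients(point.u1, point.u2, par.h12)


def energy_gap(u1, u2):
    """Energy-gap coordinate dU = u1 - u2 (u2 includes delta_alpha)."""
    return np.asarray(u1, dtype=float) - np.asarray(u2, dtype=float)


def ground_state_gradient(grad_u1, grad_u2, weights: StateWeights):
    """Gradient of Eg for constant h12 (Hellmann-Feynman form).

    dEg/dx = c1^2 dU1/dx + c2^2 dU2/dx, componentwise.
    """
    g1 = np.asarray(grad_u1, dtype=float)
    g2 = np.asarray(grad_u2, dtype=float)
    if g1.shape != g2.shape:
        raise InvalidInputError(
            f"gradient shapes differ: {g1.shape} vs {g2.shape}"
        )
    _check_finite(g1, g2)
    return weights.c1_sq * g1 + weights.c2_sq * g2
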