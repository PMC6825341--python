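"""Piecewise contact-restraint energy.

The well is flat at -U_ij up to the 8 Å contact distance, rises through a
half-sine to zero at the length-dependent inflection d2, continues through a
second half-sine to +U_ij at 80 Å, and stays flat beyond:

    E(d) = -U                                          d <= 8
         = -(U/2) [1 - sin((d - (8+d2)/2)/(d2-8) pi)]  8 < d <= d2
         =  (U/2) [1 + sin((d - (80+d2)/2)/(80-d2) pi)] d2 < d < 80
         =  U                                          d >= 80

d2 ranges from 14 to 24 Å with chain length.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .contact_consensus import ConsensusContactSet
    from .folding_engine import ChainConformation

D_CONTACT = 8.0
D_FAR = 80.0
D2_MIN = 14.0
D2_MAX = 24.0
#: chain-length window over which d2 interpolates linearly
D2_L_MIN = 50
D2_L_MAX = 350


def d2_for_length(L: int) -> float:
    """Length-dependent well inflection distance.

    Clamped linear map from chain length onto [14, 24] Å over
    L in [50, 350]; the simplest monotone rule spanning the range.
    """
    if L < 2:
        raise ValueError("chain length must be at least 2")
    frac = np.clip((L - D2_L_MIN) / (D2_L_MAX - D2_L_MIN), 0.0, 1.0)
    return float(D2_MIN + (D2_MAX - D2_MIN) * frac)


@dataclass(frozen=True)
class RestraintParams:
    d2: float
    d_contact: float = D_CONTACT
    d_far: float = D_FAR

    def __post_init__(self):
        if not (self.d_contact < self.d2 < self.d_far):
            raise ValueError(
                f"d2={self.d2} must lie in ({self.d_contact}, {self.d_far})")

    @classmethod
    def from_length(cls, L: int) -> "RestraintParams":
        return cls(d2=d2_for_length(L))


def contact_energy(d_ij, u_ij: float, d2: float):
    """Evaluate the piecewise restraint well (scalar or array distances)."""
    if np.any(np.asarray(d_ij) < 0):
        raise ValueError("distances must be non-negative")
    if u_ij <= 0:
        raise ValueError("U_ij must be positive")
    if not (D_CONTACT < d2 < D_FAR):
        raise ValueError(f"d2 must lie in ({D_CONTACT}, {D_FAR})")
    d = np.asarray(d_ij, dtype=float)
    rising = -(u_ij / 2.0) * (
        1.0 - np.sin((d - (D_CONTACT + d2) / 2.0) / (d2 - D_CONTACT) * np.pi))
    upper = (u_ij / 2.0) * (
        1.0 + np.sin((d - (D_FAR + d2) / 2.0) / (D_FAR - d2) * np.pi))
    e = np.select(
        [d <= D_CONTACT, d <= d2, d < D_FAR],
        [-u_ij, rising, upper],
        default=u_ij)
    if np.isscalar(d_ij) or np.ndim(d_ij) == 0:
        return float(e)
    return e


def restraint_energy(conf: "ChainConformation", cs: "ConsensusContactSet",
                     params: RestraintParams) -> float:
    """Sum of the contact well over all consensus contacts, measured on
    Cβ-Cβ distances."""
    if len(cs) == 0:
        return 0.0
    idx_i = np.array([c.i - 1 for c in cs.contacts])
    idx_j = np.array([c.j - 1 for c in cs.contacts])
    if idx_j.max() >= conf.n_res:
        raise IndexError(
            f"contact index {idx_j.max() + 1} exceeds chain length "
            f"{conf.n_res}")
    u = np.array([c.u for c in cs.contacts])
    d = np.linalg.norm(conf.cb[idx_i] - conf.cb[idx_j], axis=1)
    # vectorised evaluation of the same piecewise form, per-pair weights
    rising = -(u / 2.0) * (
        1.0 - np.sin((d - (D_CONTACT + params.d2) / 2.0)
                     / (params.d2 - D_CONTACT) * np.pi))
    upper = (u / 2.0) * (
        1.0 + np.sin((d - (D_FAR + params.d2) / 2.0)
                     / (D_FAR - params.d2) * np.pi))
    e = np.select(
        [d <= D_CONTACT, d <= params.d2, d < D_FAR, d >= D_FAR],
        [-u, rising, upper, u])
    return float(e.sum())
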