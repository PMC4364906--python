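"""Biexponential plasma pharmacokinetics of the ADC.

The systemic forcing function is a classic two-compartment antibody profile:
a fast alpha (distribution) phase and a slow beta (elimination) phase,

    C_plasma(t) = C0 · [A·exp(−ka·t) + B·exp(−kb·t)],   A + B = 1.

Axial concentration differences along the capillary are neglected (antibody
extravasation is slow relative to blood flow), so a single plasma
concentration drives the whole Krogh cylinder. Repeated IV boluses are
handled by linear superposition of identical biexponentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .params import ParameterSet, derive_parameters, normalize_units

__all__ = ["PlasmaModel", "plasma_concentration"]


@dataclass(frozen=True)
class PlasmaModel:
    """Biexponential plasma concentration (internal units: hours, nM).

    Parameters
    ----------
    C0 : float
        Initial plasma concentration per dose, nM.
    A, B : float
        Fractions of the alpha and beta clearance phases (sum to 1).
    ka, kb : float
        Clearance rates of the two phases, 1/hr.
    dose_times : tuple of float
        Administration times in hours (default: a single bolus at t = 0).
    """

    C0: float
    A: float
    B: float
    ka: float
    kb: float
    dose_times: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        if abs(self.A + self.B - 1.0) > 1e-12:
            raise ValueError(f"A + B must equal 1, got A={self.A}, B={self.B}")
        if self.C0 < 0 or self.ka < 0 or self.kb < 0:
            raise ValueError("C0, ka and kb must be >= 0")

    @classmethod
    def from_parameters(cls, params: ParameterSet,
                        dose_times: Sequence[float] = (0.0,)) -> "PlasmaModel":
        p = normalize_units(params)
        d = derive_parameters(p)
        return cls(C0=d.C0, A=p.A, B=p.B, ka=p.ka, kb=p.kb,
                   dose_times=tuple(sorted(dose_times)))

    def concentration(self, t):
        """Plasma concentration (nM) at time(s) ``t`` (hours).

        Before the first administration the concentration is zero.
        """
        return plasma_concentration(self, t)


def plasma_concentration(model: PlasmaModel, t):
    """Evaluate ``model`` at scalar or array time ``t`` (hours, >= 0)."""
    t_arr = np.asarray(t, dtype=float)
    out = np.zeros_like(t_arr)
    for tau in model.dose_times:
        dt = t_arr - tau
        active = dt >= 0
        out = out + np.where(
            active,
            model.C0 * (
                model.A * np.exp(-model.ka * np.where(active, dt, 0.0))
                + model.B * np.exp(-model.kb * np.where(active, dt, 0.0))
            ),
            0.0,
        )
    if np.isscalar(t):
        return float(out)
    return out
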