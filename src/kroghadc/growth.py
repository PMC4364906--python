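"""Proliferating/quiescent tumor-mass dynamics with a payload kill switch.

Tumor cell mass at each node splits into proliferating mass P (cycling,
drug-sensitive) and quiescent mass Q, with Γ = P + Q normalized to 1 at
t = 0:

    dP/dt = (γ − α − k_kill·(Cp/Γ)·E50)·P + β·Q
    dQ/dt = α·P − β·Q

γ is the relative growth rate of cycling cells, α the proliferating→
quiescent transition rate, β the reverse transition, and the kill term acts
on proliferating cells only. γ and α are fixed by two constraints: total
drug-free mass doubles at the tumor doubling time td, and the
proliferating-to-quiescent ratio stays at rt (see
:func:`kroghadc.params.growth_rates`).

The payload effect is an all-or-nothing Hill switch on the cell-mass-
normalized cytosolic payload x = Cp/Γ:

    E50 = x^h / (x^h + IC50^h)

with a very steep Hill coefficient (nominal h = 100), so killing engages
only once x exceeds IC50. E50 is evaluated in log space; naive powers
overflow at h = 100. k_kill (``kill_rate_scale``, nominal 1/(nM·day))
converts the nM-valued product (Cp/Γ)·E50 into a first-order kill rate.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["hill_effect", "growth_rhs"]

_GAMMA_GUARD = 1e-12


def hill_effect(Cp, Gamma, IC50, h):
    """Hill switch E50 = x^h/(x^h + IC50^h), x = Cp/Γ, in [0, 1).

    Computed as a logistic in log space, stable for arbitrarily large Hill
    coefficients. Where Γ falls below 1e-12 (dead tissue) the normalized
    payload is treated as 0.
    """
    Cp = np.asarray(Cp, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    x = np.where(Gamma > _GAMMA_GUARD, Cp / np.maximum(Gamma, _GAMMA_GUARD), 0.0)
    with np.errstate(divide="ignore"):
        logratio = np.log(np.maximum(x, 0.0)) - np.log(IC50)
    out = expit(h * logratio)
    out = np.where(x <= 0.0, 0.0, out)
    if out.ndim == 0:
        return float(out)
    return out


def growth_rhs(P, Q, Cp, gamma, alpha, beta, kill_rate_scale, IC50, h):
    """Rates (dP/dt, dQ/dt) of the proliferating/quiescent system.

    All rate constants in consistent units (internal: 1/hr and 1/(nM·hr));
    ``Cp`` is the node-local cytosolic payload (nM) and the normalizing Γ is
    the node-local P + Q.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    Gamma = P + Q
    e50 = hill_effect(Cp, Gamma, IC50, h)
    x = np.where(Gamma > _GAMMA_GUARD, np.asarray(Cp, dtype=float) /
                 np.maximum(Gamma, _GAMMA_GUARD), 0.0)
    kill = kill_rate_scale * x * e50
    dP = (gamma - alpha - kill) * P + beta * Q
    dQ = alpha * P - beta * Q
    return dP, dQ
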