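"""Local (per-node) binding, endocytic trafficking and payload kinetics.

Species at each radial node, all on a total-tissue-volume basis (nM):

==========  ===========================================================
``C``       free ADC in the interstitium
``T``       free surface receptor
``B``       surface ADC-receptor complex
``Te``      endosomal free receptor
``Be``      endosomal ADC-receptor complex
``Cp``      intracellular (cytosolic) payload
``Cp_ext``  interstitial payload
==========  ===========================================================

Free ADC and receptor are confined to the interstitial volume, so their
effective concentrations in the binding law are the tissue values divided by
the void fraction ε; the free-receptor concentration additionally scales
with local tumor cell mass Γ. Receptors are synthesized at a constant rate
Rs, internalize at kinT, and exit endosomes at keT with a fraction feT
recycling to the surface and (1−feT) degraded in lysosomes; the complex
traffics analogously with kinB, keB, feB. Lysosomal degradation of the
complex releases DAR payload molecules per antibody into the cytosol
(non-cleavable linkers); with cleavable linkers the payload is instead
released on endosomal entry of the complex. Cytosolic payload effluxes at
kout = ln2/tp and, when bystander re-entry is enabled, re-enters from the
interstitium at kin_payload (interstitial concentration again divided by ε).
"""

from __future__ import annotations

import numpy as np

__all__ = ["binding_flux", "trafficking_rhs", "payload_rhs"]


def binding_flux(C, T, B, Gamma, kon, koff, eps, single_eps=False):
    """Net forward binding rate Rxn (nM/hr).

    Default reading divides both interstitium-restricted concentrations by
    the void fraction: Rxn = kon·(C/ε)·(T/ε)·Γ − koff·B. With
    ``single_eps=True`` only the ADC concentration is scaled (sensitivity
    variant): Rxn = kon·(C/ε)·T·Γ − koff·B.
    """
    if single_eps:
        return kon * (C / eps) * T * Gamma - koff * B
    return kon * (C / eps) * (T / eps) * Gamma - koff * B


def trafficking_rhs(T, Te, B, Be, Rxn, Rs, kinT, keT, feT, kinB, keB, feB):
    """Receptor and complex trafficking rates (dT, dB, dTe, dBe), nM/hr.

    Degraded complexes (fraction 1−feB of endosomal exits) leave the
    receptor pool; recycled complexes return to the surface unchanged.
    """
    dT = Rs - Rxn - kinT * T + keT * feT * Te
    dB = Rxn - kinB * B + keB * feB * Be
    dTe = kinT * T - keT * Te
    dBe = kinB * B - keB * Be
    return dT, dB, dTe, dBe


def payload_rhs(B, Be, Cp, Cp_ext, DAR, kout, kin_payload, eps,
                keB, feB, kinB, cleavage_site="lysosomal"):
    """Local payload rates (dCp, dCp_ext), nM/hr, excluding diffusion.

    The payload source is ``keB·(1−feB)·Be·DAR`` for lysosomal release
    (non-cleavable linker) or ``kinB·B·DAR`` for endosomal release
    (cleavable linker). Diffusion of ``Cp_ext`` is applied by the grid
    operator, not here.
    """
    if cleavage_site == "lysosomal":
        release = keB * (1.0 - feB) * Be * DAR
    elif cleavage_site == "endosomal":
        release = kinB * B * DAR
    else:
        raise ValueError(
            f"cleavage_site must be 'lysosomal' or 'endosomal', got "
            f"{cleavage_site!r}"
        )
    reentry = kin_payload * Cp_ext / eps
    dCp = release - kout * Cp + reentry
    dCp_ext = kout * Cp - reentry
    return dCp, dCp_ext
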