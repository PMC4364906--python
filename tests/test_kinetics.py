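"""Binding, receptor trafficking and payload release kernels."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from kroghadc import (
    binding_flux,
    derive_parameters,
    nominal_parameters,
    normalize_units,
    payload_rhs,
    trafficking_rhs,
)


@pytest.fixture
def p():
    return normalize_units(nominal_parameters())


@pytest.fixture
def d(p):
    return derive_parameters(p)


class TestBindingFlux:
    def test_direct_value(self):
        # kon (C/eps)(T/eps) Γ with C=10, T=77.4, eps=0.24, kon=0.36
        got = binding_flux(10.0, 77.4, 0.0, 1.0, kon=0.36, koff=0.036,
                           eps=0.24)
        assert got == pytest.approx(0.36 * (10 / 0.24) * (77.4 / 0.24),
                                    rel=1e-12)
        assert got == pytest.approx(4.8375e3, rel=1e-3)

    def test_zero_and_equilibrium(self):
        assert binding_flux(0.0, 50.0, 0.0, 1.0, 0.36, 0.036, 0.24) == 0.0
        kon, koff, eps = 0.36, 0.036, 0.24
        C, T, G = 5.0, 30.0, 0.8
        Beq = kon * (C / eps) * (T / eps) * G / koff
        assert binding_flux(C, T, Beq, G, kon, koff, eps) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_single_eps_variant(self):
        kw = dict(C=10.0, T=77.4, B=0.0, Gamma=1.0, kon=0.36, koff=0.036,
                  eps=0.24)
        assert binding_flux(**kw, single_eps=True) == pytest.approx(
            0.24 * binding_flux(**kw, single_eps=False)
        )

    def test_scales_with_local_cell_mass(self):
        base = binding_flux(10.0, 77.4, 0.0, 1.0, 0.36, 0.036, 0.24)
        half = binding_flux(10.0, 77.4, 0.0, 0.5, 0.36, 0.036, 0.24)
        assert half == pytest.approx(0.5 * base)


class TestTrafficking:
    def test_drug_free_steady_state(self, p, d):
        Te = p.kinT * d.Tinit / p.keT
        rates = trafficking_rhs(d.Tinit, Te, 0.0, 0.0, Rxn=0.0, Rs=d.Rs,
                                kinT=p.kinT, keT=p.keT, feT=p.feT,
                                kinB=p.kinB, keB=p.keB, feB=p.feB)
        np.testing.assert_allclose(rates, 0.0, atol=1e-12 * d.Tinit)

    def test_full_recycling_conserves_receptor(self, p):
        # feT = 1, no synthesis, no drug: T + Te has no loss pathway
        dT, _, dTe, _ = trafficking_rhs(40.0, 10.0, 0.0, 0.0, Rxn=0.0, Rs=0.0,
                                        kinT=p.kinT, keT=p.keT, feT=1.0,
                                        kinB=p.kinB, keB=p.keB, feB=p.feB)
        assert dT + dTe == pytest.approx(0.0, abs=1e-12)

    def test_no_internalization_isolates_surface_complex(self, p):
        rxn = 2.5
        _, dB, _, dBe = trafficking_rhs(40.0, 10.0, 5.0, 1.0, Rxn=rxn, Rs=0.0,
                                        kinT=p.kinT, keT=p.keT, feT=p.feT,
                                        kinB=0.0, keB=p.keB, feB=p.feB)
        assert dB == pytest.approx(rxn + p.keB * p.feB * 1.0)
        assert dBe == pytest.approx(-p.keB * 1.0)


class TestPayload:
    def test_zero_sources(self, p, d):
        for site in ("lysosomal", "endosomal"):
            dCp, dExt = payload_rhs(0.0, 0.0, 0.0, 0.0, p.DAR, d.kout,
                                    0.0, p.eps, p.keB, p.feB, p.kinB,
                                    cleavage_site=site)
            assert dCp == 0.0 and dExt == 0.0

    def test_dar_linearity(self, p, d):
        one, _ = payload_rhs(2.0, 3.0, 0.0, 0.0, 1.0, d.kout, 0.0, p.eps,
                             p.keB, p.feB, p.kinB)
        six, _ = payload_rhs(2.0, 3.0, 0.0, 0.0, 6.0, d.kout, 0.0, p.eps,
                             p.keB, p.feB, p.kinB)
        assert six == pytest.approx(6 * one)

    def test_unknown_cleavage_site(self, p, d):
        with pytest.raises(ValueError, match="cleavage_site"):
            payload_rhs(1.0, 1.0, 0.0, 0.0, p.DAR, d.kout, 0.0, p.eps,
                        p.keB, p.feB, p.kinB, cleavage_site="membrane")

    def test_steady_state_release_over_efflux(self, p, d):
        # constant release R: Cp -> R / kout
        Be = 5.0
        release = p.keB * (1 - p.feB) * Be * p.DAR

        def rhs(t, y):
            dCp, _ = payload_rhs(0.0, Be, y[0], 0.0, p.DAR, d.kout, 0.0,
                                 p.eps, p.keB, p.feB, p.kinB)
            return [dCp]

        sol = solve_ivp(rhs, (0.0, 20.0 / d.kout), [0.0], rtol=1e-10,
                        atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(release / d.kout, rel=1e-6)

    def test_mass_balance_against_dar(self, p, d):
        # kout = 0, no re-entry: cytosolic payload equals DAR x cumulative
        # degraded complex; track the cumulative integral as extra state.
        kinB, keB, feB, DAR = p.kinB, p.keB, p.feB, p.DAR
        rxn = 1.0  # constant binding source feeding B

        def rhs(t, y):
            B, Be, Cp, cum_degraded = y
            dB = rxn - kinB * B + keB * feB * Be
            dBe = kinB * B - keB * Be
            dCp, _ = payload_rhs(B, Be, Cp, 0.0, DAR, 0.0, 0.0, p.eps,
                                 keB, feB, kinB)
            return [dB, dBe, dCp, keB * (1 - feB) * Be]

        sol = solve_ivp(rhs, (0.0, 50.0), [0.0, 0.0, 0.0, 0.0],
                        rtol=1e-10, atol=1e-13)
        B, Be, Cp, cum = sol.y[:, -1]
        assert Cp == pytest.approx(DAR * cum, rel=1e-6)

    def test_endosomal_release_dominates(self, p, d):
        # along any complex trajectory, cumulative endosomal release
        # (kinB·B·DAR) exceeds cumulative lysosomal release when feB > 0
        kinB, keB, feB, DAR = p.kinB, p.keB, p.feB, p.DAR
        rxn = 1.0

        def rhs(t, y):
            B, Be, cum_lyso, cum_endo = y
            dB = rxn * np.exp(-0.5 * t) - kinB * B + keB * feB * Be
            dBe = kinB * B - keB * Be
            return [dB, dBe, keB * (1 - feB) * Be * DAR, kinB * B * DAR]

        sol = solve_ivp(rhs, (0.0, 100.0), [0.0] * 4, rtol=1e-9, atol=1e-12)
        cum_lyso, cum_endo = sol.y[2, -1], sol.y[3, -1]
        assert cum_endo > cum_lyso > 0.0
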