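"""Parameter validation, unit normalization and derived quantities."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from kroghadc import (
    ParameterError,
    ParameterSet,
    derive_parameters,
    dump_config,
    growth_rates,
    initial_plasma_concentration,
    initial_receptor_concentration,
    load_config,
    nominal_parameters,
    normalize_units,
    payload_efflux_rate,
    to_table_units,
)


class TestUnitNormalization:
    def test_known_conversions(self):
        p = normalize_units(nominal_parameters())
        assert p.unit_system == "internal"
        assert p.D == pytest.approx(4.68e4)          # 1.3e-7 cm²/s in μm²/hr
        assert p.kon == pytest.approx(0.36)          # 6e-3 /(nM·min) in /(nM·hr)
        assert p.kb == pytest.approx(0.17 / 24.0)    # 1/day -> 1/hr
        assert p.Pvasc == pytest.approx(2.8e-7 * 3.6e7)
        assert p.kinT == pytest.approx(0.6)          # 0.01/min -> 0.6/hr
        assert p.ka == 0.6                           # already 1/hr

    def test_involutive(self):
        p = normalize_units(nominal_parameters())
        assert normalize_units(p) is p

    @given(
        D=st.floats(1e-8, 1e-6),
        kb=st.floats(0.01, 1.0),
        kon=st.floats(1e-4, 1.0),
        td=st.floats(1.0, 40.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_round_trip(self, D, kb, kon, td):
        p = nominal_parameters(D=D, kb=kb, kon=kon, td=td)
        back = to_table_units(normalize_units(p))
        for f in dataclasses.fields(ParameterSet):
            a, b = getattr(p, f.name), getattr(back, f.name)
            if isinstance(a, float):
                assert b == pytest.approx(a, rel=1e-14), f.name
            else:
                assert a == b, f.name

    @pytest.mark.parametrize(
        "field,value",
        [("eps", 1.2), ("eps", 0.0), ("feT", -0.1), ("kon", -1.0),
         ("td", 0.0), ("rt", 0.0), ("tp", -7.0), ("cleavage_site", "golgi")],
    )
    def test_validation_names_field(self, field, value):
        with pytest.raises(ParameterError, match=field):
            nominal_parameters(**{field: value})

    def test_ab_and_geometry_invariants(self):
        with pytest.raises(ParameterError, match="A \\+ B"):
            nominal_parameters(A=0.7)
        with pytest.raises(ParameterError, match="RKrogh"):
            nominal_parameters(RKrogh=5.0)


class TestDerivedQuantities:
    def test_initial_receptor_concentration(self):
        # direct evaluation: 1e5 / (6.022e23 * 4/3π·8³ μm³ in litres)
        assert initial_receptor_concentration(1e5, 8.0) == pytest.approx(
            77.43, rel=1e-3
        )
        assert initial_receptor_concentration(0.0, 8.0) == 0.0
        assert initial_receptor_concentration(2e5, 8.0) == pytest.approx(
            2 * initial_receptor_concentration(1e5, 8.0)
        )

    def test_payload_efflux_rate(self):
        assert payload_efflux_rate(7.0) == pytest.approx(math.log(2) / 7)
        assert payload_efflux_rate(math.log(2)) == pytest.approx(1.0)
        assert payload_efflux_rate(1e12) == pytest.approx(0.0, abs=1e-11)
        with pytest.raises(ParameterError):
            payload_efflux_rate(0.0)

    def test_growth_rates_closed_form(self):
        gamma, alpha = growth_rates(10.0, 0.1 / 0.9, 0.05)
        assert gamma == pytest.approx(0.6931, rel=1e-3)
        assert alpha == pytest.approx(1.0738, rel=1e-3)
        g0, a0 = growth_rates(10.0, 1.0, 0.0)
        assert g0 == pytest.approx(2 * math.log(2) / 10)
        assert a0 == pytest.approx(math.log(2) / 10)

    @pytest.mark.parametrize("td,rt,beta", [(10.0, 0.1 / 0.9, 0.05),
                                            (5.0, 0.4, 0.0),
                                            (20.0, 1.0, 0.2)])
    def test_growth_rates_doubling_oracle(self, td, rt, beta):
        # independent oracle: matrix exponential of the drug-free linear system
        gamma, alpha = growth_rates(td, rt, beta)
        M = np.array([[gamma - alpha, beta], [alpha, -beta]])
        p0 = np.array([rt, 1.0]) / (1.0 + rt)
        pt = expm(M * td) @ p0
        assert pt.sum() == pytest.approx(2.0, rel=1e-9)
        # (rt, 1) is an eigenvector with eigenvalue ln2/td
        assert pt / p0 == pytest.approx(np.full(2, 2.0), rel=1e-9)

    def test_initial_plasma_concentration(self):
        assert initial_plasma_concentration(1.0) == pytest.approx(66.67, rel=1e-3)
        assert initial_plasma_concentration(0.0) == 0.0
        assert initial_plasma_concentration(30.0) == pytest.approx(
            30 * initial_plasma_concentration(1.0)
        )

    def test_receptor_synthesis_closure(self):
        p = normalize_units(nominal_parameters())
        d = derive_parameters(p)
        assert d.Rs == pytest.approx(p.kinT * (1 - p.feT) * d.Tinit)
        assert d.koff == pytest.approx(p.kon * p.KD)


class TestConfigIO:
    def test_nominal_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        dump_config(nominal_parameters(), str(path))
        loaded = load_config(str(path))
        assert loaded == nominal_parameters()
        assert loaded.rt == 0.1 / 0.9

    def test_preset_shortcut_and_overrides(self):
        p = load_config({"preset": "nominal", "dose": 10})
        assert p.dose == 10.0
        assert p.KD == 0.1

    def test_unknown_key_rejected(self):
        with pytest.raises(ParameterError, match="bogus"):
            load_config({"bogus": 1.0})

    def test_units_block_must_match_contract(self):
        assert load_config({"units": {"D": "cm^2/s"}}) == nominal_parameters()
        with pytest.raises(ParameterError, match="units"):
            load_config({"units": {"D": "m^2/s"}})
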