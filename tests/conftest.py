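"""Shared fixtures: expensive reference simulations computed once per session."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import pytest

from kroghadc import (
    TumorPenetrationModel,
    nominal_parameters,
    payload_efflux_rate,
)

RECEPTOR_DENSITIES = (1e3, 1e4, 1e5, 1e6)
BYSTANDER_RATIOS = (0.0, 1.0, 10.0, 100.0)


@pytest.fixture(scope="session")
def nominal_result():
    """Nominal single-dose 1 mg/kg simulation at the default 1 μm grid."""
    return TumorPenetrationModel(nominal_parameters()).run(
        snapshot_times=[24.0, 72.0]
    )


@pytest.fixture(scope="session")
def nrec_results(nominal_result):
    """Receptor-density sweep at 1 mg/kg, KD = 0.1 nM, 30-day horizon."""
    out = {}
    for nrec in RECEPTOR_DENSITIES:
        if nrec == nominal_parameters().nRec:
            out[nrec] = nominal_result
            continue
        out[nrec] = TumorPenetrationModel(
            nominal_parameters(nRec=nrec)
        ).run(snapshot_times=[24.0, 72.0])
    return out


@pytest.fixture(scope="session")
def bystander_results(nominal_result):
    """Payload re-entry sweep: kin = ratio * kout at otherwise nominal values."""
    kout = payload_efflux_rate(nominal_parameters().tp)
    out = {}
    for ratio in BYSTANDER_RATIOS:
        if ratio == 0.0:
            out[ratio] = nominal_result
            continue
        out[ratio] = TumorPenetrationModel(
            nominal_parameters(kin_payload=ratio * kout)
        ).run()
    return out
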