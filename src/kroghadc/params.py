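"""Model parameters, unit normalization, and derived quantities.

The simulator's inputs are the physical parameters of a mouse-xenograft
Krogh-cylinder ADC model: plasma clearance fractions and rates, tissue
geometry and transport coefficients, receptor binding/trafficking kinetics,
payload release and efflux kinetics, and tumor growth constants.

Two unit systems coexist:

* the *table* system — the units in which the parameters are conventionally
  reported (mixed 1/min, 1/hr, 1/day, cm/s, cm²/s, μm, nM);
* the *internal* system — hours / micrometres / nanomolar, in which every
  rate is 1/hour and every diffusivity μm²/hour. All numerical kernels
  operate in internal units; working at μm scale avoids the tiny magnitudes
  that cm²/s diffusivities would produce on a micrometre grid.

:class:`ParameterSet` carries a ``unit_system`` tag so that conversion is
explicit, involutive and reversible.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, fields, replace
from typing import Any, Mapping

import yaml

__all__ = [
    "AVOGADRO",
    "ParameterSet",
    "DerivedParameters",
    "nominal_parameters",
    "normalize_units",
    "to_table_units",
    "derive_parameters",
    "initial_receptor_concentration",
    "payload_efflux_rate",
    "growth_rates",
    "initial_plasma_concentration",
    "load_config",
    "dump_config",
    "ParameterError",
]

AVOGADRO = 6.02214076e23  # 1/mol

#: Multiplicative factor taking each field from table units to internal units
#: (hours / μm / nM). Fields absent here are identical in both systems.
_TO_INTERNAL: dict[str, float] = {
    "kb": 1.0 / 24.0,            # 1/day -> 1/hr
    "Pvasc": 3.6e7,              # cm/s -> μm/hr
    "D": 3.6e11,                 # cm²/s -> μm²/hr
    "Dp": 3.6e11,                # cm²/s -> μm²/hr
    "Pvasc_payload": 3.6e7,      # cm/s -> μm/hr
    "kon": 60.0,                 # 1/(nM·min) -> 1/(nM·hr)
    "kinT": 60.0,                # 1/min -> 1/hr
    "keT": 60.0,
    "kinB": 60.0,
    "keB": 60.0,
    "beta": 1.0 / 24.0,          # 1/day -> 1/hr
    "td": 24.0,                  # day -> hr
    "kill_rate_scale": 1.0 / 24.0,  # 1/(nM·day) -> 1/(nM·hr)
    "sim_horizon": 24.0,         # day -> hr
}

#: Declared external (table) units, the configuration-file contract.
TABLE_UNITS: dict[str, str] = {
    "A": "fraction",
    "B": "fraction",
    "ka": "1/hr",
    "kb": "1/day",
    "RKrogh": "um",
    "Rcap": "um",
    "Pvasc": "cm/s",
    "D": "cm^2/s",
    "kon": "1/(nM*min)",
    "KD": "nM",
    "eps": "fraction",
    "kinT": "1/min",
    "keT": "1/min",
    "feT": "fraction",
    "kinB": "1/min",
    "keB": "1/min",
    "feB": "fraction",
    "tp": "hr",
    "kin_payload": "1/hr",
    "DAR": "dimensionless",
    "Dp": "cm^2/s",
    "Pvasc_payload": "cm/s",
    "beta": "1/day",
    "td": "day",
    "rt": "dimensionless",
    "IC50": "nM",
    "h": "dimensionless",
    "nRec": "count",
    "Rcell": "um",
    "dose": "mg/kg",
    "body_weight": "g",
    "plasma_volume": "mL",
    "adc_molar_mass": "g/mol",
    "kill_rate_scale": "1/(nM*day)",
    "sim_horizon": "day",
    "grid_step": "um",
}


class ParameterError(ValueError):
    """A parameter failed validation; the message names the offending field."""


@dataclass(frozen=True)
class ParameterSet:
    """Full configuration of one Krogh-cylinder ADC simulation.

    Defaults are the nominal mouse-xenograft values (table units): a
    biexponential IgG plasma profile, a 72 μm Krogh cylinder around an 8 μm
    capillary, 1e5 receptors/cell with KD = 0.1 nM, lysosomal payload release
    with a 7 hr retention half-life and no bystander re-entry, and a tumor
    doubling every 10 days with 10% of cell mass proliferating.
    """

    # --- plasma pharmacokinetics ---
    A: float = 0.60          # fraction of alpha clearance phase
    B: float = 0.40          # fraction of beta clearance phase
    ka: float = 0.6          # alpha-phase clearance rate, 1/hr
    kb: float = 0.17         # beta-phase clearance rate, 1/day
    # --- geometry & transport ---
    RKrogh: float = 72.0     # Krogh cylinder radius, μm
    Rcap: float = 8.0        # capillary radius, μm
    Pvasc: float = 2.8e-7    # vascular permeability, cm/s
    D: float = 1.3e-7        # ADC effective diffusivity, cm²/s
    # --- binding ---
    kon: float = 6e-3        # forward binding rate, 1/(nM·min)
    KD: float = 0.1          # dissociation constant, nM
    eps: float = 0.24        # void (interstitial) fraction
    # --- receptor trafficking ---
    kinT: float = 0.01       # free-receptor internalization rate, 1/min
    keT: float = 0.03        # free-receptor endosomal exit rate, 1/min
    feT: float = 0.5         # free-receptor recycling fraction
    kinB: float = 0.01       # complex internalization rate, 1/min
    keB: float = 0.03        # complex endosomal exit rate, 1/min
    feB: float = 0.5         # complex recycling fraction
    # --- payload ---
    tp: float = 7.0          # payload retention half-life, hr
    kin_payload: float = 0.0  # payload re-entry rate into cytosol, 1/hr
    DAR: float = 3.0         # drug-antibody ratio
    Dp: float = 3.2e-6       # payload effective diffusivity, cm²/s
    Pvasc_payload: float = 1e-5  # capillary permeability of free payload, cm/s
    # --- tumor growth ---
    beta: float = 0.05       # quiescent->proliferating transition rate, 1/day
    td: float = 10.0         # tumor doubling time, day
    rt: float = 0.1 / 0.9    # proliferating-to-quiescent cell-mass ratio
    IC50: float = 3.0        # payload potency threshold, nM
    h: float = 100.0         # Hill coefficient
    # --- cell / receptor census ---
    nRec: float = 1e5        # receptors per cell
    Rcell: float = 8.0       # cell radius, μm
    # --- dosing ---
    dose: float = 1.0        # administered dose, mg/kg
    body_weight: float = 20.0     # g
    plasma_volume: float = 2.0    # mL
    adc_molar_mass: float = 150_000.0  # g/mol (typical IgG)
    # --- model options ---
    cleavage_site: str = "lysosomal"   # or "endosomal"
    kill_rate_scale: float = 1.0       # 1/(nM·day)
    single_eps_binding: bool = False   # alternative binding-law reading
    payload_capillary_sink: bool = True   # payload washes out to blood at wall
    kill_averaging: str = "local"      # or "global" (cylinder-averaged kill)
    # --- simulation controls ---
    sim_horizon: float = 30.0  # day
    grid_step: float = 1.0     # μm
    unit_system: str = "table"  # "table" or "internal"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ParameterError` naming the first invalid field."""
        nonneg = (
            "ka", "kb", "Pvasc", "D", "kon", "KD", "kinT", "keT", "kinB",
            "keB", "kin_payload", "DAR", "Dp", "Pvasc_payload", "beta",
            "IC50", "h", "nRec",
            "kill_rate_scale", "dose",
        )
        for name in nonneg:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be finite and >= 0, got {v}")
        positive = (
            "RKrogh", "Rcap", "tp", "td", "rt", "Rcell", "body_weight",
            "plasma_volume", "adc_molar_mass", "sim_horizon", "grid_step",
        )
        for name in positive:
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be finite and > 0, got {v}")
        if abs(self.A + self.B - 1.0) > 1e-12:
            raise ParameterError(f"A + B must equal 1, got A={self.A}, B={self.B}")
        if not 0.0 < self.eps < 1.0:
            raise ParameterError(f"eps must lie in (0, 1), got {self.eps}")
        for name in ("feT", "feB"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.RKrogh <= self.Rcap:
            raise ParameterError(
                f"RKrogh must exceed Rcap, got RKrogh={self.RKrogh}, Rcap={self.Rcap}"
            )
        if self.cleavage_site not in ("lysosomal", "endosomal"):
            raise ParameterError(
                f"cleavage_site must be 'lysosomal' or 'endosomal', got "
                f"{self.cleavage_site!r}"
            )
        if self.kill_averaging not in ("local", "global"):
            raise ParameterError(
                f"kill_averaging must be 'local' or 'global', got "
                f"{self.kill_averaging!r}"
            )
        if self.unit_system not in ("table", "internal"):
            raise ParameterError(
                f"unit_system must be 'table' or 'internal', got "
                f"{self.unit_system!r}"
            )

    # -- conversion helpers ----------------------------------------------

    def to_internal(self) -> "ParameterSet":
        return normalize_units(self)

    def to_table(self) -> "ParameterSet":
        return to_table_units(self)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def nominal_parameters(**overrides: Any) -> ParameterSet:
    """The nominal parameter set (table units), optionally overridden."""
    return replace(ParameterSet(), **overrides)


def normalize_units(params: ParameterSet) -> ParameterSet:
    """Convert a parameter set to the internal hours/μm/nM system.

    Involutive: normalizing an already-internal set returns it unchanged.
    """
    if params.unit_system == "internal":
        return params
    changes: dict[str, Any] = {
        name: getattr(params, name) * f for name, f in _TO_INTERNAL.items()
    }
    changes["unit_system"] = "internal"
    return replace(params, **changes)


def to_table_units(params: ParameterSet) -> ParameterSet:
    """Inverse of :func:`normalize_units`."""
    if params.unit_system == "table":
        return params
    changes: dict[str, Any] = {
        name: getattr(params, name) / f for name, f in _TO_INTERNAL.items()
    }
    changes["unit_system"] = "table"
    return replace(params, **changes)


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DerivedParameters:
    """Quantities computed from a :class:`ParameterSet` (internal units).

    Attributes
    ----------
    koff : float
        Reverse binding rate, ``kon * KD`` (1/hr).
    kout : float
        Payload efflux rate from the cytosol, ``ln 2 / tp`` (1/hr).
    Tinit : float
        Initial surface-receptor concentration over total tissue volume (nM).
    Rs : float
        Receptor synthesis rate, closed so the drug-free receptor pool is
        stationary at ``Tinit`` (nM/hr).
    gamma : float
        Relative growth rate of proliferating cells (1/hr).
    alpha : float
        Proliferating-to-quiescent transition rate (1/hr).
    C0 : float
        Initial plasma ADC concentration for the configured dose (nM).
    """

    koff: float
    kout: float
    Tinit: float
    Rs: float
    gamma: float
    alpha: float
    C0: float


def initial_receptor_concentration(nRec: float, Rcell: float) -> float:
    """Receptor concentration (nM) of ``nRec`` receptors in a cell of radius
    ``Rcell`` μm: nRec / (N_A · V_cell), V_cell = 4/3·π·Rcell³."""
    if nRec < 0:
        raise ParameterError(f"nRec must be >= 0, got {nRec}")
    if Rcell <= 0:
        raise ParameterError(f"Rcell must be > 0, got {Rcell}")
    vcell_litre = (4.0 / 3.0) * math.pi * Rcell**3 * 1e-15  # μm³ -> L
    return nRec / (AVOGADRO * vcell_litre) * 1e9  # mol/L -> nM


def payload_efflux_rate(tp: float) -> float:
    """Cytosolic payload efflux rate kout = ln2 / tp (1/hr for tp in hr)."""
    if tp <= 0:
        raise ParameterError(f"tp must be > 0, got {tp}")
    return math.log(2.0) / tp


def growth_rates(td: float, rt: float, beta: float) -> tuple[float, float]:
    """Growth constants (gamma, alpha) in 1/day from doubling constraints.

    Chosen so that the drug-free proliferating/quiescent system started at
    P/Q = rt grows exponentially, doubling total mass exactly at ``td`` while
    preserving P/Q = rt:

        gamma = (ln2/td) * (rt + 1) / rt
        alpha = (ln2/td + beta) / rt

    With these, (P, Q) ∝ (rt, 1) is an eigenvector of the drug-free linear
    system with eigenvalue ln2/td.
    """
    if td <= 0:
        raise ParameterError(f"td must be > 0, got {td}")
    if rt <= 0:
        raise ParameterError(f"rt must be > 0, got {rt}")
    if beta < 0:
        raise ParameterError(f"beta must be >= 0, got {beta}")
    lam = math.log(2.0) / td
    gamma = lam * (rt + 1.0) / rt
    alpha = (lam + beta) / rt
    return gamma, alpha


def initial_plasma_concentration(
    dose: float,
    body_weight: float = 20.0,
    plasma_volume: float = 2.0,
    adc_molar_mass: float = 150_000.0,
) -> float:
    """Initial plasma concentration (nM) of an IV bolus.

    ``dose`` mg/kg into ``body_weight`` g distributes over ``plasma_volume``
    mL; dividing the mass concentration by the ADC molar mass gives molarity.
    """
    if min(body_weight, plasma_volume, adc_molar_mass) <= 0 or dose < 0:
        raise ParameterError("dose must be >= 0 and the remaining arguments > 0")
    mg_total = dose * body_weight / 1000.0  # mg/kg * kg
    g_per_litre = mg_total / plasma_volume  # mg/mL == g/L
    return g_per_litre / adc_molar_mass * 1e9


def derive_parameters(params: ParameterSet) -> DerivedParameters:
    """Compute all derived quantities, in internal units (1/hr, nM)."""
    p = normalize_units(params)
    tinit = initial_receptor_concentration(p.nRec, p.Rcell)
    gamma_d, alpha_d = growth_rates(p.td / 24.0, p.rt, p.beta * 24.0)
    return DerivedParameters(
        koff=p.kon * p.KD,
        kout=payload_efflux_rate(p.tp),
        Tinit=tinit,
        Rs=p.kinT * (1.0 - p.feT) * tinit,
        gamma=gamma_d / 24.0,
        alpha=alpha_d / 24.0,
        C0=initial_plasma_concentration(
            p.dose, p.body_weight, p.plasma_volume, p.adc_molar_mass
        ),
    )


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

_FIELD_NAMES = {f.name for f in fields(ParameterSet)}


def _coerce(name: str, value: Any) -> Any:
    f = {f.name: f for f in fields(ParameterSet)}[name]
    if f.type in ("float", float):
        return float(value)
    if f.type in ("bool", bool) and not isinstance(value, bool):
        raise ParameterError(f"{name} must be a boolean, got {value!r}")
    return value


def load_config(source: str | Mapping[str, Any]) -> ParameterSet:
    """Load a parameter set from a YAML/JSON file path or a mapping.

    The file is a flat map of parameter symbol names to values in table
    units. ``preset: nominal`` loads the nominal defaults before applying any
    other keys. An optional ``units`` block declares units per field and must
    match the table-unit contract exactly. Unknown keys are rejected.
    """
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ParameterError("config must be a mapping of parameter names")
    preset = raw.pop("preset", None)
    if preset is not None and preset != "nominal":
        raise ParameterError(f"unknown preset {preset!r}; valid presets: nominal")
    units = raw.pop("units", None)
    if units is not None:
        for name, unit in units.items():
            if name not in TABLE_UNITS:
                raise ParameterError(f"units block names unknown field {name!r}")
            if unit != TABLE_UNITS[name]:
                raise ParameterError(
                    f"units[{name!r}] = {unit!r} does not match the declared "
                    f"unit {TABLE_UNITS[name]!r}"
                )
    unknown = set(raw) - _FIELD_NAMES
    if unknown:
        raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
    if "unit_system" in raw and raw["unit_system"] != "table":
        raise ParameterError("config files must specify parameters in table units")
    values = {name: _coerce(name, v) for name, v in raw.items()}
    return replace(ParameterSet(), **values)


def dump_config(params: ParameterSet, path: str | None = None) -> str:
    """Serialize a parameter set (converted to table units) to YAML.

    Round-trips bit-exactly: floats are emitted via ``repr``.
    """
    tab = to_table_units(params).to_dict()
    tab.pop("unit_system")
    lines = ["# kroghadc parameter configuration (table units)"]
    for name, value in tab.items():
        lines.append(f"{name}: {value!r}" if isinstance(value, str) else f"{name}: {value!r}")
    lines.append("units:")
    for name, unit in TABLE_UNITS.items():
        lines.append(f"  {name}: {unit!r}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
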