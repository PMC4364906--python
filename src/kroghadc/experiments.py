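"""Parameter-sweep engine and named presets for the model's design studies.

The presets encode the published design-space studies over the Krogh-cylinder
model: receptor density (binding-site barrier), receptor trafficking rates,
tumor growth constants, vascularization, affinity x dose, payload cleavage
site and retention half-life, and bystander re-entry kinetics. Each preset
returns a :class:`SweepSpec` whose base is the nominal parameter set;
:func:`run_sweep` runs the cartesian product and returns a tidy long-format
:class:`pandas.DataFrame` (one row per combination x metric observation).

Two *virtual* axes translate study coordinates into model parameters:

* ``proliferating_fraction`` f -> ``rt = f / (1 - f)``;
* ``kin_over_kout`` r -> ``kin_payload = r * kout`` with kout = ln2/tp taken
  from the base parameter set.

Sweeping ``KD`` changes the off-rate only (kon is held at its nominal value;
koff = kon*KD by construction).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd

from .grid import volume_average
from .params import ParameterSet, nominal_parameters, payload_efflux_rate
from .simulate import SimulationResult, TumorPenetrationModel

__all__ = ["SweepSpec", "run_sweep", "preset", "PRESET_NAMES",
           "payload_profile_cv"]

METRICS = ("max_shrinkage", "pct_change_timeseries", "payload_profile_cv")

MAX_SWEEP_SIZE = 10_000

#: Virtual axis name -> function(params, value) -> params
VIRTUAL_AXES: dict[str, Callable[[ParameterSet, float], ParameterSet]] = {
    "proliferating_fraction": lambda p, f: replace(p, rt=f / (1.0 - f)),
    "kin_over_kout": lambda p, r: replace(
        p, kin_payload=r * payload_efflux_rate(p.tp)
    ),
}


@dataclass(frozen=True)
class SweepSpec:
    """A cartesian parameter sweep.

    Attributes
    ----------
    base : ParameterSet
        Parameters shared by every run (table units).
    axes : tuple of (name, values)
        Parameter names (fields of :class:`ParameterSet` or virtual axes)
        and the value lists to sweep.
    metrics : tuple of str
        Subset of ``("max_shrinkage", "pct_change_timeseries",
        "payload_profile_cv")``.
    snapshot_times : tuple of float
        Times (hours) at which radial profiles are recorded for
        profile-based metrics.
    """

    base: ParameterSet = field(default_factory=nominal_parameters)
    axes: tuple[tuple[str, tuple[float, ...]], ...] = ()
    metrics: tuple[str, ...] = ("max_shrinkage",)
    snapshot_times: tuple[float, ...] = (24.0,)

    def __post_init__(self) -> None:
        valid = set(ParameterSet.__dataclass_fields__) | set(VIRTUAL_AXES)
        size = 1
        for name, values in self.axes:
            if name not in valid:
                raise ValueError(f"unknown sweep axis {name!r}")
            if len(values) == 0:
                raise ValueError(f"axis {name!r} has no values")
            size *= len(values)
        if size > MAX_SWEEP_SIZE:
            raise ValueError(
                f"sweep size {size} exceeds the {MAX_SWEEP_SIZE}-run bound"
            )
        for m in self.metrics:
            if m not in METRICS:
                raise ValueError(f"unknown metric {m!r}; valid: {METRICS}")

    @property
    def size(self) -> int:
        return math.prod(len(v) for _, v in self.axes) if self.axes else 1


def _apply_axes(base: ParameterSet, coords: dict[str, float]) -> ParameterSet:
    params = base
    plain = {k: v for k, v in coords.items() if k not in VIRTUAL_AXES}
    if plain:
        params = replace(params, **plain)
    for name, fn in VIRTUAL_AXES.items():
        if name in coords:
            params = fn(params, coords[name])
    return params


def payload_profile_cv(result: SimulationResult, snapshot_index: int = 0,
                       species: str = "Cp") -> float:
    """Volume-weighted coefficient of variation of a radial payload profile.

    A small CV means a homogeneous payload distribution across the cylinder;
    a large CV means a steep radial gradient (binding-site barrier). NaN if
    the mean profile is zero.
    """
    prof = result.radial_profiles[species][snapshot_index]
    w = result.grid.weights
    mean = float(w @ prof)
    if mean <= 0.0:
        return float("nan")
    var = float(w @ (prof - mean) ** 2)
    return math.sqrt(var) / mean


def run_sweep(spec: SweepSpec, run_kwargs: dict[str, Any] | None = None
              ) -> pd.DataFrame:
    """Run every axis combination and tabulate the requested metrics.

    Returns a tidy long-format table with one column per sweep axis plus
    ``metric``, ``time_hr`` (NaN for time-independent metrics), ``value``,
    ``status`` ("ok" or "error") and ``message``. A failed run produces one
    flagged row per metric and the sweep continues. Results are deterministic
    and independent of axis ordering.
    """
    run_kwargs = dict(run_kwargs or {})
    run_kwargs.setdefault("snapshot_times", spec.snapshot_times)
    names = [name for name, _ in spec.axes]
    value_lists = [values for _, values in spec.axes]
    rows: list[dict[str, Any]] = []
    for combo in itertools.product(*value_lists):
        coords = dict(zip(names, combo))
        try:
            params = _apply_axes(spec.base, coords)
            result = TumorPenetrationModel(params).run(**run_kwargs)
        except Exception as exc:  # noqa: BLE001 - flagged row, sweep continues
            for metric in spec.metrics:
                rows.append({**coords, "metric": metric, "time_hr": np.nan,
                             "value": np.nan, "status": "error",
                             "message": str(exc)})
            continue
        for metric in spec.metrics:
            if metric == "max_shrinkage":
                rows.append({**coords, "metric": metric, "time_hr": np.nan,
                             "value": result.max_shrinkage, "status": "ok",
                             "message": ""})
            elif metric == "pct_change_timeseries":
                for t, v in zip(result.times, result.tumor_mass_pct_change):
                    rows.append({**coords, "metric": metric,
                                 "time_hr": float(t), "value": float(v),
                                 "status": "ok", "message": ""})
            elif metric == "payload_profile_cv":
                for k, t in enumerate(result.snapshot_times):
                    rows.append({**coords, "metric": metric,
                                 "time_hr": float(t),
                                 "value": payload_profile_cv(result, k),
                                 "status": "ok", "message": ""})
    return pd.DataFrame(rows, columns=[*names, "metric", "time_hr", "value",
                                       "status", "message"])


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def _log_grid(lo: float, hi: float, n: int = 13) -> tuple[float, ...]:
    return tuple(float(v) for v in np.logspace(math.log10(lo), math.log10(hi), n))


def _build_presets() -> dict[str, Callable[[], SweepSpec]]:
    nominal = nominal_parameters

    def fig2_receptor_profiles() -> SweepSpec:
        return SweepSpec(
            base=nominal(),
            axes=(("nRec", (1e3, 1e4, 1e5, 1e6)),),
            metrics=("payload_profile_cv", "max_shrinkage"),
            snapshot_times=(24.0, 72.0),
        )

    def fig3_receptor_timeseries() -> SweepSpec:
        return SweepSpec(
            base=nominal(),
            axes=(("nRec", (1e3, 1e4, 1e5, 1e6)),),
            metrics=("pct_change_timeseries", "max_shrinkage"),
        )

    def fig4_receptor_maxshrink() -> SweepSpec:
        return SweepSpec(
            base=nominal(),
            axes=(("nRec", _log_grid(1e3, 1e6)),
                  ("dose", (1.0, 10.0, 30.0))),
        )

    def fig5_trafficking() -> SweepSpec:
        return SweepSpec(
            base=nominal(),
            axes=(("nRec", (1e3, 1e5)),
                  ("kinT", (1e-3, 1e-2, 1e-1)),
                  ("feT", (0.1, 0.5, 0.9))),
        )

    def fig6_growth() -> SweepSpec:
        return SweepSpec(
            base=nominal(),
            axes=(("td", (5.0, 10.0, 15.0, 20.0)),
                  ("proliferating_fraction", (0.05, 0.2, 0.3, 0.4, 0.5))),
        )

    def fig7_vascularization() -> SweepSpec:
        return SweepSpec(
            base=nominal(),
            axes=(("RKrogh", (40.0, 72.0, 120.0, 168.0)),),
            metrics=("pct_change_timeseries", "max_shrinkage"),
        )

    def fig8_kd_dose() -> SweepSpec:
        return SweepSpec(
            base=nominal(),
            axes=(("KD", _log_grid(1e-3, 1e2)),
                  ("dose", (1.0, 5.0, 10.0, 30.0)),
                  ("nRec", (1e3, 1e4, 1e5, 1e6))),
        )

    def fig9_payload() -> SweepSpec:
        return SweepSpec(
            base=nominal(),
            axes=(("cleavage_site", ("lysosomal", "endosomal")),
                  ("tp", (1.0, 3.0, 7.0, 15.0, 25.0))),
        )

    def fig10_bystander() -> SweepSpec:
        return SweepSpec(
            base=nominal(),
            axes=(("kin_over_kout", (0.0, 1.0, 10.0, 100.0)),),
            metrics=("pct_change_timeseries", "max_shrinkage"),
        )

    return {
        fn.__name__: fn
        for fn in (
            fig2_receptor_profiles, fig3_receptor_timeseries,
            fig4_receptor_maxshrink, fig5_trafficking, fig6_growth,
            fig7_vascularization, fig8_kd_dose, fig9_payload,
            fig10_bystander,
        )
    }


_PRESETS = _build_presets()
PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str) -> SweepSpec:
    """Return a named sweep preset; raises with the valid names otherwise."""
    try:
        return _PRESETS[name]()
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        ) from None
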