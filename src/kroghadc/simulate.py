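"""Method-of-lines assembly and integration of the full Krogh-cylinder model.

:class:`TumorPenetrationModel` is constructed from a
:class:`~kroghadc.params.ParameterSet`; :meth:`TumorPenetrationModel.run`
integrates the coupled system and returns a :class:`SimulationResult`
carrying the tumor-mass time course, radial profiles, summary metrics and
solver diagnostics.

The state vector stacks nine per-node blocks,

    [C | T | B | Te | Be | Cp | Cp_ext | P | Q],

where free ADC (C) diffuses with a permeability-limited (Robin) capillary
wall driven by the biexponential plasma profile, interstitial payload
(Cp_ext) diffuses with no-flux walls by default, and the remaining species
are purely local. P and Q are spatially resolved: the local cell mass
Γ = P + Q scales the free-receptor concentration in the binding law and
normalizes the cytosolic payload in the kill switch, so tissue far from the
capillary can escape killing when a binding-site barrier confines the
payload near the vessel. The reported tumor mass is the annular volume
average of Γ.

The system is stiff (binding is orders of magnitude faster than growth), so
the default integrator is BDF with the sparse Jacobian pattern of the
coupled blocks.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .grid import RadialGrid, build_grid, diffusion_matrix, volume_average
from .growth import growth_rhs, hill_effect
from .kinetics import binding_flux, payload_rhs, trafficking_rhs
from .params import (
    DerivedParameters,
    ParameterSet,
    derive_parameters,
    normalize_units,
    to_table_units,
)
from .plasma import PlasmaModel

__all__ = [
    "SPECIES",
    "SimulationError",
    "SimulationResult",
    "TumorPenetrationModel",
    "assemble_rhs",
    "run_simulation",
    "max_shrinkage",
]

#: Order of the per-node state blocks.
SPECIES = ("C", "T", "B", "Te", "Be", "Cp", "Cp_ext", "P", "Q")

#: Shrinkage magnitudes below this (in % of initial mass) are floating-point
#: rounding noise of the volume average, not tumor response.
_SHRINKAGE_NOISE_FLOOR = 1e-9


def _clamped_min(pct: np.ndarray) -> float:
    m = float(np.min(pct))
    return m if m < -_SHRINKAGE_NOISE_FLOOR else 0.0


class SimulationError(RuntimeError):
    """Integration failed or produced non-finite derivatives.

    Attributes ``t`` (last time reached, hours) and ``state`` (snapshot of
    the state vector at failure, if available) support post-mortem
    inspection.
    """

    def __init__(self, message: str, t: float | None = None,
                 state: np.ndarray | None = None):
        super().__init__(message)
        self.t = t
        self.state = state


@dataclass
class SimulationResult:
    """Output of one simulation run.

    Attributes
    ----------
    times : ndarray
        Output times, hours.
    tumor_mass_pct_change : ndarray
        100·(⟨Γ⟩(t) − 1), the % change in volume-averaged tumor cell mass
        from its value at dosing; negative values are shrinkage.
    plasma : ndarray
        Plasma ADC concentration at ``times``, nM.
    max_shrinkage : float
        Most negative tumor-mass % change over the run, clamped to <= 0
        (0 means the tumor never shrank below baseline).
    snapshot_times : ndarray
        Times (hours) at which full radial profiles were recorded.
    radial_profiles : dict
        species name -> array (n_snapshots, n_nodes), nM (or dimensionless
        cell mass for P and Q).
    states : ndarray
        Full trajectory, shape (n_species, n_nodes, n_times).
    grid : RadialGrid
    params : ParameterSet
        Resolved parameters in table units.
    derived : DerivedParameters
    diagnostics : dict
        Solver statistics (nfev, njev, nlu, status, message, walltime_s...).
    """

    times: np.ndarray
    tumor_mass_pct_change: np.ndarray
    plasma: np.ndarray
    max_shrinkage: float
    snapshot_times: np.ndarray
    radial_profiles: dict[str, np.ndarray]
    states: np.ndarray
    grid: RadialGrid
    params: ParameterSet
    derived: DerivedParameters
    diagnostics: dict[str, Any]

    def species(self, name: str) -> np.ndarray:
        """Trajectory of one species, shape (n_nodes, n_times)."""
        return self.states[SPECIES.index(name)]

    @property
    def nadir_time(self) -> float:
        """Time (hours) of the most negative tumor-mass change."""
        return float(self.times[int(np.argmin(self.tumor_mass_pct_change))])

    def summary(self) -> str:
        """Plain-text summary of the run."""
        p = self.params
        lines = [
            "Krogh-cylinder ADC simulation",
            "=" * 64,
            f"dose              {p.dose:g} mg/kg   (C0 = {self.derived.C0:.4g} nM)",
            f"receptors/cell    {p.nRec:g}   (Tinit = {self.derived.Tinit:.4g} nM)",
            f"KD                {p.KD:g} nM    cleavage: {p.cleavage_site}",
            f"geometry          Rcap {p.Rcap:g} um, RKrogh {p.RKrogh:g} um, "
            f"step {p.grid_step:g} um ({self.grid.n} nodes)",
            f"horizon           {p.sim_horizon:g} d, output {self.times.size} points",
            "-" * 64,
            f"max shrinkage     {self.max_shrinkage:.4g} %"
            + (f"  (nadir at {self.nadir_time / 24.0:.3g} d)"
               if self.max_shrinkage < 0 else "  (tumor never shrank)"),
            f"final mass change {self.tumor_mass_pct_change[-1]:+.4g} % "
            f"at {self.times[-1] / 24.0:g} d",
            f"solver            {self.diagnostics.get('method', '?')}, "
            f"nfev={self.diagnostics.get('nfev')}, "
            f"njev={self.diagnostics.get('njev')}, "
            f"walltime={self.diagnostics.get('walltime_s', float('nan')):.2f} s",
            "=" * 64,
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the tumor-mass % change time course. Returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times / 24.0, self.tumor_mass_pct_change)
        ax.axhline(0.0, color="0.6", lw=0.8)
        ax.set_xlabel("time (days)")
        ax.set_ylabel("% change in tumor mass")
        return ax

    def plot_profiles(self, species: str = "Cp", ax=None):
        """Plot recorded radial profiles of one species. Returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for t_snap, prof in zip(self.snapshot_times,
                                self.radial_profiles[species]):
            ax.plot(self.grid.r, prof, label=f"{t_snap / 24.0:g} d")
        ax.set_xlabel("radius (um)")
        ax.set_ylabel(f"{species} (nM)")
        ax.legend(title="time")
        return ax


class TumorPenetrationModel:
    """Krogh-cylinder reaction-diffusion model of ADC tumor penetration.

    Parameters
    ----------
    params : ParameterSet
        Model configuration in table or internal units.
    dose_times : sequence of float, optional
        IV bolus times in hours (default: single dose at t = 0). Multiple
        doses superpose identical biexponential plasma profiles.
    """

    def __init__(self, params: ParameterSet,
                 dose_times: Sequence[float] = (0.0,)):
        params.validate()
        self.params_table = to_table_units(params)
        p = normalize_units(params)
        self.p = p
        self.derived = derive_parameters(p)
        self.grid = build_grid(p.Rcap, p.RKrogh, p.grid_step)
        self.plasma = PlasmaModel.from_parameters(p, dose_times)
        n = self.grid.n
        self.n_nodes = n
        # ADC: Robin capillary wall driven by plasma. Interstitial payload:
        # by default the small molecule washes out to blood through the wall
        # (Robin against zero plasma payload at its own permeability, which
        # is far higher than the antibody's); without the sink both payload
        # walls are closed and released payload never leaves the cylinder.
        self._Mc, self._bc = diffusion_matrix(
            self.grid, p.D, Pvasc=p.Pvasc, eps=p.eps,
            inner_bc="robin_permeability",
        )
        inner_payload = ("robin_permeability" if p.payload_capillary_sink
                         else "no_flux")
        self._Mp, _ = diffusion_matrix(
            self.grid, p.Dp, Pvasc=p.Pvasc_payload, eps=p.eps,
            inner_bc=inner_payload,
        )

    # -- initial conditions -------------------------------------------------

    def initial_state(self) -> np.ndarray:
        """Pre-dose stationary state (except for growth): no drug anywhere,
        receptors at their drug-free surface/endosome steady state, cell
        mass normalized to Γ = 1 with P/Q = rt."""
        p, d, n = self.p, self.derived, self.n_nodes
        y = np.zeros((len(SPECIES), n))
        y[SPECIES.index("T")] = d.Tinit
        y[SPECIES.index("Te")] = p.kinT * d.Tinit / p.keT if p.keT > 0 else 0.0
        y[SPECIES.index("P")] = p.rt / (1.0 + p.rt)
        y[SPECIES.index("Q")] = 1.0 / (1.0 + p.rt)
        return y.ravel()

    # -- right-hand side ----------------------------------------------------

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        """Time derivative of the stacked state vector (internal units)."""
        p, d, n = self.p, self.derived, self.n_nodes
        C, T, B, Te, Be, Cp, Cp_ext, P, Q = y.reshape(len(SPECIES), n)
        Gamma = P + Q
        cpl = self.plasma.concentration(t)

        rxn = binding_flux(C, T, B, Gamma, p.kon, d.koff, p.eps,
                           single_eps=p.single_eps_binding)
        dC = self._Mc @ C + self._bc * cpl - rxn
        dT, dB, dTe, dBe = trafficking_rhs(
            T, Te, B, Be, rxn, d.Rs, p.kinT, p.keT, p.feT,
            p.kinB, p.keB, p.feB,
        )
        dCp, dCp_ext = payload_rhs(
            B, Be, Cp, Cp_ext, p.DAR, d.kout, p.kin_payload, p.eps,
            p.keB, p.feB, p.kinB, cleavage_site=p.cleavage_site,
        )
        dCp_ext = dCp_ext + self._Mp @ Cp_ext

        kill_scale = p.kill_rate_scale
        if p.kill_averaging == "global":
            w = self.grid.weights
            x_bar = (w @ Cp) / max(w @ Gamma, 1e-12)
            kill = kill_scale * x_bar * hill_effect(x_bar, 1.0, p.IC50, p.h)
            dP = (d.gamma - d.alpha - kill) * P + p.beta * Q
            dQ = d.alpha * P - p.beta * Q
        else:
            dP, dQ = growth_rhs(P, Q, Cp, d.gamma, d.alpha, p.beta,
                                kill_scale, p.IC50, p.h)

        dy = np.concatenate([dC, dT, dB, dTe, dBe, dCp, dCp_ext, dP, dQ])
        if not np.all(np.isfinite(dy)):
            raise SimulationError(
                f"non-finite derivative at t = {t:.6g} h", t=t, state=y.copy()
            )
        return dy

    def jac_sparsity(self) -> sp.csr_matrix:
        """Sparsity pattern of the Jacobian for the stiff integrator."""
        n = self.n_nodes
        ns = len(SPECIES)
        eye = sp.eye_array(n, format="csr")
        tri = sp.diags_array([np.ones(n - 1), np.ones(n), np.ones(n - 1)],
                             offsets=[-1, 0, 1]).tocsr()
        blocks: list[list[Any]] = [[None] * ns for _ in range(ns)]
        local = {
            name: SPECIES.index(name) for name in SPECIES
        }
        # within-node coupling: conservatively mark all species pairs local
        for i in range(ns):
            for j in range(ns):
                blocks[i][j] = eye
        blocks[local["C"]][local["C"]] = tri
        blocks[local["Cp_ext"]][local["Cp_ext"]] = tri
        if self.p.kill_averaging == "global":
            dense = sp.csr_matrix(np.ones((n, n)))
            for row in ("P", "Q"):
                for col in ("Cp", "P", "Q"):
                    blocks[local[row]][local[col]] = dense
        return sp.bmat(blocks, format="csr")

    # -- integration --------------------------------------------------------

    def run(
        self,
        output_cadence: float = 1.0,
        snapshot_times: Sequence[float] | None = None,
        rtol: float = 1e-6,
        atol: float = 1e-9,
        method: str = "BDF",
    ) -> SimulationResult:
        """Integrate from t = 0 to the simulation horizon.

        Parameters
        ----------
        output_cadence : float
            Spacing of output times, hours (default hourly).
        snapshot_times : sequence of float, optional
            Times (hours) at which to record full radial profiles; defaults
            to [24 h, horizon/2, horizon].
        rtol, atol : float
            Integrator tolerances (atol in nM).
        method : str
            Any stiff ``scipy.integrate.solve_ivp`` method accepting a
            Jacobian sparsity pattern ("BDF" default, or "Radau"/"LSODA").
        """
        p = self.p
        horizon = p.sim_horizon  # hours (internal units)
        t_grid = np.arange(0.0, horizon + 1e-9, output_cadence)
        if t_grid[-1] < horizon:
            t_grid = np.append(t_grid, horizon)
        if snapshot_times is None:
            snapshot_times = [min(24.0, horizon), horizon / 2.0, horizon]
        snaps = np.unique(np.clip(np.asarray(snapshot_times, float), 0.0, horizon))
        t_eval = np.unique(np.concatenate([t_grid, snaps]))

        kwargs: dict[str, Any] = dict(rtol=rtol, atol=atol)
        if method in ("BDF", "Radau"):
            kwargs["jac_sparsity"] = self.jac_sparsity()
        t0 = _time.perf_counter()
        sol = solve_ivp(self.rhs, (0.0, horizon), self.initial_state(),
                        method=method, t_eval=t_eval, **kwargs)
        walltime = _time.perf_counter() - t0
        if not sol.success:
            last_t = float(sol.t[-1]) if sol.t.size else 0.0
            raise SimulationError(
                f"integrator failed at t = {last_t:.6g} h: {sol.message}",
                t=last_t,
                state=sol.y[:, -1] if sol.t.size else None,
            )

        n = self.n_nodes
        states = sol.y.reshape(len(SPECIES), n, sol.t.size)
        gamma_field = states[SPECIES.index("P")] + states[SPECIES.index("Q")]
        gamma_avg = self.grid.weights @ gamma_field
        pct = 100.0 * (gamma_avg - 1.0)
        snap_idx = np.searchsorted(sol.t, snaps)
        profiles = {
            name: states[k][:, snap_idx].T for k, name in enumerate(SPECIES)
        }
        diagnostics = {
            "method": method,
            "nfev": int(sol.nfev),
            "njev": int(sol.njev),
            "nlu": int(sol.nlu),
            "status": int(sol.status),
            "message": str(sol.message),
            "rtol": rtol,
            "atol": atol,
            "n_nodes": n,
            "n_states": int(sol.y.shape[0]),
            "walltime_s": walltime,
        }
        return SimulationResult(
            times=sol.t,
            tumor_mass_pct_change=pct,
            plasma=np.asarray(self.plasma.concentration(sol.t)),
            max_shrinkage=_clamped_min(pct),
            snapshot_times=snaps,
            radial_profiles=profiles,
            states=states,
            grid=self.grid,
            params=self.params_table,
            derived=self.derived,
            diagnostics=diagnostics,
        )


def assemble_rhs(params: ParameterSet):
    """Build the method-of-lines right-hand side f(t, y) for ``params``."""
    return TumorPenetrationModel(params).rhs


def run_simulation(params: ParameterSet, **kwargs: Any) -> SimulationResult:
    """One-call convenience wrapper: build the model and run it."""
    return TumorPenetrationModel(params).run(**kwargs)


def max_shrinkage(result: SimulationResult) -> float:
    """Most negative tumor-mass % change, clamped to <= 0."""
    pct = np.asarray(result.tumor_mass_pct_change, dtype=float)
    if pct.size == 0:
        raise ValueError("result has no recorded times")
    return _clamped_min(pct)
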