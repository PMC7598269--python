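"""Mass-action ODE assembly and stiff integration for the PGHS-1 network.

The state vector stacks the 28 enzyme species (canonical label order), the
six free metabolite pools (AA, O2, RC, OC, PGG2, PGH2) and the damage sink
that receives arachidonate moieties discarded on enzyme inactivation.  Every
reaction contributes rate = k * [enzyme] * prod [consumed metabolite]^n
(O2 enters squared in the oxygenation step); the two binding templates add a
reverse koff * [complex] term.  Fluxes are evaluated post hoc on the stored
output grid, not co-integrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import (
    DAMAGE_SINK,
    METABOLITES,
    NetworkModel,
    ParameterSet,
)

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "SimulationError",
    "RateSystem",
    "assemble_rhs",
    "simulate",
    "reaction_flux",
]


class SimulationError(RuntimeError):
    """Integration failed; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


@dataclass
class SimulationConfig:
    """Initial conditions, time span and solver settings (concentrations uM).

    By default the whole enzyme pool starts in the resting holoenzyme E1 and
    the run is seeded with a trace of PGG2 (0.01 uM) to ignite the peroxidase
    cycle; O2 defaults to an air-saturated 200 uM and can be clamped constant.
    """

    enzyme_total: float = 0.035
    aa0: float = 0.0
    rc0: float = 0.0
    o2_0: float = 200.0
    oc0: float = 0.0
    pgg2_0: float = 0.01
    pgh2_0: float = 0.0
    o2_clamped: bool = False
    t_end: float = 300.0
    t_start: float = 0.0
    n_points: int = 800
    grid: str = "log"  # "log" resolves the fast ignition transient
    t_eval: np.ndarray | None = None
    rtol: float = 1e-8
    atol: float = 1e-10
    initial_species: str = "E1"
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("enzyme_total", "aa0", "rc0", "o2_0", "oc0", "pgg2_0", "pgh2_0"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative initial concentration {name}")
        if self.t_end <= self.t_start:
            raise ValueError("time span must be strictly increasing")

    def time_grid(self) -> np.ndarray:
        if self.t_eval is not None:
            t = np.asarray(self.t_eval, dtype=float)
            if t.ndim != 1 or np.any(np.diff(t) <= 0):
                raise ValueError("t_eval must be strictly increasing")
            return t
        if self.grid == "log":
            # geometric grid from 0.1 ms, prefixed with t=0
            lo = min(1e-4, self.t_end / 1e4)
            inner = np.geomspace(lo, self.t_end, self.n_points - 1)
            return np.concatenate(([self.t_start], self.t_start + inner))
        return np.linspace(self.t_start, self.t_end, self.n_points)

    def as_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "enzyme_total", "aa0", "rc0", "o2_0", "oc0", "pgg2_0", "pgh2_0",
                "o2_clamped", "t_end", "t_start", "n_points", "grid",
                "rtol", "atol", "initial_species",
            )
        }
        d["overrides"] = dict(self.overrides)
        return d


class RateSystem:
    """Compiled right-hand side of the mass-action ODE system.

    Reversible bindings are expanded into forward/backward directed reactions
    internally; ``fluxes`` folds them back to net fluxes per ReactionInstance.
    """

    def __init__(self, model: NetworkModel, o2_clamped: bool = False):
        self.model = model
        self.o2_clamped = o2_clamped
        self.state_names: list[str] = (
            model.species_labels() + list(METABOLITES) + [DAMAGE_SINK]
        )
        self.n_states = len(self.state_names)
        index = {name: i for i, name in enumerate(self.state_names)}
        self.index = index
        self._o2_row = index["O2"]

        k, src, met_idx, met_pow = [], [], [], []
        cols: list[np.ndarray] = []
        # map directed reaction -> (instance index, +1 fwd / -1 rev)
        self._directed_owner: list[tuple[int, int]] = []
        for r in model.reactions:
            col = np.zeros(self.n_states)
            col[index[r.reactant]] -= 1.0
            col[index[r.product]] += 1.0
            for met, delta in r.metabolites.items():
                col[index[met]] += delta
            k.append(r.kf)
            src.append(index[r.reactant])
            if r.consumed:
                (met, power), = r.consumed
                met_idx.append(index[met])
                met_pow.append(power)
            else:
                met_idx.append(-1)
                met_pow.append(0)
            cols.append(col)
            self._directed_owner.append((r.index, +1))
            if r.reversible:
                k.append(r.kr)
                src.append(index[r.product])
                met_idx.append(-1)
                met_pow.append(0)
                cols.append(-col)
                self._directed_owner.append((r.index, -1))

        self.k = np.asarray(k)
        self.src = np.asarray(src, dtype=int)
        self.met_idx = np.asarray(met_idx, dtype=int)
        self.met_pow = np.asarray(met_pow, dtype=float)
        self.N = np.column_stack(cols)  # n_states x n_directed
        if o2_clamped:
            self.N[self._o2_row, :] = 0.0
        self._has_met = self.met_idx >= 0
        self._met_rows = self.met_idx[self._has_met]
        self._met_pows = self.met_pow[self._has_met]
        self.n_directed = len(self.k)

    def rates(self, y: np.ndarray) -> np.ndarray:
        r = self.k * y[self.src]
        r[self._has_met] *= y[self._met_rows] ** self._met_pows
        return r

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.N @ self.rates(y)

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        dr = np.zeros((self.n_directed, self.n_states))
        metf = np.ones(self.n_directed)
        metf[self._has_met] = y[self._met_rows] ** self._met_pows
        dr[np.arange(self.n_directed), self.src] = self.k * metf
        idx = np.flatnonzero(self._has_met)
        ym = y[self._met_rows]
        dmet = self.k[idx] * y[self.src[idx]] * self._met_pows * np.where(
            ym > 0, ym ** (self._met_pows - 1), 0.0
        )
        for j, row, val in zip(idx, self._met_rows, dmet):
            dr[j, row] += val
        return self.N @ dr

    def net_fluxes(self, y: np.ndarray) -> np.ndarray:
        """Net flux per ReactionInstance (forward minus reverse), uM/s."""
        directed = self.rates(y)
        out = np.zeros(len(self.model.reactions))
        for j, (owner, sign) in enumerate(self._directed_owner):
            out[owner] += sign * directed[j]
        return out


def assemble_rhs(model: NetworkModel, o2_clamped: bool = False) -> RateSystem:
    """Compile the mass-action rate function for the given network."""
    return RateSystem(model, o2_clamped=o2_clamped)


@dataclass
class Trajectory:
    """Species and flux time courses of one simulation."""

    t: np.ndarray
    y: np.ndarray  # n_states x n_times
    system: RateSystem
    config: SimulationConfig
    _fluxes: np.ndarray | None = None

    @property
    def model(self) -> NetworkModel:
        return self.system.model

    @property
    def state_names(self) -> list[str]:
        return self.system.state_names

    def conc(self, name: str) -> np.ndarray:
        return self.y[self.system.index[name]]

    @property
    def fluxes(self) -> np.ndarray:
        """Net flux matrix V_i(t), reactions x times, uM/s."""
        if self._fluxes is None:
            self._fluxes = np.column_stack(
                [self.system.net_fluxes(self.y[:, j]) for j in range(self.y.shape[1])]
            )
        return self._fluxes

    def flux(self, reaction_index: int) -> np.ndarray:
        if not 0 <= reaction_index < len(self.model.reactions):
            raise KeyError(f"unknown reaction index {reaction_index}")
        return self.fluxes[reaction_index]

    def flux_by_paper(self, number: int) -> np.ndarray:
        return self.flux(self.model.reaction_by_paper_number(number).index)

    def template_flux(self, template_id: str) -> np.ndarray:
        """Sum of net fluxes over all reactions of a template."""
        rows = [r.index for r in self.model.reactions if r.template_id == template_id]
        if not rows:
            return np.zeros_like(self.t)
        return self.fluxes[rows].sum(axis=0)

    def enzyme_total(self) -> np.ndarray:
        rows = [self.system.index[s.label] for s in self.model.species]
        return self.y[rows].sum(axis=0)

    def arachidonate_total(self) -> np.ndarray:
        """Free AA + PGG2 + PGH2 + site-bound moieties + damage sink."""
        total = self.conc("AA") + self.conc("PGG2") + self.conc("PGH2")
        total = total + self.conc(DAMAGE_SINK)
        for s in self.model.species:
            if s.bound_arachidonate:
                total = total + self.conc(s.label)
        return total

    def conservation_report(self) -> dict[str, float]:
        """Maximum relative drift of each conserved moiety along the run."""

        def drift(series: np.ndarray) -> float:
            ref = series[0]
            if ref == 0:
                return float(np.max(np.abs(series)))
            return float(np.max(np.abs(series - ref)) / abs(ref))

        report = {
            "enzyme_total": drift(self.enzyme_total()),
            "rc_plus_oc": drift(self.conc("RC") + self.conc("OC")),
            "arachidonate": drift(self.arachidonate_total()),
        }
        return report

    def to_frame(self, tidy: bool = False) -> pd.DataFrame:
        wide = pd.DataFrame(self.y.T, columns=self.state_names)
        wide.insert(0, "time_s", self.t)
        if not tidy:
            return wide
        return wide.melt(id_vars="time_s", var_name="species",
                         value_name="concentration_uM")

    def flux_frame(self) -> pd.DataFrame:
        cols = {
            f"V{r.paper_reaction}" if r.paper_reaction else f"r{r.index}": self.fluxes[r.index]
            for r in self.model.reactions
        }
        out = pd.DataFrame(cols)
        out.insert(0, "time_s", self.t)
        return out


def simulate(model: NetworkModel, config: SimulationConfig) -> Trajectory:
    """Integrate the network under the given configuration.

    Parameter overrides in the config rebuild the reaction list before
    integration.  Uses the stiff BDF method with the analytic Jacobian.
    """
    if config.overrides:
        model = model.with_params(model.params.with_values(**config.overrides))
    system = assemble_rhs(model, o2_clamped=config.o2_clamped)

    y0 = np.zeros(system.n_states)
    if config.enzyme_total > 0:
        y0[system.index[config.initial_species]] = config.enzyme_total
    y0[system.index["AA"]] = config.aa0
    y0[system.index["O2"]] = config.o2_0
    y0[system.index["RC"]] = config.rc0
    y0[system.index["OC"]] = config.oc0
    y0[system.index["PGG2"]] = config.pgg2_0
    y0[system.index["PGH2"]] = config.pgh2_0

    t_eval = config.time_grid()
    sol = solve_ivp(
        system,
        (t_eval[0], t_eval[-1]),
        y0,
        method="BDF",
        jac=system.jac,
        t_eval=t_eval,
        rtol=config.rtol,
        atol=config.atol,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else None
        raise SimulationError(f"integration failed: {sol.message}", last_time=last)
    return Trajectory(t=sol.t, y=sol.y, system=system, config=config)


def reaction_flux(
    traj: Trajectory, reaction_ids: Iterable[int], by_paper_number: bool = True
) -> pd.DataFrame:
    """Flux time series V_i(t) for the requested reactions, uM/s."""
    data = {"time_s": traj.t}
    for rid in reaction_ids:
        series = traj.flux_by_paper(rid) if by_paper_number else traj.flux(rid)
        data[f"V{rid}"] = series
    return pd.DataFrame(data)


def max_flux(traj: Trajectory, paper_number: int) -> float:
    """Maximum over time of a reaction's net flux, uM/s."""
    return float(np.max(traj.flux_by_paper(paper_number)))
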