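"""Weighted least-squares estimation of grouped rate constants.

Each template shares one rate constant, so the free parameters are a mask
over the unified 18-constant set.  Optimisation runs in log10 space within
bounds (default +/- 3 decades around the fitted values) with seeded
Latin-hypercube multistart followed by local least-squares refinement.
Failed simulations contribute a large finite penalty so optimisers continue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import least_squares
from scipy.stats import qmc

from .network import NetworkModel, ParameterSet, Profile, build_network
from .simulate import SimulationConfig, simulate

__all__ = [
    "Condition",
    "Dataset",
    "FitSpec",
    "FitResult",
    "objective",
    "fit",
    "profile_objective",
    "load_datasets",
    "write_datasets",
]

_PENALTY = 1e8  # objective charged per record when a simulation fails

OBSERVABLES = ("PGG2", "PGH2", "AA", "OC")


@dataclass(frozen=True)
class Condition:
    """One experimental condition block (concentrations in uM)."""

    id: str
    enzyme_total: float
    aa0: float = 0.0
    rc0: float = 0.0
    peroxide0: float = 0.01  # POX-substrate pool seed (PGG2 or H2O2)
    profile: Profile = Profile.PHENOL_PGG2
    o2_0: float = 200.0

    def to_config(self, t_eval: np.ndarray) -> SimulationConfig:
        return SimulationConfig(
            enzyme_total=self.enzyme_total,
            aa0=self.aa0,
            rc0=self.rc0,
            pgg2_0=self.peroxide0,
            o2_0=self.o2_0,
            t_end=float(t_eval[-1]),
            t_eval=t_eval,
        )


@dataclass
class Dataset:
    """Time series of one observable under one condition."""

    condition: Condition
    observable: str
    times: np.ndarray
    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.observable not in OBSERVABLES:
            raise ValueError(f"unknown observable {self.observable!r}")
        if np.any(self.times < 0):
            raise ValueError("times must be >= 0")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be > 0")
        if not (len(self.times) == len(self.values) == len(self.weights)):
            raise ValueError("times, values and weights must align")


def _simulate_conditions(
    params: ParameterSet, datasets: Sequence[Dataset]
) -> dict[str, object]:
    """One simulation per condition block; grid = union of requested times."""
    by_condition: dict[str, list[Dataset]] = {}
    conditions: dict[str, Condition] = {}
    for ds in datasets:
        by_condition.setdefault(ds.condition.id, []).append(ds)
        conditions[ds.condition.id] = ds.condition
    out: dict[str, object] = {}
    for cid, group in by_condition.items():
        cond = conditions[cid]
        times = np.unique(np.concatenate([ds.times for ds in group]))
        if times[0] > 0:
            t_eval = np.concatenate(([0.0], times))
        else:
            t_eval = times
        cond_params = params
        if cond.profile is not params.profile:
            pox = ParameterSet.default(cond.profile)
            cond_params = replace(
                params, profile=cond.profile,
                k5=pox.k5, k6=pox.k6, k7=pox.k7, k8=pox.k8,
            )
        model = build_network(params=cond_params)
        out[cid] = simulate(model, cond.to_config(t_eval))
    return out


def _residual_vector(params: ParameterSet, datasets: Sequence[Dataset]) -> np.ndarray:
    """Weighted residuals; a failed condition yields a finite penalty block."""
    res: list[np.ndarray] = []
    by_condition: dict[str, list[Dataset]] = {}
    for ds in datasets:
        by_condition.setdefault(ds.condition.id, []).append(ds)
    for cid, group in by_condition.items():
        try:
            sims = _simulate_conditions(params, group)
            traj = sims[cid]
            for ds in group:
                sim = np.interp(ds.times, traj.t, traj.conc(ds.observable))
                res.append(np.sqrt(ds.weights) * (sim - ds.values))
        except Exception:
            res.append(
                np.full(sum(len(ds.times) for ds in group), np.sqrt(_PENALTY))
            )
    return np.concatenate(res)


def objective(
    params: ParameterSet,
    datasets: Sequence[Dataset],
) -> float:
    """Weighted sum of squared errors over all records.

    The cosubstrate profile of each condition selects the POX block; free-mask
    parameters are taken from ``params`` as given.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    r = _residual_vector(params, datasets)
    return float(np.dot(r, r))


@dataclass
class FitSpec:
    """Free-parameter mask, bounds, multistart settings and seed."""

    free: tuple[str, ...]
    bounds_decades: float = 3.0
    n_starts: int = 16
    seed: int = 0
    max_nfev: int = 80
    base_params: ParameterSet = field(default_factory=ParameterSet.default)

    def __post_init__(self) -> None:
        if not self.free:
            # an empty mask is legal: the objective is then a constant
            return
        for name in self.free:
            getattr(self.base_params, name)  # raises on unknown parameter

    def bounds_log10(self) -> tuple[np.ndarray, np.ndarray]:
        centre = np.log10(
            np.array([getattr(self.base_params, n) for n in self.free])
        )
        return centre - self.bounds_decades, centre + self.bounds_decades


@dataclass
class FitResult:
    """Best estimate with provenance of every multistart run."""

    params: ParameterSet
    estimates: dict[str, float]
    objective: float
    start_objectives: list[float]
    start_points: list[dict[str, float]]
    bounds_hit: dict[str, bool]
    n_starts: int
    success: bool

    def to_json(self) -> str:
        return json.dumps(
            {
                "estimates": self.estimates,
                "objective": self.objective,
                "start_objectives": self.start_objectives,
                "start_points": self.start_points,
                "bounds_hit": self.bounds_hit,
                "n_starts": self.n_starts,
                "success": self.success,
            },
            indent=1,
        )


def _apply_theta(spec: FitSpec, theta_log: np.ndarray) -> ParameterSet:
    return spec.base_params.with_values(
        **{n: float(10.0 ** v) for n, v in zip(spec.free, theta_log)}
    )


def fit(spec: FitSpec, datasets: Sequence[Dataset]) -> FitResult:
    """Seeded Latin-hypercube multistart + local least-squares refinement.

    Deterministic: identical seed and inputs give an identical result.  The
    returned objective never exceeds the objective at any start point.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    if not spec.free:
        params = spec.base_params
        obj = objective(params, datasets)
        return FitResult(params, {}, obj, [obj], [{}], {}, 0, True)

    lo, hi = spec.bounds_log10()
    sampler = qmc.LatinHypercube(d=len(spec.free), seed=spec.seed)
    starts = lo + sampler.random(spec.n_starts) * (hi - lo)
    # the fitted defaults are always one of the starting points
    starts[0] = np.log10(np.array([getattr(spec.base_params, n) for n in spec.free]))

    def residuals(theta_log: np.ndarray) -> np.ndarray:
        return _residual_vector(_apply_theta(spec, theta_log), datasets)

    best = None
    start_objs: list[float] = []
    start_pts: list[dict[str, float]] = []
    failures = 0
    for theta0 in starts:
        start_pts.append(
            {n: float(10.0 ** v) for n, v in zip(spec.free, theta0)}
        )
        try:
            sol = least_squares(
                residuals, theta0, bounds=(lo, hi), max_nfev=spec.max_nfev,
                xtol=1e-10, ftol=1e-10,
            )
            obj = float(2.0 * sol.cost)
            start_objs.append(obj)
            if best is None or obj < best[0]:
                best = (obj, sol.x)
        except Exception:
            failures += 1
            start_objs.append(float("inf"))
    if best is None:
        raise RuntimeError(
            f"all {len(starts)} starts failed during local refinement"
        )
    obj, theta = best
    params = _apply_theta(spec, theta)
    tol = 1e-6
    bounds_hit = {
        n: bool(theta[i] - lo[i] < tol or hi[i] - theta[i] < tol)
        for i, n in enumerate(spec.free)
    }
    return FitResult(
        params=params,
        estimates={n: getattr(params, n) for n in spec.free},
        objective=obj,
        start_objectives=start_objs,
        start_points=start_pts,
        bounds_hit=bounds_hit,
        n_starts=len(starts),
        success=failures < len(starts),
    )


def profile_objective(
    spec: FitSpec,
    datasets: Sequence[Dataset],
    parameter: str,
    grid: Sequence[float],
) -> pd.DataFrame:
    """Objective profile: re-minimise the other free parameters at each value.

    A flat profile flags a parameter the data do not constrain.
    """
    if parameter not in spec.free:
        raise ValueError(f"{parameter} is not in the free mask")
    remaining = tuple(n for n in spec.free if n != parameter)
    values, objectives = [], []
    for value in grid:
        base = spec.base_params.with_values(**{parameter: float(value)})
        sub = replace(spec, free=remaining, base_params=base, n_starts=1)
        if remaining:
            result = fit(sub, datasets)
            objectives.append(result.objective)
        else:
            objectives.append(objective(base, datasets))
        values.append(float(value))
    return pd.DataFrame({parameter: values, "objective": objectives})


# --------------------------------------------------------------------------
# Dataset file format: records CSV + conditions YAML
# --------------------------------------------------------------------------


def write_datasets(datasets: Sequence[Dataset], csv_path, yaml_path) -> None:
    rows = []
    conds: dict[str, dict] = {}
    for ds in datasets:
        for t, v, w in zip(ds.times, ds.values, ds.weights):
            rows.append(
                {
                    "condition_id": ds.condition.id,
                    "observable": ds.observable,
                    "time_s": t,
                    "value_uM": v,
                    "weight": w,
                }
            )
        c = ds.condition
        conds[c.id] = {
            "enzyme_total": c.enzyme_total,
            "aa0": c.aa0,
            "rc0": c.rc0,
            "peroxide0": c.peroxide0,
            "profile": c.profile.value,
            "o2_0": c.o2_0,
        }
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(conds, fh, sort_keys=True)


def load_datasets(csv_path, yaml_path) -> list[Dataset]:
    records = pd.read_csv(csv_path)
    with open(yaml_path) as fh:
        conds_raw: Mapping[str, Mapping] = yaml.safe_load(fh)
    conditions = {
        cid: Condition(
            id=cid,
            enzyme_total=c["enzyme_total"],
            aa0=c.get("aa0", 0.0),
            rc0=c.get("rc0", 0.0),
            peroxide0=c.get("peroxide0", 0.01),
            profile=Profile(c.get("profile", "phenol_pgg2")),
            o2_0=c.get("o2_0", 200.0),
        )
        for cid, c in conds_raw.items()
    }
    datasets = []
    for (cid, obs), group in records.groupby(["condition_id", "observable"]):
        group = group.sort_values("time_s")
        datasets.append(
            Dataset(
                condition=conditions[cid],
                observable=str(obs),
                times=group["time_s"].to_numpy(),
                values=group["value_uM"].to_numpy(),
                weights=group["weight"].to_numpy(),
            )
        )
    return datasets
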