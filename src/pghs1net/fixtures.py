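"""Synthetic calibration fixtures.

The kinetic measurements this model is calibrated against exist only as
figures in the source literature, so calibration and its tests run against
synthetic datasets of the same shape: time courses simulated from the fitted
parameter set under the published experimental conditions, sampled on a
log-spaced grid and corrupted with multiplicative Gaussian noise.  Three
scenario classes are emulated:

* ``PG_KINETICS``   - PGG2/PGH2 production at 35 nM enzyme, 80 uM AA and
  phenol levels of 100/1000/5000 uM;
* ``AA_CONSUMPTION``- AA decay at 0.5/1/2/20 uM enzyme, 1000 uM phenol;
* ``ADRENOCHROME``  - oxidised-cosubstrate accumulation at adrenaline levels
  0.32-3.22 uM with 1050 uM H2O2 driving the peroxidase site (AA absent).

All files are synthetic stand-ins generated by this module, not digitised
experimental data.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .calibrate import Condition, Dataset, write_datasets
from .network import ParameterSet, Profile, build_network
from .simulate import SimulationConfig, simulate

__all__ = ["Scenario", "FixtureSpec", "generate_fixtures"]


class Scenario(enum.Enum):
    PG_KINETICS = "pg_kinetics"
    AA_CONSUMPTION = "aa_consumption"
    ADRENOCHROME = "adrenochrome"


# (condition blocks, observables, time span) per scenario.  Concentrations in
# uM; spans cover the interval the corresponding experiments resolve.
_SCENARIOS: dict[Scenario, dict] = {
    Scenario.PG_KINETICS: {
        "observables": ("PGG2", "PGH2"),
        "t_span": 1200.0,
        "conditions": [
            Condition(id=f"pg_rc{int(rc)}", enzyme_total=0.035, aa0=80.0, rc0=rc)
            for rc in (100.0, 1000.0, 5000.0)
        ],
    },
    Scenario.AA_CONSUMPTION: {
        "observables": ("AA",),
        "t_span": 120.0,
        "conditions": [
            Condition(id=f"aa_e{str(e).replace('.', 'p')}", enzyme_total=e,
                      aa0=80.0, rc0=1000.0)
            for e in (0.5, 1.0, 2.0, 20.0)
        ],
    },
    Scenario.ADRENOCHROME: {
        "observables": ("OC",),
        "t_span": 300.0,
        "conditions": [
            Condition(id=f"adr_rc{str(rc).replace('.', 'p')}", enzyme_total=0.1,
                      aa0=0.0, rc0=rc, peroxide0=1050.0,
                      profile=Profile.ADRENALINE_H2O2)
            for rc in (0.32, 0.54, 1.08, 1.62, 2.16, 3.22)
        ],
    },
}


@dataclass
class FixtureSpec:
    """Scenario, sampling times, noise level and seed for one fixture set."""

    scenario: Scenario
    sigma: float = 0.05  # multiplicative noise, fraction of the value
    seed: int = 0
    n_times: int = 10
    times: np.ndarray | None = None
    conditions: list[Condition] | None = None  # subset override

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise level must be >= 0")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if np.any(np.diff(self.times) <= 0) or np.any(self.times <= 0):
                raise ValueError("times must be positive and increasing")

    def resolved_times(self) -> np.ndarray:
        if self.times is not None:
            return self.times
        span = _SCENARIOS[self.scenario]["t_span"]
        return np.geomspace(span / 200.0, span, self.n_times)

    def resolved_conditions(self) -> list[Condition]:
        if self.conditions is not None:
            return list(self.conditions)
        return list(_SCENARIOS[self.scenario]["conditions"])


def generate_fixtures(
    spec: FixtureSpec,
    params: ParameterSet | None = None,
    outdir: str | Path | None = None,
) -> list[Dataset]:
    """Simulate each condition, sample, add seeded noise; optionally write files.

    Weights default to 1/max(series)^2 so every series contributes on the
    same scale to the calibration objective.  Noise is multiplicative
    Gaussian clipped at zero (concentration data cannot be negative).
    Writes ``<scenario>_records.csv`` and ``<scenario>_conditions.yaml`` when
    ``outdir`` is given; identical seeds give identical files.
    """
    params = params or ParameterSet.default()
    rng = np.random.default_rng(spec.seed)
    times = spec.resolved_times()
    observables = _SCENARIOS[spec.scenario]["observables"]
    t_eval = np.concatenate(([0.0], times))

    datasets: list[Dataset] = []
    for cond in spec.resolved_conditions():
        cond_params = params
        if cond.profile is not params.profile:
            cond_params = ParameterSet.default(cond.profile)
        model = build_network(params=cond_params)
        traj = simulate(model, cond.to_config(t_eval))
        for obs in observables:
            clean = np.interp(times, traj.t, traj.conc(obs))
            noisy = clean * np.clip(1.0 + spec.sigma * rng.standard_normal(len(times)), 0.0, None)
            scale = float(np.max(np.abs(clean)))
            weight = 1.0 / scale**2 if scale > 0 else 1.0
            datasets.append(
                Dataset(
                    condition=cond,
                    observable=obs,
                    times=times.copy(),
                    values=noisy,
                    weights=np.full(len(times), weight),
                )
            )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stem = spec.scenario.value
        write_datasets(
            datasets,
            outdir / f"{stem}_records.csv",
            outdir / f"{stem}_conditions.yaml",
        )
    return datasets
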