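"""Morris elementary-effects global sensitivity analysis.

One-at-a-time screening on a p-level grid in the unit hypercube, mapped to
log-uniform parameter ranges (default one decade either side of the fitted
constants).  Per parameter the method reports the mean mu and standard
deviation sigma of the elementary-effect samples and the combined ranking
statistic sqrt(mu^2 + sigma^2); sigma flags non-linearity and interactions.
The default model output is the area under the PGH2 time course.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .network import PARAMETER_NAMES, NetworkModel, ParameterSet, build_network
from .observables import auc
from .simulate import SimulationConfig, simulate

__all__ = [
    "MorrisPlan",
    "MorrisResult",
    "morris_sample",
    "elementary_effects",
    "morris_ranking",
    "evaluate_auc_pgh2",
    "run_morris",
]


@dataclass
class MorrisPlan:
    """Sampling plan: parameter ranges (log10), grid levels and trajectories."""

    names: tuple[str, ...] = PARAMETER_NAMES
    log_low: np.ndarray | None = None
    log_high: np.ndarray | None = None
    p: int = 4
    r: int = 100
    seed: int = 0
    base_params: ParameterSet = field(default_factory=ParameterSet.default)
    config: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(
            enzyme_total=0.035, aa0=80.0, rc0=100.0, t_end=1200.0, n_points=300
        )
    )

    def __post_init__(self) -> None:
        if self.p < 2 or self.p % 2:
            raise ValueError("number of levels p must be even and >= 2")
        if self.r < 2:
            raise ValueError("need at least two trajectories")
        if self.log_low is None or self.log_high is None:
            defaults = np.array([getattr(self.base_params, n) for n in self.names])
            if np.any(defaults <= 0):
                raise ValueError("log-space ranges need strictly positive defaults")
            if self.log_low is None:
                self.log_low = np.log10(defaults / 10.0)
            if self.log_high is None:
                self.log_high = np.log10(defaults * 10.0)
        self.log_low = np.asarray(self.log_low, dtype=float)
        self.log_high = np.asarray(self.log_high, dtype=float)
        if not np.all(np.isfinite(self.log_low)) or not np.all(
            np.isfinite(self.log_high)
        ):
            raise ValueError("ranges must be finite")
        if np.any(self.log_high <= self.log_low):
            raise ValueError("ranges must have positive width")

    @property
    def k(self) -> int:
        return len(self.names)

    @property
    def delta(self) -> float:
        return self.p / (2.0 * (self.p - 1))

    def map_to_params(self, x_unit: np.ndarray) -> ParameterSet:
        """Map one unit-hypercube point to a ParameterSet (log-uniform)."""
        logs = self.log_low + x_unit * (self.log_high - self.log_low)
        return self.base_params.with_values(
            **{n: float(10.0 ** v) for n, v in zip(self.names, logs)}
        )


def morris_sample(plan: MorrisPlan) -> np.ndarray:
    """r trajectories of (k+1) unit-hypercube points, one factor moved per step.

    Standard randomised-orientation construction: base points on the grid
    {0, 1/(p-1), ..., 1-delta}, each factor perturbed once by +/- delta in a
    random order.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(plan.seed)
    k, p, delta = plan.k, plan.p, plan.delta
    n_base_levels = p // 2  # levels from which +delta stays inside [0, 1]
    blocks = []
    lower = np.tril(np.ones((k + 1, k)), -1)  # B matrix
    for _ in range(plan.r):
        base = rng.integers(0, n_base_levels, size=k) / (p - 1)
        signs = rng.choice([-1.0, 1.0], size=k)
        order = rng.permutation(k)
        P = np.eye(k)[:, order]
        D = np.diag(signs)
        # B* = (J x* + delta/2 [(2B - J) D + J]) P
        J = np.ones((k + 1, k))
        bstar = (J * base + (delta / 2.0) * ((2.0 * lower - J) @ D + J)) @ P
        # signs of -1 move below the base point; shift those columns up so the
        # walk stays inside the unit cube
        for col in range(k):
            if bstar[:, col].min() < -1e-12:
                bstar[:, col] += delta
        blocks.append(bstar)
    design = np.vstack(blocks)
    if design.min() < -1e-9 or design.max() > 1 + 1e-9:
        raise AssertionError("design left the unit hypercube")
    return np.clip(design, 0.0, 1.0)


def elementary_effects(
    design: np.ndarray, outputs: np.ndarray, plan: MorrisPlan
) -> pd.DataFrame:
    """Per-parameter mean (mu) and standard deviation (sigma) of the EEs.

    EE = (y(x + delta e_i) - y(x)) / delta, signed with the direction of the
    step.  NaN outputs drop the affected effects; the count is reported.
    """
    outputs = np.asarray(outputs, dtype=float)
    if len(outputs) != len(design):
        raise ValueError("outputs not aligned with design rows")
    k = plan.k
    per_param: list[list[float]] = [[] for _ in range(k)]
    dropped = 0
    n_rows = k + 1
    for block in range(len(design) // n_rows):
        rows = slice(block * n_rows, (block + 1) * n_rows)
        x = design[rows]
        y = outputs[rows]
        for step in range(k):
            dx = x[step + 1] - x[step]
            i = int(np.argmax(np.abs(dx)))
            if np.isnan(y[step]) or np.isnan(y[step + 1]):
                dropped += 1
                continue
            per_param[i].append((y[step + 1] - y[step]) / dx[i])
    mu = np.array([np.mean(e) if e else np.nan for e in per_param])
    sigma = np.array([np.std(e, ddof=1) if len(e) > 1 else 0.0 for e in per_param])
    out = pd.DataFrame(
        {
            "parameter": list(plan.names),
            "mu": mu,
            "sigma": sigma,
            "n_effects": [len(e) for e in per_param],
        }
    )
    out.attrs["dropped_effects"] = dropped
    return out


@dataclass
class MorrisResult:
    """Per-parameter (mu, sigma) and the sqrt(mu^2 + sigma^2) ranking."""

    effects: pd.DataFrame
    plan: MorrisPlan

    @property
    def table(self) -> pd.DataFrame:
        df = self.effects.copy()
        df["ranking"] = np.sqrt(df["mu"] ** 2 + df["sigma"] ** 2)
        return df.sort_values("ranking", ascending=False).reset_index(drop=True)

    def ranking(self, parameter: str) -> float:
        row = self.effects[self.effects["parameter"] == parameter]
        if row.empty:
            raise KeyError(parameter)
        return float(np.sqrt(row["mu"].iloc[0] ** 2 + row["sigma"].iloc[0] ** 2))


def morris_ranking(result: MorrisResult) -> pd.DataFrame:
    """Parameters in descending order of sqrt(mu^2 + sigma^2)."""
    return result.table


def evaluate_auc_pgh2(params: ParameterSet, config: SimulationConfig) -> float:
    """Model output functional: AUC of the PGH2 time course, uM*s."""
    model = build_network(params=params)
    traj = simulate(model, config)
    return auc(traj.conc("PGH2"), traj.t)


def run_morris(
    plan: MorrisPlan,
    output: Callable[[ParameterSet, SimulationConfig], float] = evaluate_auc_pgh2,
) -> MorrisResult:
    """Sample, evaluate the model on every design point and analyse."""
    design = morris_sample(plan)
    outputs = np.empty(len(design))
    for i, x in enumerate(design):
        try:
            outputs[i] = output(plan.map_to_params(x), plan.config)
        except Exception:
            outputs[i] = np.nan
    return MorrisResult(effects=elementary_effects(design, outputs, plan), plan=plan)
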