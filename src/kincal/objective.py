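"""Weighted least-squares objective with plateau censoring.

Calibration data are normalized cleavage time courses per treatment
condition (e.g. ligand dose).  Once cleavage completes, the reporter
signal is no longer reliable, so observations are censored to a plateau:
from the first time a series reaches the plateau value (1 by default) all
later values are replaced by exactly that value.  The objective is the
unnormalized weighted sum of squared residuals

    F(p) = sum_i w_i * (yhat_i - y_i(p))^2

over all conditions and mapped time points, with the model simulated on
the data's own time grid.  A simulation failure evaluates to the sentinel
``FAILURE_SENTINEL`` (inf) so that optimizers can treat the start as
failed without crashing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import OdeModel, SimulationError, simulate
from .parameter_space import ParameterSpace

__all__ = [
    "Dataset",
    "ObjectiveSpec",
    "apply_plateau_rule",
    "objective",
    "FAILURE_SENTINEL",
]

FAILURE_SENTINEL = math.inf


def apply_plateau_rule(values: np.ndarray, plateau: float = 1.0) -> np.ndarray:
    """Censor a series to ``plateau`` from its first arrival there onward.

    From the first index where the value reaches >= ``plateau``, every
    subsequent value (fluctuations included) is replaced by exactly
    ``plateau``; earlier points are untouched.  Idempotent.
    """
    values = np.asarray(values, float).copy()
    hit = np.nonzero(values >= plateau)[0]
    if hit.size:
        values[hit[0]:] = plateau
    return values


@dataclass
class Dataset:
    """Tidy calibration data plus per-condition input settings.

    ``frame`` columns: condition, time_min, observable, value, weight
    (weight defaults to 1).  ``settings`` maps each condition label to
    initial-concentration overrides (e.g. ligand dose -> initial ligand
    amount).
    """

    frame: pd.DataFrame
    settings: dict[str, dict[str, float]] = field(default_factory=dict)

    REQUIRED = ("condition", "time_min", "observable", "value")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset frame missing columns {missing}")
        if "weight" not in self.frame.columns:
            self.frame = self.frame.assign(weight=1.0)
        if (self.frame["weight"] < 0).any():
            raise ValueError("weights must be >= 0")
        for cond, group in self.frame.groupby("condition"):
            for obs, sub in group.groupby("observable"):
                t = sub["time_min"].to_numpy()
                if not np.all(np.diff(t) > 0):
                    raise ValueError(
                        f"times not strictly increasing for condition {cond!r}, "
                        f"observable {obs!r}"
                    )

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.frame["condition"]))

    @property
    def observables(self) -> list[str]:
        return list(dict.fromkeys(self.frame["observable"]))

    def n_points(self) -> int:
        return len(self.frame)

    def with_plateau(self, plateau: float = 1.0,
                     observables: Sequence[str] | None = None) -> "Dataset":
        """Copy with the plateau rule applied per (condition, observable)."""
        frame = self.frame.sort_values(["condition", "observable", "time_min"],
                                       kind="stable").reset_index(drop=True)
        observables = set(observables if observables is not None
                          else frame["observable"].unique())
        parts = []
        for (cond, obs), sub in frame.groupby(["condition", "observable"], sort=False):
            sub = sub.copy()
            if obs in observables:
                sub["value"] = apply_plateau_rule(sub["value"].to_numpy(), plateau)
            parts.append(sub)
        return Dataset(pd.concat(parts, ignore_index=True), dict(self.settings))

    # -- persistence -------------------------------------------------------
    def save(self, csv_path, settings_path=None) -> None:
        self.frame.to_csv(csv_path, index=False)
        if settings_path is not None:
            with open(settings_path, "w") as fh:
                json.dump(self.settings, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, csv_path, settings_path=None) -> "Dataset":
        frame = pd.read_csv(csv_path)
        settings = {}
        if settings_path is not None:
            with open(settings_path) as fh:
                settings = json.load(fh)
        return cls(frame, settings)


@dataclass
class ObjectiveSpec:
    """Everything needed to evaluate F(p) for one calibration problem.

    ``mapping`` pairs model observables with dataset observables (defaults
    to the identity on the dataset's observables).  ``normalize`` divides F
    by the number of data points, for comparability across datasets; the
    default is the plain (unnormalized) weighted sum of squares.
    """

    dataset: Dataset
    model: OdeModel
    space: ParameterSpace
    mapping: dict[str, str] | None = None
    plateau: bool = True
    plateau_value: float = 1.0
    normalize: bool = False
    rtol: float = 1e-6
    atol: float = 1e-9

    def __post_init__(self):
        if self.mapping is None:
            self.mapping = {obs: obs for obs in self.dataset.observables}
        for model_obs, data_obs in self.mapping.items():
            if (model_obs not in self.model.observables
                    and model_obs not in self.model.species_names):
                raise ValueError(f"model has no observable {model_obs!r}")
            if data_obs not in self.dataset.observables:
                raise ValueError(f"dataset has no observable {data_obs!r}")
        data = (self.dataset.with_plateau(self.plateau_value,
                                          list(self.mapping.values()))
                if self.plateau else self.dataset)
        # precompile per-condition grids and observation arrays
        self._blocks = []
        for cond in data.conditions:
            sub = data.frame[data.frame["condition"] == cond]
            # integration always starts at t=0 (stimulus addition), even
            # when the first observation comes later
            grid = np.unique(np.append(sub["time_min"].to_numpy(), 0.0))
            obs_arrays = []
            for model_obs, data_obs in self.mapping.items():
                rows = sub[sub["observable"] == data_obs]
                idx = np.searchsorted(grid, rows["time_min"].to_numpy())
                obs_arrays.append(
                    (model_obs, idx, rows["value"].to_numpy(),
                     rows["weight"].to_numpy())
                )
            self._blocks.append(
                (cond, data.settings.get(cond, {}), grid, obs_arrays)
            )
        self._n_points = data.n_points()

    def simulate_condition(self, condition: str,
                           parameters: Mapping[str, float] | None = None,
                           grid: np.ndarray | None = None):
        """Simulate the model under one condition's initial settings."""
        for cond, settings, cond_grid, _ in self._blocks:
            if cond == condition:
                model = self.model.with_initial(**settings) if settings else self.model
                return simulate(model, parameters,
                                grid=cond_grid if grid is None else grid,
                                rtol=self.rtol, atol=self.atol,
                                condition_label=condition)
        raise KeyError(f"unknown condition {condition!r}")


def objective(free_values: Sequence[float], spec: ObjectiveSpec) -> float:
    """Weighted least-squares misfit of the model at one free-parameter vector.

    ``free_values`` are natural-unit values of ``spec.space.free_ids``;
    pinned parameters stay at nominal.  Returns ``FAILURE_SENTINEL`` when
    any condition's simulation fails.
    """
    params = spec.space.full_dict(free_values)
    total = 0.0
    for cond, settings, grid, obs_arrays in spec._blocks:
        model = spec.model.with_initial(**settings) if settings else spec.model
        try:
            traj = simulate(model, params, grid=grid,
                            rtol=spec.rtol, atol=spec.atol, condition_label=cond)
        except SimulationError:
            return FAILURE_SENTINEL
        for model_obs, idx, values, weights in obs_arrays:
            sim = traj.get(model_obs)[idx]
            total += float(np.sum(weights * (values - sim) ** 2))
    if spec.normalize and spec._n_points:
        total /= spec._n_points
    return total
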