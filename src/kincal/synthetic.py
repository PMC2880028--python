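"""Synthetic fixtures: a toy snap-action death cascade and noisy datasets.

The toy cascade emulates the qualitative biology of receptor-triggered
apoptosis with a deliberately small mass-action network (16 species, 12
rate constants): ligand binds receptor; the ligand-receptor complex
activates initiator caspase (C8); C8 activates effector caspase (C3); C3
cleaves the death substrate (PARP).  An inhibitor pool (XIAP analog)
sequesters free C3, producing a long delay, while C3 triggers release of
a mitochondrial pro-apoptotic store (Smac analog) that neutralizes the
inhibitor — a positive feedback that makes substrate cleavage complete in
a rapid, switch-like burst once free C3 escapes inhibition
("variable-delay, snap-action" dynamics).  A parallel caspase-6-analog
branch is catalytic dead weight: it consumes nothing that feeds the death
pathway, so cleavage is insensitive to it by construction.

Known ground truth makes every pipeline stage testable: sensitivity signs
(inhibitor negative, store positive, dispensable branch nil), dominant-
parameter rankings, and full parameter-recovery calibration experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import OdeModel, Reaction, Species, extract_features, parse_reaction, simulate
from .objective import Dataset, apply_plateau_rule
from .parameter_space import ParameterSpace, ParameterSpec

__all__ = [
    "TRUE_PARAMETERS",
    "INITIAL_CONCENTRATIONS",
    "ToyCascadeSpec",
    "SyntheticDataset",
    "ConstructionError",
    "build_toy_cascade",
    "toy_parameter_space",
    "calibration_space",
    "generate_dataset",
    "bimodal_problem",
]


class ConstructionError(RuntimeError):
    """The requested cascade violates one of its behavioral invariants."""


#: Ground-truth rate constants (per nM per min for bimolecular steps,
#: per min for unimolecular ones).
TRUE_PARAMETERS: dict[str, float] = {
    "k_bind": 3.0e-5,
    "k_unbind": 1.0e-5,
    "k_c8_act": 6.0e-4,
    "k_c3_act": 3.0e-4,
    "k_parp": 2.5e-2,
    "k_xiap_bind": 3.0e-1,
    "k_xiap_release": 5.0e-3,
    "k_smac_release": 8.0e-2,
    "k_smac_bind": 5.0e-3,
    "k_smac_unbind": 1.0e-5,
    "k_c6_act": 1.0e-4,
    "k_c6_deg": 1.0e-2,
}

#: Non-zero initial concentrations (nM-scale arbitrary units).
INITIAL_CONCENTRATIONS: dict[str, float] = {
    "R": 40.0,
    "pC8": 30.0,
    "pC3": 100.0,
    "PARP": 100.0,
    "XIAP": 50.0,
    "Smac_m": 120.0,
    "pC6": 100.0,
}

_REACTIONS = [
    "L + R -> LR @ k_bind",
    "LR -> L + R @ k_unbind",
    "LR + pC8 -> LR + C8 @ k_c8_act",
    "C8 + pC3 -> C8 + C3 @ k_c3_act",
    "C3 + PARP -> C3 + cPARP @ k_parp",
    "C3 + XIAP -> C3_XIAP @ k_xiap_bind",
    "C3_XIAP -> C3 + XIAP @ k_xiap_release",
    "C3 + Smac_m -> C3 + Smac @ k_smac_release",
    "Smac + XIAP -> Smac_XIAP @ k_smac_bind",
    "Smac_XIAP -> Smac + XIAP @ k_smac_unbind",
    "C3 + pC6 -> C3 + C6 @ k_c6_act",
    "C6 -> 0 @ k_c6_deg",
]


@dataclass(frozen=True)
class ToyCascadeSpec:
    """Ground truth and study conditions for the toy cascade."""

    true_parameters: dict[str, float] = field(
        default_factory=lambda: dict(TRUE_PARAMETERS))
    initial_concentrations: dict[str, float] = field(
        default_factory=lambda: dict(INITIAL_CONCENTRATIONS))
    horizon: float = 720.0
    dose_levels: tuple[float, ...] = (10.0, 50.0, 250.0)
    dose_species: str = "L"
    sampling_interval: float = 3.0

    def grid(self) -> np.ndarray:
        n = int(round(self.horizon / self.sampling_interval)) + 1
        return np.linspace(0.0, self.horizon, n)


def build_toy_cascade(spec: ToyCascadeSpec | None = None, *,
                      certify: bool = True) -> OdeModel:
    """Assemble the cascade model at its ground-truth parameters.

    With ``certify=True`` (default) the three behavioral invariants are
    checked by simulation at the top dose: (1) the cell dies within the
    horizon with a sharp switch (t_switch < 0.2 t_delay); (2) removing the
    caspase-6-analog branch changes final cleavage by < 1%; (3) median
    delay time strictly decreases with dose.  Violations raise
    :class:`ConstructionError` naming the failed invariant.
    """
    spec = spec or ToyCascadeSpec()
    init = spec.initial_concentrations
    names = ["L", "R", "LR", "pC8", "C8", "pC3", "C3", "PARP", "cPARP",
             "XIAP", "C3_XIAP", "Smac_m", "Smac", "Smac_XIAP", "pC6", "C6"]
    compartments = {"Smac_m": "mitochondria"}
    species = tuple(
        Species(n, init.get(n, 0.0), compartments.get(n, "cytoplasm"))
        for n in names
    )
    model = OdeModel(
        species=species,
        reactions=tuple(parse_reaction(r) for r in _REACTIONS),
        parameters=dict(spec.true_parameters),
        observables={"cleaved_fraction": "cPARP / (PARP + cPARP)"},
        pools={"parp_total": ("PARP", "cPARP"),
               "xiap_total": ("XIAP", "C3_XIAP", "Smac_XIAP")},
        name="toy_snap_action_cascade",
    )
    if certify:
        _certify(model, spec)
    return model


def _certify(model: OdeModel, spec: ToyCascadeSpec) -> None:
    grid = spec.grid()
    top = max(spec.dose_levels)
    delays = {}
    for dose in sorted(spec.dose_levels):
        traj = simulate(model.with_initial(**{spec.dose_species: dose}), grid=grid)
        feats = extract_features(traj)
        delays[dose] = feats.t_delay
        if dose == top:
            if not feats.dead:
                raise ConstructionError(
                    f"invariant: top dose {top} must die within the horizon")
            if feats.t_switch is None or feats.t_switch >= 0.2 * feats.t_delay:
                raise ConstructionError(
                    "invariant: switch must be sharp "
                    f"(t_switch={feats.t_switch}, t_delay={feats.t_delay})")
    defined = [d for d in sorted(spec.dose_levels) if delays[d] is not None]
    vals = [delays[d] for d in defined]
    if any(b >= a for a, b in zip(vals, vals[1:])) if len(vals) > 1 else False:
        raise ConstructionError(f"invariant: t_delay must decrease with dose, got {delays}")
    # dispensable branch: silencing it must not move final cleavage
    silenced = model.with_parameters({"k_c6_act": 0.0})
    base = simulate(model.with_initial(**{spec.dose_species: top}), grid=grid)
    off = simulate(silenced.with_initial(**{spec.dose_species: top}), grid=grid)
    f_base = base.get("cleaved_fraction")[-1]
    f_off = off.get("cleaved_fraction")[-1]
    if abs(f_base - f_off) > 0.01 * max(f_base, 1e-12):
        raise ConstructionError(
            "invariant: caspase-6-analog branch must be dispensable "
            f"(final cleavage {f_base:.4f} vs {f_off:.4f} without it)")


_NARROWER_TIERS = {
    # tier semantics follow common practice for these reaction classes:
    # caspase-cleavage steps (effector activation, substrate cleavage,
    # dispensable-branch activation, store release) have prior kinetic
    # support -> medium (x10); inhibitor sequestration and store-inhibitor
    # binding are the best characterized -> narrow (x2); receptor-stage
    # constants stay wide (x100)
    "k_c3_act": "medium", "k_c6_act": "medium",
    "k_parp": "medium", "k_smac_release": "medium",
    "k_xiap_bind": "narrow", "k_xiap_release": "narrow",
    "k_smac_bind": "narrow", "k_smac_unbind": "narrow",
}


def toy_parameter_space(model: OdeModel, *, tier: str = "wide",
                        tiers: dict[str, str] | None = None) -> ParameterSpace:
    """Space centered on the model's own (ground-truth) parameter values.

    Used for sensitivity analysis, where sampling explores uncertainty
    around the nominal point.  Default tiers mirror the usual practice of
    narrowing bounds for kinetically well characterized steps.
    """
    return ParameterSpace.from_model(
        model, tier=tier, tiers=_NARROWER_TIERS if tiers is None else tiers)


def calibration_space(model: OdeModel, *, seed: int = 20, offset_decades: float = 0.4,
                      tier: str = "medium") -> ParameterSpace:
    """Space whose nominals are plausible literature-style guesses, not truth.

    Each nominal is the true value perturbed by a seeded log-uniform factor
    within ±``offset_decades`` decades, with bounds wide enough
    (default ×10 tier) to contain the truth.  This is the honest starting
    point for calibration experiments: pinned parameters sit at slightly
    wrong values, and freeing more dominant parameters improves the
    attainable fit.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for pid, true_value in model.parameters.items():
        factor = 10.0 ** rng.uniform(-offset_decades, offset_decades)
        specs.append(ParameterSpec(pid, true_value * factor, tier=tier))
    return ParameterSpace(specs)


@dataclass
class SyntheticDataset:
    """A calibration dataset together with its generating ground truth."""

    dataset: Dataset
    true_parameters: dict[str, float]
    noise_sd: float
    seed: int | None
    sampling_interval: float


def generate_dataset(
    model: OdeModel,
    parameters: dict[str, float] | None = None,
    doses: tuple[float, ...] = (10.0, 50.0, 250.0),
    *,
    dose_species: str = "L",
    sampling_interval: float = 3.0,
    horizon: float = 720.0,
    noise_sd: float = 0.02,
    seed: int | None = None,
    observable: str = "cleaved_fraction",
    plateau: float = 1.0,
) -> SyntheticDataset:
    """Noisy single-cell-like cleavage time courses at each ligand dose.

    Simulates the model at the (ground-truth) parameters, samples the
    cleavage fraction on the regular reporter grid, adds seeded i.i.d.
    Gaussian noise truncated at zero, and applies the plateau-censoring
    rule.  Bit-identical regeneration from the same seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    parameters = dict(parameters or model.parameters)
    n = int(round(horizon / sampling_interval)) + 1
    grid = np.linspace(0.0, horizon, n)
    rng = np.random.default_rng(seed)
    frames = []
    settings = {}
    for dose in doses:
        label = f"dose_{dose:g}"
        traj = simulate(model.with_initial(**{dose_species: dose}),
                        parameters, grid=grid, condition_label=label)
        values = traj.get(observable).copy()
        if noise_sd > 0:
            values = np.maximum(values + rng.normal(0.0, noise_sd, values.shape), 0.0)
        values = apply_plateau_rule(values, plateau)
        frames.append(pd.DataFrame(
            {"condition": label, "time_min": grid, "observable": observable,
             "value": values, "weight": 1.0}))
        settings[label] = {dose_species: float(dose)}
    dataset = Dataset(pd.concat(frames, ignore_index=True), settings)
    return SyntheticDataset(dataset=dataset, true_parameters=parameters,
                            noise_sd=noise_sd, seed=seed,
                            sampling_interval=sampling_interval)


def bimodal_problem(
    *, seed: int = 0, noise_sd: float = 0.0,
    shift_decades: float = 1.5,
) -> tuple[Dataset, OdeModel, ParameterSpace, dict[str, float], dict[str, float]]:
    """A deliberately multimodal calibration problem from mixed datasets.

    Two incompatible datasets are concatenated under distinct condition
    labels: the full three-dose panel generated at the default ground
    truth, plus one top-dose time course generated with receptor binding
    ``shift_decades`` decades faster.  No parameter vector fits both, and
    over the two freed parameters (ligand binding and effector-caspase
    activation) the conflict produces multiple local optima: a deep region
    that fits the majority dataset, shallower compensation optima, and
    no-death flats near the lower bounds.  Deterministic local searches
    started from a bound-corner get trapped on the shallow structure while
    multistart/hybrid reach the deep one, and the sorted multistart
    objective curve shows the plateau signature of repeated local optima.

    Returns (mixed dataset, model, 2-parameter space, truth A, truth B).
    """
    free_ids = ("k_bind", "k_c8_act", "k_c3_act")
    model = build_toy_cascade(certify=False)
    theta_a = dict(model.parameters)
    theta_b = dict(theta_a)
    theta_b["k_bind"] = theta_a["k_bind"] * 10.0**shift_decades

    ds_a = generate_dataset(model, theta_a, doses=(10.0, 50.0, 250.0),
                            noise_sd=noise_sd, seed=seed).dataset
    ds_b = generate_dataset(model, theta_b, doses=(250.0,),
                            noise_sd=noise_sd,
                            seed=None if seed is None else seed + 1).dataset
    frame_b = ds_b.frame.assign(
        condition=ds_b.frame["condition"].map(lambda c: c + "_B"))
    settings = dict(ds_a.settings)
    settings.update({k + "_B": v for k, v in ds_b.settings.items()})
    mixed = Dataset(pd.concat([ds_a.frame, frame_b], ignore_index=True), settings)

    specs = [
        ParameterSpec(pid, value, tier=None,
                      lower=value / 1000.0, upper=value * 1000.0)
        if pid in ("k_bind", "k_c8_act")
        else ParameterSpec(pid, value, tier="wide")
        for pid, value in theta_a.items()
    ]
    space = ParameterSpace(specs, list(free_ids))
    return mixed, model, space, theta_a, theta_b
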