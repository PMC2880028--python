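"""Mass-action reaction networks as ODE systems.

A model is a list of species with initial concentrations, a list of
irreversible mass-action reactions (reversible steps are written as two
reactions), a map of rate-constant values, and named observables defined
as arithmetic expressions over species concentrations.  The right-hand
side generated from the reaction list is

    d[x]/dt = N @ r(x),     r_j = k_j * prod_i [x_i]^s_ij

with N the net stoichiometry matrix and s_ij the reactant stoichiometry
of species i in reaction j.

Models can be built programmatically or read from a small declarative
text format (see :func:`load_model`), e.g.::

    # kincal-model v1
    species L 250
    species R 200 compartment=membrane
    reaction L + R -> LR @ k_bind
    parameter k_bind 3e-4
    observable cleaved_fraction = cPARP / (PARP + cPARP)
    pool parp_total = PARP + cPARP
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint, solve_ivp

__all__ = [
    "Species",
    "Reaction",
    "OdeModel",
    "Trajectory",
    "DynamicFeatures",
    "ModelDefinitionError",
    "SimulationError",
    "FeatureError",
    "parse_reaction",
    "build_rhs",
    "simulate",
    "extract_features",
    "load_model",
    "save_model",
]


class ModelDefinitionError(ValueError):
    """Raised when a model references unknown species/parameters or violates invariants."""


class SimulationError(RuntimeError):
    """Integration failure; carries the offending parameter vector and failure time."""

    def __init__(self, message: str, parameters=None, time=None):
        super().__init__(message)
        self.parameters = parameters
        self.time = time


class FeatureError(ValueError):
    """Requested observable absent from a trajectory."""


@dataclass(frozen=True)
class Species:
    name: str
    initial_concentration: float = 0.0
    compartment: str = "cytoplasm"

    def __post_init__(self):
        if self.initial_concentration < 0:
            raise ModelDefinitionError(
                f"species {self.name!r}: initial concentration must be >= 0, "
                f"got {self.initial_concentration}"
            )


@dataclass(frozen=True)
class Reaction:
    """An irreversible mass-action reaction.

    ``reactants`` and ``products`` are tuples of (species name, stoichiometry).
    The rate is ``k * prod([reactant]^stoichiometry)`` with ``k`` looked up
    by ``rate_constant``.
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_constant: str

    def __post_init__(self):
        for name, stoich in (*self.reactants, *self.products):
            if not (isinstance(stoich, (int, np.integer)) and stoich > 0):
                raise ModelDefinitionError(
                    f"reaction @ {self.rate_constant}: stoichiometry of {name!r} "
                    f"must be a positive integer, got {stoich!r}"
                )


_REACTION_RE = re.compile(r"^(?P<lhs>[^-@>]*)->(?P<rhs>[^@]*)@(?P<k>.+)$")


def _parse_side(text: str, rate_id: str) -> tuple[tuple[str, int], ...]:
    text = text.strip()
    if text in ("", "0", "∅"):
        return ()
    terms = []
    for term in text.split("+"):
        term = term.strip()
        m = re.match(r"^(?:(\d+)\s+)?([A-Za-z_]\w*)$", term)
        if not m:
            raise ModelDefinitionError(
                f"reaction @ {rate_id}: cannot parse term {term!r}"
            )
        stoich = int(m.group(1)) if m.group(1) else 1
        terms.append((m.group(2), stoich))
    return tuple(terms)


def parse_reaction(text: str) -> Reaction:
    """Parse ``"A + 2 B -> C @ k1"``; an empty side (or ``0``) means none."""
    m = _REACTION_RE.match(text.strip())
    if not m:
        raise ModelDefinitionError(f"cannot parse reaction {text!r}")
    k = m.group("k").strip()
    return Reaction(
        reactants=_parse_side(m.group("lhs"), k),
        products=_parse_side(m.group("rhs"), k),
        rate_constant=k,
    )


@dataclass
class OdeModel:
    """A mass-action reaction network with named observables.

    ``observables`` maps a name to an arithmetic expression over species
    names (operators ``+ - * / **`` and parentheses).  ``pools`` declares
    conservation pools (lists of species whose summed concentration should
    stay constant along any trajectory); they are used for validation, not
    for simulation.
    """

    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    parameters: dict[str, float]
    observables: dict[str, str] = field(default_factory=dict)
    pools: dict[str, tuple[str, ...]] = field(default_factory=dict)
    name: str = "model"

    def __post_init__(self):
        self.species = tuple(
            s if isinstance(s, Species) else Species(*s) for s in self.species
        )
        self.reactions = tuple(self.reactions)
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ModelDefinitionError(f"duplicate species names: {dup}")
        self._index = {n: i for i, n in enumerate(names)}
        for rxn in self.reactions:
            for sname, _ in (*rxn.reactants, *rxn.products):
                if sname not in self._index:
                    raise ModelDefinitionError(
                        f"reaction @ {rxn.rate_constant} references unknown "
                        f"species {sname!r}"
                    )
            if rxn.rate_constant not in self.parameters:
                raise ModelDefinitionError(
                    f"reaction references unknown rate constant "
                    f"{rxn.rate_constant!r}"
                )
        for pool, members in self.pools.items():
            for sname in members:
                if sname not in self._index:
                    raise ModelDefinitionError(
                        f"pool {pool!r} references unknown species {sname!r}"
                    )

    # -- convenience accessors -------------------------------------------
    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def parameter_ids(self) -> list[str]:
        return list(self.parameters)

    def species_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ModelDefinitionError(f"unknown species {name!r}") from None

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species], float)

    def with_initial(self, **overrides: float) -> "OdeModel":
        """Copy of the model with some initial concentrations replaced."""
        for name in overrides:
            self.species_index(name)
        new_species = tuple(
            replace(s, initial_concentration=float(overrides[s.name]))
            if s.name in overrides
            else s
            for s in self.species
        )
        return replace(self, species=new_species)

    def with_parameters(self, updates: Mapping[str, float]) -> "OdeModel":
        unknown = set(updates) - set(self.parameters)
        if unknown:
            raise ModelDefinitionError(f"unknown parameters: {sorted(unknown)}")
        params = dict(self.parameters)
        params.update({k: float(v) for k, v in updates.items()})
        return replace(self, parameters=params)


try:  # optional accelerator; the pure-numpy path is always available
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is an optional extra
    _njit = None

if _njit is not None:

    @_njit(cache=False)
    def _mass_action_kernel(y, p, kidx, exponents, net):  # pragma: no cover - jitted
        nr, ns = exponents.shape
        rates = np.empty(nr)
        for j in range(nr):
            r = p[kidx[j]]
            for i in range(ns):
                e = exponents[j, i]
                if e != 0.0:
                    c = y[i] if y[i] > 0.0 else 0.0
                    r *= c if e == 1.0 else c**e
            rates[j] = r
        dy = np.zeros(ns)
        for j in range(nr):
            for i in range(ns):
                n = net[i, j]
                if n != 0.0:
                    dy[i] += n * rates[j]
        return dy

else:
    _mass_action_kernel = None


def build_rhs(model: OdeModel) -> Callable[[float, np.ndarray, np.ndarray], np.ndarray]:
    """Return the vector field ``f(t, y, p) -> dy/dt`` for the reaction network.

    ``p`` is ordered like ``model.parameter_ids``.  Concentrations are
    floored at zero inside the rate law so that tiny solver undershoots do
    not flip rate signs.  The compiled vector field is cached on the model
    (rates depend only on the network structure, not the parameter values).
    """
    cached = getattr(model, "_rhs_cache", None)
    if cached is not None:
        return cached
    ns, nr = len(model.species), len(model.reactions)
    exponents = np.zeros((nr, ns))
    net = np.zeros((ns, nr))
    pindex = {pid: i for i, pid in enumerate(model.parameter_ids)}
    kidx = np.zeros(nr, dtype=np.int64)
    for j, rxn in enumerate(model.reactions):
        kidx[j] = pindex[rxn.rate_constant]
        for sname, stoich in rxn.reactants:
            i = model.species_index(sname)
            exponents[j, i] += stoich
            net[i, j] -= stoich
        for sname, stoich in rxn.products:
            net[model.species_index(sname), j] += stoich

    if _mass_action_kernel is not None:

        def rhs(t: float, y: np.ndarray, p: np.ndarray) -> np.ndarray:
            return _mass_action_kernel(y, p, kidx, exponents, net)

    else:

        def rhs(t: float, y: np.ndarray, p: np.ndarray) -> np.ndarray:
            conc = np.maximum(y, 0.0)
            rates = p[kidx] * np.prod(conc**exponents, axis=1)
            return net @ rates

    object.__setattr__(model, "_rhs_cache", rhs)
    return rhs


@dataclass
class Trajectory:
    """Observable time courses from one simulation.

    ``values`` holds one column per observable, indexed by time (minutes);
    ``states`` holds the raw species concentrations on the same grid.
    """

    times: np.ndarray
    values: pd.DataFrame
    states: pd.DataFrame
    condition_label: str = ""

    def get(self, output_id: str) -> np.ndarray:
        """Series for a named observable, falling back to raw species."""
        if output_id in self.values.columns:
            return self.values[output_id].to_numpy()
        if output_id in self.states.columns:
            return self.states[output_id].to_numpy()
        raise FeatureError(f"trajectory has no observable or species {output_id!r}")

    def to_tidy(self) -> pd.DataFrame:
        """Long-format export: condition, time_min, observable, value."""
        out = self.values.reset_index(names="time_min").melt(
            id_vars="time_min", var_name="observable", value_name="value"
        )
        out.insert(0, "condition", self.condition_label)
        return out


def _eval_observable(expr: str, env: dict[str, np.ndarray]) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        val = eval(expr, {"__builtins__": {}}, env)  # noqa: S307 - arithmetic over species only
    return np.asarray(val, float)


def simulate(
    model: OdeModel,
    parameters: Mapping[str, float] | Sequence[float] | None = None,
    horizon: float = 720.0,
    grid: np.ndarray | None = None,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    condition_label: str = "",
) -> Trajectory:
    """Integrate the model and evaluate its observables on a time grid.

    ``parameters`` may be a mapping (subset allowed; missing ids keep their
    nominal value) or a full vector ordered like ``model.parameter_ids``;
    ``None`` uses the nominal values.  ``grid`` defaults to 241 evenly
    spaced points on ``[0, horizon]``.  Raises :class:`SimulationError` on
    integrator failure or non-finite states.
    """
    if parameters is None:
        pvec = np.array([model.parameters[k] for k in model.parameter_ids], float)
    elif isinstance(parameters, Mapping):
        merged = dict(model.parameters)
        merged.update(parameters)
        pvec = np.array([merged[k] for k in model.parameter_ids], float)
    else:
        pvec = np.asarray(parameters, float)
        if pvec.shape != (len(model.parameters),):
            raise ModelDefinitionError(
                f"parameter vector has length {pvec.size}, expected "
                f"{len(model.parameters)}"
            )
    if grid is None:
        if horizon <= 0:
            raise ValueError("horizon must be positive")
        grid = np.linspace(0.0, horizon, 241)
    grid = np.asarray(grid, float)

    rhs = build_rhs(model)
    if method == "LSODA":
        # the odeint entry point to the same LSODA core has far less
        # per-step overhead than solve_ivp
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            y, info = odeint(
                rhs, model.initial_state(), grid, args=(pvec,),
                rtol=rtol, atol=atol, tfirst=True, full_output=True,
            )
        if info["message"] != "Integration successful." or not np.all(np.isfinite(y)):
            t_fail = float(info["tcur"][-1]) if len(info.get("tcur", [])) else grid[0]
            raise SimulationError(
                f"integration failed at t={t_fail:g}: {info['message']}",
                parameters=pvec,
                time=t_fail,
            )
        states = np.maximum(y, 0.0)  # clip solver undershoot for observables
    else:
        sol = solve_ivp(
            rhs,
            (grid[0], grid[-1]),
            model.initial_state(),
            t_eval=grid,
            args=(pvec,),
            method=method,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            t_fail = sol.t[-1] if sol.t.size else grid[0]
            raise SimulationError(
                f"integration failed at t={t_fail:g}: {sol.message}",
                parameters=pvec,
                time=t_fail,
            )
        states = np.maximum(sol.y.T, 0.0)
    states_df = pd.DataFrame(states, index=pd.Index(grid, name="time_min"),
                             columns=model.species_names)
    env = {name: states_df[name].to_numpy() for name in model.species_names}
    obs = {}
    for name, expr in model.observables.items():
        obs[name] = np.nan_to_num(_eval_observable(expr, env), nan=0.0)
    values = pd.DataFrame(obs, index=states_df.index)
    return Trajectory(times=grid, values=values, states=states_df,
                      condition_label=condition_label)


@dataclass(frozen=True)
class DynamicFeatures:
    """Scalar descriptors of a cleavage time course.

    ``t_delay`` is the interpolated first crossing of the death threshold
    (None if never crossed); ``t_switch`` is the 10-to-90% rise time of the
    final cleavage level; ``dead`` mirrors whether the threshold was crossed.
    """

    t_delay: float | None
    t_switch: float | None
    dead: bool


def _first_crossing(times: np.ndarray, values: np.ndarray, level: float) -> float | None:
    """Linearly interpolated first upward crossing of ``level``."""
    if values[0] >= level:
        return float(times[0])
    above = np.nonzero(values >= level)[0]
    if above.size == 0:
        return None
    i = above[0]
    t0, t1 = times[i - 1], times[i]
    v0, v1 = values[i - 1], values[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (level - v0) * (t1 - t0) / (v1 - v0))


def extract_features(
    traj: Trajectory,
    observable: str = "cleaved_fraction",
    threshold: float = 0.5,
    switch_levels: tuple[float, float] = (0.1, 0.9),
) -> DynamicFeatures:
    """Delay time, switching time and death call from a cleavage trajectory.

    ``t_delay`` is the first time the observable crosses ``threshold``
    (linear interpolation between samples); the cell is scored dead iff the
    crossing occurs within the simulated horizon.  ``t_switch`` is the time
    between crossing ``switch_levels`` fractions of the *final* cleavage
    level, a standard width measure for a snap-action switch.
    """
    values = traj.get(observable)
    times = traj.times
    t_delay = _first_crossing(times, values, threshold)
    final = values[-1]
    t_switch = None
    if final > 0:
        lo = _first_crossing(times, values, switch_levels[0] * final)
        hi = _first_crossing(times, values, switch_levels[1] * final)
        if lo is not None and hi is not None:
            t_switch = hi - lo
    return DynamicFeatures(t_delay=t_delay, t_switch=t_switch, dead=t_delay is not None)


# ----------------------------------------------------------------------
# model-file dialect
# ----------------------------------------------------------------------

_HEADER = "# kincal-model v1"


def save_model(model: OdeModel, path) -> None:
    lines = [_HEADER, f"name {model.name}"]
    for s in model.species:
        line = f"species {s.name} {s.initial_concentration:.17g}"
        if s.compartment != "cytoplasm":
            line += f" compartment={s.compartment}"
        lines.append(line)
    for rxn in model.reactions:
        def side(terms):
            if not terms:
                return "0"
            return " + ".join(n if st == 1 else f"{st} {n}" for n, st in terms)
        lines.append(
            f"reaction {side(rxn.reactants)} -> {side(rxn.products)} @ {rxn.rate_constant}"
        )
    for pid, value in model.parameters.items():
        lines.append(f"parameter {pid} {value:.17g}")
    for name, expr in model.observables.items():
        lines.append(f"observable {name} = {expr}")
    for name, members in model.pools.items():
        lines.append(f"pool {name} = " + " + ".join(members))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_model(path) -> OdeModel:
    with open(path) as fh:
        raw = fh.read().splitlines()
    if not raw or raw[0].strip() != _HEADER:
        raise ModelDefinitionError(
            f"{path}: missing model-file header {_HEADER!r}"
        )
    species, reactions, observables, pools = [], [], {}, {}
    parameters: dict[str, float] = {}
    name = "model"
    for lineno, line in enumerate(raw[1:], start=2):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        kind, _, rest = line.partition(" ")
        rest = rest.strip()
        try:
            if kind == "name":
                name = rest
            elif kind == "species":
                parts = rest.split()
                comp = "cytoplasm"
                if len(parts) == 3 and parts[2].startswith("compartment="):
                    comp = parts[2].split("=", 1)[1]
                species.append(Species(parts[0], float(parts[1]), comp))
            elif kind == "reaction":
                reactions.append(parse_reaction(rest))
            elif kind == "parameter":
                pid, value = rest.split()
                parameters[pid] = float(value)
            elif kind == "observable":
                oname, _, expr = rest.partition("=")
                observables[oname.strip()] = expr.strip()
            elif kind == "pool":
                pname, _, expr = rest.partition("=")
                pools[pname.strip()] = tuple(t.strip() for t in expr.split("+"))
            else:
                raise ModelDefinitionError(f"unknown directive {kind!r}")
        except ModelDefinitionError:
            raise
        except Exception as exc:
            raise ModelDefinitionError(f"{path}:{lineno}: {exc}") from exc
    return OdeModel(
        species=tuple(species),
        reactions=tuple(reactions),
        parameters=parameters,
        observables=observables,
        pools=pools,
        name=name,
    )
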