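"""Normalized local sensitivities and their averaged global index.

The local sensitivity of output ``y_i(t)`` to input ``p_j`` is the
dimensionless log-log derivative

    S_ij(t) = (dy_i(t)/dp_j) * (p_j / y_i(t)),

estimated by central finite differences with a relative step (default
1e-3).  Inputs may be rate constants or initial concentrations.  A global
index is obtained by integrating |S_ij(t)| over the monitoring window
(trapezoid, normalized by the window length) and averaging over parameter
vectors sampled within their uncertainty bounds; keeping the sign of the
integral instead preserves the direction of the effect and is what the
qualitative-validation stage inspects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import OdeModel, SimulationError, simulate
from .parameter_space import ParameterSpace

__all__ = [
    "local_sensitivity",
    "integrated_sensitivity",
    "global_average_sensitivity",
    "qualitative_report",
    "SensitivityResult",
    "SensitivityAbort",
]

logger = logging.getLogger(__name__)


class SensitivityAbort(RuntimeError):
    """Raised when more than the tolerated fraction of samples fail."""


def _perturbed_output(
    model: OdeModel,
    parameters: dict[str, float],
    input_id: str,
    factor: float,
    output_id: str,
    times: np.ndarray,
    rtol: float,
    atol: float,
) -> np.ndarray:
    """Output series with one input (rate constant or initial conc.) scaled."""
    if input_id in model.parameters:
        params = dict(parameters)
        params[input_id] = parameters[input_id] * factor
        traj = simulate(model, params, grid=times, rtol=rtol, atol=atol)
    elif input_id in model.species_names:
        base = model.species[model.species_index(input_id)].initial_concentration
        if base <= 0:
            raise ValueError(
                f"initial concentration of {input_id!r} is zero; a relative "
                "perturbation is undefined"
            )
        traj = simulate(
            model.with_initial(**{input_id: base * factor}),
            parameters, grid=times, rtol=rtol, atol=atol,
        )
    else:
        raise ValueError(
            f"input {input_id!r} is neither a rate constant nor a species"
        )
    return traj.get(output_id)


def local_sensitivity(
    model: OdeModel,
    parameters: dict[str, float],
    input_id: str,
    output_id: str,
    times: np.ndarray,
    rel_step: float = 1e-3,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    zero_tol: float = 1e-12,
) -> np.ndarray:
    """Time series of the normalized local sensitivity S_ij(t).

    Central differences: both perturbed runs use the same relative step
    ``rel_step`` up and down.  Where the unperturbed output is (numerically)
    zero the normalized sensitivity is defined as 0.
    """
    times = np.asarray(times, float)
    base = simulate(model, parameters, grid=times, rtol=rtol, atol=atol)
    y0 = base.get(output_id)
    y_hi = _perturbed_output(model, parameters, input_id, 1.0 + rel_step,
                             output_id, times, rtol, atol)
    y_lo = _perturbed_output(model, parameters, input_id, 1.0 - rel_step,
                             output_id, times, rtol, atol)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (y_hi - y_lo) / (2.0 * rel_step * y0)
    s[np.abs(y0) <= zero_tol] = 0.0
    return s


def integrated_sensitivity(s: np.ndarray, times: np.ndarray, signed: bool = False) -> float:
    """Trapezoidal time integral of S(t), normalized by the window length.

    ``signed=False`` integrates |S(t)| (magnitude index); ``signed=True``
    integrates S(t) itself, preserving the direction of the effect.
    """
    times = np.asarray(times, float)
    s = np.asarray(s, float)
    span = times[-1] - times[0]
    integrand = s if signed else np.abs(s)
    return float(np.trapezoid(integrand, times) / span)


@dataclass
class SensitivityResult:
    """Signed integrated-sensitivity samples per (input, output) pair.

    ``samples[(input, output)]`` is the array of signed integrated
    sensitivities across the sampled parameter vectors; the global index is
    the mean of their absolute values.
    """

    inputs: list[str]
    outputs: list[str]
    samples: dict[tuple[str, str], np.ndarray]
    n_requested: int
    n_failed: int = 0
    scheme: str = "log-uniform"
    seed: int | None = None

    @property
    def global_index(self) -> dict[tuple[str, str], float]:
        return {key: float(np.mean(np.abs(v))) for key, v in self.samples.items()}

    def index_series(self, output: str | None = None) -> pd.Series:
        output = output or self.outputs[0]
        return pd.Series(
            {inp: self.global_index[(inp, output)] for inp in self.inputs},
            name="global_index",
        )

    def signed_summary(self) -> pd.DataFrame:
        """Box-plot-ready quartiles/whiskers of the signed samples."""
        rows = []
        for (inp, out), vals in self.samples.items():
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append(
                {"input": inp, "output": out, "min": vals.min(), "q1": q1,
                 "median": med, "q3": q3, "max": vals.max(),
                 "frac_negative": float(np.mean(vals < 0)),
                 "frac_positive": float(np.mean(vals > 0))}
            )
        return pd.DataFrame(rows)

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for (inp, out), vals in self.samples.items():
            for i, v in enumerate(vals):
                rows.append(
                    {"input": inp, "output": out, "sample_index": i,
                     "signed_value": v, "unsigned_value": abs(v)}
                )
        return pd.DataFrame(rows)


def global_average_sensitivity(
    model: OdeModel,
    space: ParameterSpace,
    inputs: list[str],
    output: str,
    times: np.ndarray,
    n_samples: int,
    seed: int | None = None,
    *,
    rel_step: float = 1e-3,
    scheme: str = "log-uniform",
    max_failed_fraction: float = 0.5,
) -> SensitivityResult:
    """Averaged-local-sensitivity global index over parameter uncertainty.

    Draws ``n_samples`` free-parameter vectors from ``space`` and, at each,
    computes the signed time-integrated local sensitivity of ``output`` with
    respect to every input.  Samples whose simulations fail are excluded
    and counted; the analysis aborts if more than ``max_failed_fraction``
    of them fail.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    times = np.asarray(times, float)
    draws = space.sample(n_samples, scheme=scheme, seed=seed)
    collected: dict[tuple[str, str], list[float]] = {
        (inp, output): [] for inp in inputs
    }
    n_failed = 0
    for row in draws:
        params = space.full_dict(row)
        try:
            per_input = {}
            for inp in inputs:
                s = local_sensitivity(model, params, inp, output, times,
                                      rel_step=rel_step)
                per_input[inp] = integrated_sensitivity(s, times, signed=True)
        except (SimulationError, FloatingPointError):
            n_failed += 1
            continue
        for inp, val in per_input.items():
            collected[(inp, output)].append(val)
    if n_failed > max_failed_fraction * n_samples:
        raise SensitivityAbort(
            f"{n_failed}/{n_samples} sampled parameter sets failed to simulate"
        )
    if n_failed:
        logger.warning("excluded %d/%d failed samples", n_failed, n_samples)
    return SensitivityResult(
        inputs=list(inputs),
        outputs=[output],
        samples={key: np.array(vals) for key, vals in collected.items()},
        n_requested=n_samples,
        n_failed=n_failed,
        scheme=scheme,
        seed=seed,
    )


def qualitative_report(
    result: SensitivityResult,
    expectations: dict[str, str],
    *,
    insensitive_fraction: float = 0.05,
    straddle_tolerance: float = 0.05,
) -> pd.DataFrame:
    """Check signed sensitivity distributions against expected signs.

    ``expectations`` maps input ids to ``"positive"``, ``"negative"`` or
    ``"insensitive"``.  Per input: PASS when the median sign matches (or,
    for "insensitive", when the global index is below
    ``insensitive_fraction`` of the largest index); FLAG when the sign is
    right but more than ``straddle_tolerance`` of the samples sit on the
    wrong side of zero; FAIL otherwise.  Machine-readable: one row per
    expectation with a ``status`` column.
    """
    unknown = set(expectations) - set(result.inputs)
    if unknown:
        raise ValueError(f"expectations reference unknown inputs: {sorted(unknown)}")
    output = result.outputs[0]
    indices = result.index_series(output)
    max_index = float(indices.max()) if len(indices) else 0.0
    rows = []
    for inp, expected in expectations.items():
        vals = result.samples[(inp, output)]
        median = float(np.median(vals))
        index = indices[inp]
        frac_neg = float(np.mean(vals < 0))
        frac_pos = float(np.mean(vals > 0))
        if expected == "insensitive":
            status = "PASS" if index <= insensitive_fraction * max_index else "FAIL"
            straddle = 0.0
        elif expected in ("positive", "negative"):
            straddle = frac_neg if expected == "positive" else frac_pos
            sign_ok = (median > 0) if expected == "positive" else (median < 0)
            if not sign_ok:
                status = "FAIL"
            elif straddle > straddle_tolerance:
                status = "FLAG"
            else:
                status = "PASS"
        else:
            raise ValueError(f"unknown expectation {expected!r} for {inp!r}")
        rows.append(
            {"input": inp, "expectation": expected, "median": median,
             "global_index": index, "straddle_fraction": straddle,
             "status": status}
        )
    return pd.DataFrame(rows)
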