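"""Parameter spaces with tiered multiplicative bounds and log-space sampling.

Each rate constant gets a nominal value ``p*`` and a bound tier: ``wide``
(p*/100, 100 p*) for poorly known constants, ``medium`` (p*/10, 10 p*) for
constants with some prior support, ``narrow`` (p*/2, 2 p*) for well
constrained ones, or explicit bounds.  All sampling and gridding is
uniform in log10 space, matching the multiplicative structure of the
bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

__all__ = ["TIER_FACTORS", "ParameterSpec", "ParameterSpace", "GridSizeError"]

TIER_FACTORS = {"wide": 100.0, "medium": 10.0, "narrow": 2.0}


class GridSizeError(ValueError):
    """Requested full-factorial grid exceeds the configured cap."""


@dataclass(frozen=True)
class ParameterSpec:
    """Nominal value with multiplicative bounds for one rate constant."""

    id: str
    nominal: float
    tier: str | None = "wide"
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self):
        if self.nominal <= 0:
            raise ValueError(f"{self.id}: nominal must be positive")
        if self.lower is None or self.upper is None:
            tier = self.tier if self.tier is not None else "wide"
            if tier not in TIER_FACTORS:
                raise ValueError(
                    f"{self.id}: unknown tier {tier!r} "
                    f"(choose from {sorted(TIER_FACTORS)}) or give explicit bounds"
                )
            factor = TIER_FACTORS[tier]
            object.__setattr__(self, "tier", tier)
            object.__setattr__(self, "lower", self.nominal / factor)
            object.__setattr__(self, "upper", self.nominal * factor)
        else:
            object.__setattr__(self, "tier", None)
        if not (0 < self.lower <= self.nominal <= self.upper):
            raise ValueError(
                f"{self.id}: need 0 < lower <= nominal <= upper, got "
                f"({self.lower}, {self.nominal}, {self.upper})"
            )

    @property
    def log_bounds(self) -> tuple[float, float]:
        return (np.log10(self.lower), np.log10(self.upper))


class ParameterSpace:
    """Ordered parameter specs with a designated free subset.

    Sampling, gridding and optimization act on the free parameters only;
    pinned parameters stay at their nominal value (``full_dict`` reassembles
    a complete parameter map from a free vector).
    """

    def __init__(self, specs: Iterable[ParameterSpec], free_ids: Sequence[str] | None = None):
        self.specs: dict[str, ParameterSpec] = {}
        for spec in specs:
            if spec.id in self.specs:
                raise ValueError(f"duplicate parameter id {spec.id!r}")
            self.specs[spec.id] = spec
        if free_ids is None:
            free_ids = list(self.specs)
        unknown = [fid for fid in free_ids if fid not in self.specs]
        if unknown:
            raise ValueError(f"free_ids not in space: {unknown}")
        self.free_ids: list[str] = list(free_ids)

    # -- basic structure --------------------------------------------------
    def __len__(self) -> int:
        return len(self.specs)

    @property
    def dim(self) -> int:
        """Number of free parameters."""
        return len(self.free_ids)

    def with_free(self, free_ids: Sequence[str]) -> "ParameterSpace":
        return ParameterSpace(self.specs.values(), free_ids)

    def nominal_free(self) -> np.ndarray:
        return np.array([self.specs[fid].nominal for fid in self.free_ids])

    def log_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.specs[fid].log_bounds[0] for fid in self.free_ids])
        hi = np.array([self.specs[fid].log_bounds[1] for fid in self.free_ids])
        return lo, hi

    def contains(self, values: np.ndarray) -> bool:
        values = np.atleast_2d(values)
        lo, hi = self.log_bounds()
        logv = np.log10(values)
        return bool(np.all(logv >= lo - 1e-12) and np.all(logv <= hi + 1e-12))

    def full_dict(self, free_values: Sequence[float]) -> dict[str, float]:
        """Complete parameter map: free values merged over pinned nominals."""
        free_values = np.asarray(free_values, float)
        if free_values.shape != (self.dim,):
            raise ValueError(
                f"expected {self.dim} free values, got shape {free_values.shape}"
            )
        out = {pid: spec.nominal for pid, spec in self.specs.items()}
        out.update(dict(zip(self.free_ids, free_values)))
        return out

    # -- sampling ----------------------------------------------------------
    def sample(self, n: int, scheme: str = "log-uniform", seed: int | None = None) -> np.ndarray:
        """Draw ``n`` free-parameter vectors, uniform in log10 space.

        ``scheme`` is ``"log-uniform"`` (i.i.d.) or ``"latin-hypercube"``
        (one sample per equal-log-width stratum per dimension).  Identical
        seeds give identical samples.
        """
        if self.dim == 0:
            raise ValueError("no free parameters to sample")
        if n < 1:
            raise ValueError("n must be >= 1")
        lo, hi = self.log_bounds()
        if scheme == "log-uniform":
            rng = np.random.default_rng(seed)
            u = rng.random((n, self.dim))
        elif scheme == "latin-hypercube":
            u = qmc.LatinHypercube(d=self.dim, seed=seed).random(n)
        else:
            raise ValueError(f"unknown sampling scheme {scheme!r}")
        return 10 ** (lo + u * (hi - lo))

    def grid(self, levels: int = 3, cap: int = 100_000) -> np.ndarray:
        """Full-factorial grid over the free parameters, log-uniform levels.

        With ``levels=3`` each parameter takes its lower bound, the
        geometric midpoint ``sqrt(lower*upper)`` and its upper bound.  Rows
        are ordered row-major over the parameter order (first parameter
        varies slowest).  Refuses (with the would-be count) above ``cap``.
        """
        if levels < 2:
            raise ValueError("levels must be >= 2")
        if self.dim == 0:
            raise ValueError("no free parameters to grid")
        total = levels**self.dim
        if total > cap:
            raise GridSizeError(
                f"grid would contain {total} points (> cap {cap}); "
                "consider latin-hypercube sampling instead"
            )
        lo, hi = self.log_bounds()
        axes = [np.linspace(lo[j], hi[j], levels) for j in range(self.dim)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return 10 ** np.column_stack([m.ravel() for m in mesh])

    # -- file round-trip ---------------------------------------------------
    def to_file(self, path) -> None:
        rows = []
        for pid, spec in self.specs.items():
            tb = spec.tier if spec.tier else f"{spec.lower:.17g}:{spec.upper:.17g}"
            rows.append(
                {"id": pid, "nominal": spec.nominal, "tier_or_bounds": tb,
                 "free": pid in self.free_ids}
            )
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_file(cls, path) -> "ParameterSpace":
        frame = pd.read_csv(path)
        specs, free = [], []
        for row in frame.itertuples(index=False):
            tb = str(row.tier_or_bounds)
            if tb in TIER_FACTORS:
                specs.append(ParameterSpec(row.id, float(row.nominal), tier=tb))
            else:
                lower, upper = (float(x) for x in tb.split(":"))
                specs.append(
                    ParameterSpec(row.id, float(row.nominal), tier=None,
                                  lower=lower, upper=upper)
                )
            if bool(row.free):
                free.append(row.id)
        return cls(specs, free)

    @classmethod
    def from_model(cls, model, tier: str = "wide",
                   tiers: Mapping[str, str] | None = None,
                   free_ids: Sequence[str] | None = None) -> "ParameterSpace":
        """Space with one spec per model rate constant at its nominal value."""
        tiers = tiers or {}
        specs = [
            ParameterSpec(pid, value, tier=tiers.get(pid, tier))
            for pid, value in model.parameters.items()
        ]
        return cls(specs, free_ids)
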