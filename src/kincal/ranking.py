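"""Ranking parameters by sensitivity magnitude and cutting at the L-curve elbow.

Ranked sensitivity spectra of signaling models are typically L-shaped: a
few dominant parameters followed by a long flat tail.  The cutoff between
"dominant" and "negligible" is found where the curve (rank, log10
magnitude) is farthest from the chord joining its first and last points —
a deterministic stand-in for the visual border between the vertical and
horizontal arms.  Manual override is first-class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["RankedParameters", "rank", "elbow_cutoff", "compare_rankings"]


@dataclass
class RankedParameters:
    index_name: str
    order: list[str]
    values: np.ndarray
    cutoff: int | None = None
    cutoff_method: str | None = None
    low_confidence: bool = False

    @property
    def dominant(self) -> list[str]:
        if self.cutoff is None:
            raise ValueError("no cutoff set; call elbow_cutoff or set manually")
        return self.order[: self.cutoff]

    def top(self, k: int) -> list[str]:
        return self.order[:k]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"rank": np.arange(1, len(self.order) + 1),
             "parameter": self.order, "magnitude": self.values}
        )
        if self.cutoff is not None:
            frame["dominant"] = frame["rank"] <= self.cutoff
        return frame


def rank(values: Mapping[str, float], index_name: str = "index") -> RankedParameters:
    """Sort parameters by descending |sensitivity|; ties broken by id.

    All-zero inputs produce a valid (if uninformative) ranking with a
    warning.
    """
    items = [(pid, abs(float(v))) for pid, v in values.items() if np.isfinite(v)]
    if not items:
        raise ValueError("need at least one finite sensitivity value")
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    order = [pid for pid, _ in items]
    mags = np.array([v for _, v in items])
    if np.all(mags == 0):
        warnings.warn("all sensitivities are zero; ranking is arbitrary",
                      stacklevel=2)
    return RankedParameters(index_name=index_name, order=order, values=mags)


def elbow_cutoff(ranked: RankedParameters, override: int | None = None) -> RankedParameters:
    """Select the dominant-parameter count at the L-curve elbow.

    The elbow is the rank position maximizing the perpendicular distance
    from (rank, log10 magnitude) to the chord between the first and last
    nonzero-magnitude points; ties go to the smaller rank.  Zero
    magnitudes are unrankable on a log scale and are excluded from the
    chord.  When the spectrum is (near) log-linear there is no elbow; the
    midpoint is returned and flagged low-confidence.  Never returns 0.
    """
    if override is not None:
        if not 1 <= override <= len(ranked.order):
            raise ValueError(f"override {override} outside [1, {len(ranked.order)}]")
        return replace(ranked, cutoff=int(override), cutoff_method="manual",
                       low_confidence=False)
    nonzero = ranked.values > 0
    m = int(nonzero.sum())
    if len(ranked.order) < 3 or m < 3:
        warnings.warn("fewer than 3 usable parameters; cutoff set to all",
                      stacklevel=2)
        return replace(ranked, cutoff=max(1, len(ranked.order)),
                       cutoff_method="all (too few parameters)",
                       low_confidence=True)
    x = np.arange(1, m + 1, dtype=float)
    y = np.log10(ranked.values[:m])
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    chord = np.hypot(dx, dy)
    # perpendicular distance of each point to the first-last chord
    dist = np.abs(dx * (y - y[0]) - dy * (x - x[0])) / chord
    if dist.max() <= 1e-9 * max(chord, 1.0):
        cutoff = (m + 1) // 2
        return replace(ranked, cutoff=cutoff,
                       cutoff_method="chord (no elbow: midpoint)",
                       low_confidence=True)
    # ties (within float noise) go to the smaller rank
    near_max = dist >= dist.max() * (1.0 - 1e-9)
    cutoff = int(np.nonzero(near_max)[0][0]) + 1
    return replace(ranked, cutoff=cutoff, cutoff_method="chord",
                   low_confidence=False)


def compare_rankings(rankings: Sequence[RankedParameters], k: int) -> pd.DataFrame:
    """Top-k membership comparison across sensitivity indices.

    Returns one row per parameter appearing in any top-k set, with a
    boolean column per index and a membership count (parameters selected
    by all indices are the consensus dominant set).
    """
    universe = set(rankings[0].order)
    for r in rankings[1:]:
        if set(r.order) != universe:
            raise ValueError("rankings cover different parameter sets")
    tops = {r.index_name: set(r.top(k)) for r in rankings}
    members = sorted(set().union(*tops.values()))
    rows = []
    for pid in members:
        flags = {name: pid in sel for name, sel in tops.items()}
        rows.append({"parameter": pid, **flags,
                     "n_indices": sum(flags.values())})
    frame = pd.DataFrame(rows).sort_values(
        ["n_indices", "parameter"], ascending=[False, True]
    ).reset_index(drop=True)
    return frame
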