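"""Water-uptake phase segmentation of a fresh-weight imbibition series.

Germination stages 2 (rapid water uptake) and 3 (slow uptake) are delimited
by the change-points of the triphasic fresh-weight curve. The fitter finds
the continuous piecewise-linear least-squares fit with breakpoints restricted
to the observed time grid, by exhaustive search over breakpoint combinations.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .synthetic import FreshWeightSeries


@dataclass(frozen=True)
class PhaseFit:
    """Continuous piecewise-linear fit of a weight-vs-time series."""

    breakpoints: tuple[float, ...]
    slopes: tuple[float, ...]
    intercept: float
    rss: float

    def __post_init__(self) -> None:
        if len(self.slopes) != len(self.breakpoints) + 1:
            raise ValueError("need exactly one more slope than breakpoints")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")

    def predict(self, t: np.ndarray) -> np.ndarray:
        basis = _hinge_basis(np.asarray(t, dtype=float), np.array(self.breakpoints))
        coef = np.concatenate(
            ([self.intercept, self.slopes[0]], np.diff(self.slopes))
        )
        return basis @ coef

    def to_json(self) -> str:
        return json.dumps(
            {
                "breakpoints": list(self.breakpoints),
                "slopes": list(self.slopes),
                "intercept": self.intercept,
                "rss": self.rss,
            }
        )


def _hinge_basis(t: np.ndarray, breakpoints: np.ndarray) -> np.ndarray:
    """Design matrix [1, t, (t-b1)+, (t-b2)+, ...] of a continuous spline."""
    cols = [np.ones_like(t), t]
    for b in breakpoints:
        cols.append(np.maximum(t - b, 0.0))
    return np.column_stack(cols)


def _fit_given_breaks(
    t: np.ndarray, w: np.ndarray, breaks: np.ndarray
) -> tuple[float, np.ndarray]:
    basis = _hinge_basis(t, breaks)
    coef, _, _, _ = np.linalg.lstsq(basis, w, rcond=None)
    resid = w - basis @ coef
    return float(resid @ resid), coef

def fit_phase_breakpoints(series: FreshWeightSeries, n_segments: int = 3) -> PhaseFit:
    """Globally optimal grid-restricted segmentation into ``n_segments`` phases.

    Every combination of ``n_segments - 1`` interior grid times is fitted by
    linear least squares with continuity enforced at the breakpoints (shared
    hinge basis); the combination with smallest residual sum of squares wins.
    Ties resolve to the earliest combination in lexicographic grid order, so
    the fit is deterministic. O(n^2) fits for the default three segments.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    t = np.asarray(series.time, dtype=float)
    w = np.asarray(series.weight, dtype=float)
    n = len(t)
    if n < 3 * n_segments:
        raise ValueError(f"need at least {3 * n_segments} points for {n_segments} segments")

    n_breaks = n_segments - 1
    if n_breaks == 0:
        rss, coef = _fit_given_breaks(t, w, np.empty(0))
        return PhaseFit((), (float(coef[1]),), float(coef[0]), rss)

    # interior candidates: keep >= 2 points per outer segment so every
    # segment's slope is identified
    candidates = t[2:-2]
    best: tuple[float, tuple[float, ...], np.ndarray] | None = None
    for combo in itertools.combinations(candidates, n_breaks):
        breaks = np.array(combo)
        # require >= 2 observations strictly inside each middle segment
        counts = np.histogram(t, bins=np.concatenate(([t[0]], breaks, [t[-1]])))[0]
        if np.any(counts < 2):
            continue
        rss, coef = _fit_given_breaks(t, w, breaks)
        if best is None or rss < best[0] - 1e-12:
            best = (rss, combo, coef)
    assert best is not None
    rss, combo, coef = best
    slopes = tuple(np.cumsum(coef[1:]).tolist())
    return PhaseFit(tuple(float(b) for b in combo), slopes, float(coef[0]), rss)


def read_series(path: str | Path) -> FreshWeightSeries:
    """Read a two-column time_min/weight_g table (TSV or CSV)."""
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    return FreshWeightSeries(
        time=df["time_min"].to_numpy(float), weight=df["weight_g"].to_numpy(float)
    )
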