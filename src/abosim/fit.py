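"""Least-squares comparison of observed and simulated allele frequencies.

The fit statistic is deliberately plain: for an observed regional average
``(p, q, r)`` and a simulated mean triple, the discrepancy is the sum of
squared differences over the three alleles.  A selection regime's absolute
fit is obtained by letting each region pick its best-fitting pool size
(minimum discrepancy over the ``ne`` rows of that regime) and summing those
minima across regions; lower is better.  Regimes with stronger selection
fit O-rich regions far better, because only they produce small-``ne`` cells
with a nearly fixed O allele.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence, Union

import pandas as pd

from .core import AlleleFreqs
from .engine import GridSummary
from .exceptions import InsufficientDataError

__all__ = ["least_squares_ss", "regime_fit", "fit_table"]

GridLike = Union[Sequence[GridSummary], pd.DataFrame]


def least_squares_ss(observed: Iterable[float], expected: Iterable[float]) -> float:
    """Sum of squared allele-frequency differences, ``sum (obs - exp)^2``."""
    o = AlleleFreqs.of(observed).validate(tol=1e-6)
    e = AlleleFreqs.of(expected).validate(tol=1e-6)
    return (o.p - e.p) ** 2 + (o.q - e.q) ** 2 + (o.r - e.r) ** 2


def _grid_rows(grid: GridLike) -> list[tuple[float, AlleleFreqs]]:
    if isinstance(grid, pd.DataFrame):
        return [
            (float(row.z), AlleleFreqs(float(row.mean_p), float(row.mean_q), float(row.mean_r)))
            for row in grid.itertuples()
        ]
    return [(s.z, AlleleFreqs(s.mean_p, s.mean_q, s.mean_r)) for s in grid]


def regime_fit(
    observed_by_region: Sequence[tuple[str, Iterable[float]]],
    grid: GridLike,
    z: float,
) -> float:
    """Absolute fit of one selection regime to regional observed averages.

    For each region, computes :func:`least_squares_ss` against the simulated
    mean frequencies at every pool size available for the requested ``z``
    and keeps the minimum; returns the sum of these best fits over regions.
    Invariant to the ordering of regions and of grid rows.
    """
    if not observed_by_region:
        raise InsufficientDataError("no observed regional averages supplied")
    rows = [a for (gz, a) in _grid_rows(grid) if math.isclose(gz, float(z), abs_tol=1e-9)]
    if not rows:
        raise InsufficientDataError(f"grid contains no rows for z={z}")
    total = 0.0
    for _region, observed in observed_by_region:
        total += min(least_squares_ss(observed, mean) for mean in rows)
    return total


def fit_table(
    observed_by_region: Sequence[tuple[str, Iterable[float]]],
    grid: GridLike,
) -> pd.DataFrame:
    """Two-column table ``(z, fit)``, one row per regime, strongest first."""
    zs = sorted({gz for gz, _ in _grid_rows(grid)}, reverse=True)
    return pd.DataFrame(
        {"z": zs, "fit": [regime_fit(observed_by_region, grid, z) for z in zs]}
    )
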