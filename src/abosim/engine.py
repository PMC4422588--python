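"""Replicate runner and experiment grid.

Each replicate iterates ``select -> drift`` for a fixed number of
generations from a common starting point and is classified by its final
state: how many alleles were lost, which allele (if any) reached fixation,
and the expected heterozygosity that remains.  A grid run repeats this for
every combination of selection strength ``z`` and pool size ``ne`` and
aggregates the replicates into one summary row per cell, in the layout of
the study's headline table (mean final frequencies, loss proportions,
O-fixation fraction, heterozygosity mean and variance).

Two loss statistics are reported per cell, because they answer different
questions:

* ``prop_any_loss`` -- the proportion of replicates ending with at least
  one allele absent;
* ``prop_lost_1`` -- the allele-loss index: total allele-loss events across
  replicates divided by the maximum possible (two per replicate), i.e.
  ``(n_{>=1 lost} + n_{2 lost}) / (2 * replicates)``.  This is the
  "losing 1 allele" convention of the reference summary table and always
  lies between ``prop_lost_2`` and ``prop_any_loss``.

Seeding: every replicate owns an independent stream derived from the master
seed and the cell coordinates ``(z, ne, replicate)``, so a single cell
re-run in isolation reproduces exactly the replicates it had inside a full
grid run.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import AlleleFreqs, _step
from .exceptions import SchemaError

__all__ = [
    "DEFAULT_Z_VALUES",
    "DEFAULT_NE_VALUES",
    "DEFAULT_INITIAL",
    "SimulationConfig",
    "ReplicateOutcome",
    "GridSummary",
    "expected_heterozygosity",
    "replicate_rng",
    "run_replicate",
    "run_cell",
    "run_grid",
    "grid_to_dataframe",
    "outcomes_to_dataframe",
    "write_grid",
    "read_grid",
]

logger = logging.getLogger(__name__)

#: Selection strengths of the reference experiment, strongest first.
DEFAULT_Z_VALUES: tuple[float, ...] = (1.0, 0.75, 0.5, 0.25, 0.0)
#: Pool sizes (gene copies per generation) of the reference experiment.
DEFAULT_NE_VALUES: tuple[int, ...] = (1000, 500, 250, 100, 50, 25, 10)
#: Rounded interior equilibrium, the standard starting state.
DEFAULT_INITIAL = AlleleFreqs(0.19, 0.19, 0.62)

#: Exact column order of the grid summary table.
GRID_COLUMNS = [
    "z",
    "Ne",
    "mean_p",
    "mean_q",
    "mean_r",
    "prop_lost_1",
    "prop_lost_2",
    "frac_fix_O",
    "he_mean",
    "he_var",
    "replicates",
    "generations",
    "seed",
    "prop_any_loss",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Experiment grid definition.

    ``ne_values`` are gamete-pool sizes (gene copies per generation; see
    :mod:`abosim.drift`).  Defaults reproduce the reference protocol:
    100 generations, 1000 replicates per cell, start at (0.19, 0.19, 0.62).
    """

    z_values: tuple[float, ...] = DEFAULT_Z_VALUES
    ne_values: tuple[int, ...] = DEFAULT_NE_VALUES
    generations: int = 100
    replicates: int = 1000
    initial: AlleleFreqs = DEFAULT_INITIAL
    master_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "z_values", tuple(float(z) for z in self.z_values))
        object.__setattr__(self, "ne_values", tuple(int(n) for n in self.ne_values))
        object.__setattr__(self, "initial", AlleleFreqs.of(self.initial).validate())
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for z in self.z_values:
            if not 0.0 <= z <= 1.0:
                raise ValueError(f"z={z} outside [0, 1]")
        for ne in self.ne_values:
            if ne < 1:
                raise ValueError(f"ne={ne} must be >= 1")


@dataclass(frozen=True)
class ReplicateOutcome:
    """Final state of one simulated population."""

    final: AlleleFreqs
    n_alleles_lost: int
    fixed_allele: str  # "A", "B", "O" or "none"
    he_final: float
    generation_of_first_loss: Optional[int]


@dataclass(frozen=True)
class GridSummary:
    """Aggregate of one (z, ne) cell over independent replicates.

    ``frac_fix_o`` is ``None`` when no replicate reached fixation (the
    denominator is the set of fixation events).  ``he_var`` uses the
    unbiased (n-1) estimator and is NaN for a single replicate.
    """

    z: float
    ne: int
    mean_p: float
    mean_q: float
    mean_r: float
    prop_lost_1: float
    prop_lost_2: float
    prop_any_loss: float
    frac_fix_o: Optional[float]
    he_mean: float
    he_var: float
    replicates: int
    generations: int


def expected_heterozygosity(alleles: Iterable[float]) -> float:
    """Expected heterozygosity ``He = 1 - (p^2 + q^2 + r^2)``.

    The probability that two random gametes carry different alleles; ranges
    from 0 (monomorphic) to 2/3 (all three alleles equally common).
    """
    a = AlleleFreqs.of(alleles).validate()
    return 1.0 - (a.p * a.p + a.q * a.q + a.r * a.r)


def replicate_rng(master_seed: int, z: float, ne: int, replicate: int) -> np.random.Generator:
    """Independent, reproducible random stream for one replicate.

    The spawn key encodes the cell coordinates, so streams do not depend on
    where the cell sits inside a grid.
    """
    key = (int(round(float(z) * 10_000)), int(ne), int(replicate))
    return np.random.default_rng(np.random.SeedSequence(int(master_seed), spawn_key=key))


def run_replicate(
    z: float,
    ne: int,
    rng: np.random.Generator,
    *,
    generations: int = 100,
    initial: Iterable[float] = DEFAULT_INITIAL,
) -> ReplicateOutcome:
    """Simulate one population forward and classify its final state.

    Each generation applies the deterministic NFDS step (identity at
    ``z = 0``) and then multinomial sampling of ``ne`` gene copies.  An
    allele is lost iff its frequency is exactly zero; monomorphic states are
    absorbing, so remaining generations are skipped once one allele is left.
    """
    a = AlleleFreqs.of(initial).validate()
    ne = int(ne)
    if ne < 1:
        raise ValueError("ne must be >= 1")
    z = float(z)
    p, q, r = a
    present = (p > 0.0) + (q > 0.0) + (r > 0.0)
    first_loss: Optional[int] = None
    for gen in range(1, generations + 1):
        if present <= 1:
            break
        if z != 0.0:
            p, q, r = _step(p, q, r, z)
        c = rng.multinomial(ne, (p, q, 1.0 - p - q if p + q < 1.0 else 0.0))
        p = int(c[0]) / ne
        q = int(c[1]) / ne
        r = int(c[2]) / ne
        now = (p > 0.0) + (q > 0.0) + (r > 0.0)
        if now < present and first_loss is None:
            first_loss = gen
        present = now
    n_lost = (p == 0.0) + (q == 0.0) + (r == 0.0)
    if n_lost == 2:
        fixed = "A" if p > 0.0 else ("B" if q > 0.0 else "O")
    else:
        fixed = "none"
    he = 1.0 - (p * p + q * q + r * r)
    return ReplicateOutcome(AlleleFreqs(p, q, r), n_lost, fixed, he, first_loss)


def summarize_outcomes(
    outcomes: Sequence[ReplicateOutcome], z: float, ne: int, generations: int
) -> GridSummary:
    """Aggregate replicate outcomes into one grid row."""
    n = len(outcomes)
    if n == 0:
        raise ValueError("no outcomes to summarize")
    finals = np.array([o.final for o in outcomes], dtype=float)
    n_ge1 = sum(1 for o in outcomes if o.n_alleles_lost >= 1)
    n_two = sum(1 for o in outcomes if o.n_alleles_lost == 2)
    n_fix_o = sum(1 for o in outcomes if o.fixed_allele == "O")
    he = np.array([o.he_final for o in outcomes], dtype=float)
    return GridSummary(
        z=float(z),
        ne=int(ne),
        mean_p=float(finals[:, 0].mean()),
        mean_q=float(finals[:, 1].mean()),
        mean_r=float(finals[:, 2].mean()),
        prop_lost_1=(n_ge1 + n_two) / (2.0 * n),
        prop_lost_2=n_two / n,
        prop_any_loss=n_ge1 / n,
        frac_fix_o=(n_fix_o / n_two) if n_two > 0 else None,
        he_mean=float(he.mean()),
        he_var=float(he.var(ddof=1)) if n > 1 else float("nan"),
        replicates=n,
        generations=int(generations),
    )


def run_cell(
    z: float,
    ne: int,
    config: SimulationConfig,
    *,
    collect_outcomes: bool = False,
) -> GridSummary | tuple[GridSummary, list[ReplicateOutcome]]:
    """Run all replicates of one (z, ne) cell and summarize them."""
    t0 = time.perf_counter()
    outcomes = [
        run_replicate(
            z,
            ne,
            replicate_rng(config.master_seed, z, ne, rep),
            generations=config.generations,
            initial=config.initial,
        )
        for rep in range(config.replicates)
    ]
    summary = summarize_outcomes(outcomes, z, ne, config.generations)
    logger.info(
        "cell z=%.2f ne=%d: lost1=%.3f lost2=%.3f he=%.3f (%.2fs)",
        summary.z,
        summary.ne,
        summary.prop_lost_1,
        summary.prop_lost_2,
        summary.he_mean,
        time.perf_counter() - t0,
    )
    if collect_outcomes:
        return summary, outcomes
    return summary


def run_grid(config: SimulationConfig) -> list[GridSummary]:
    """One :class:`GridSummary` per (z, ne) pair, deterministic in the seed."""
    return [run_cell(z, ne, config) for z in config.z_values for ne in config.ne_values]


def grid_to_dataframe(summaries: Sequence[GridSummary], master_seed: int) -> pd.DataFrame:
    """Grid summaries as a table with the fixed :data:`GRID_COLUMNS` layout."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "z": s.z,
                "Ne": s.ne,
                "mean_p": s.mean_p,
                "mean_q": s.mean_q,
                "mean_r": s.mean_r,
                "prop_lost_1": s.prop_lost_1,
                "prop_lost_2": s.prop_lost_2,
                "frac_fix_O": s.frac_fix_o,
                "he_mean": s.he_mean,
                "he_var": s.he_var,
                "replicates": s.replicates,
                "generations": s.generations,
                "seed": int(master_seed),
                "prop_any_loss": s.prop_any_loss,
            }
        )
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def outcomes_to_dataframe(
    per_cell: dict[tuple[float, int], Sequence[ReplicateOutcome]]
) -> pd.DataFrame:
    """Per-replicate dump for downstream plotting."""
    rows = []
    for (z, ne), outcomes in per_cell.items():
        for rep, o in enumerate(outcomes):
            rows.append(
                {
                    "z": z,
                    "Ne": ne,
                    "replicate": rep,
                    "p": o.final.p,
                    "q": o.final.q,
                    "r": o.final.r,
                    "n_alleles_lost": o.n_alleles_lost,
                    "fixed_allele": o.fixed_allele,
                    "he_final": o.he_final,
                    "generation_of_first_loss": o.generation_of_first_loss,
                }
            )
    return pd.DataFrame(rows)


def write_grid(
    summaries: Sequence[GridSummary],
    csv_path,
    json_path=None,
    *,
    master_seed: int,
) -> pd.DataFrame:
    """Write the grid table as CSV (and optionally a JSON mirror).

    ``frac_fix_O`` is left empty in the CSV and ``null`` in the JSON when no
    fixation occurred in a cell.
    """
    df = grid_to_dataframe(summaries, master_seed)
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        records = df.to_dict(orient="records")
        for rec in records:
            for k, v in rec.items():
                if isinstance(v, float) and math.isnan(v):
                    rec[k] = None
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump({"seed": int(master_seed), "rows": records}, fh, indent=1)
    return df


def read_grid(path) -> pd.DataFrame:
    """Read a grid summary table written by :func:`write_grid`."""
    df = pd.read_csv(path)
    missing = {"z", "mean_p", "mean_q", "mean_r"} - set(df.columns)
    if missing:
        raise SchemaError(f"grid table {path} is missing columns: {sorted(missing)}")
    return df
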