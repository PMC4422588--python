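"""Wright-Fisher gamete sampling.

The drift step treats post-selection allele frequencies as expected gamete
frequencies and draws the next generation as one multinomial sample of a
finite gamete pool.  Throughout the package ``ne`` counts **gene copies**
(gametes) sampled per generation: the experiment grids index drift strength
directly by this pool size, and a diploid census of ``N`` individuals
corresponds to ``ne = 2N``.  Sampling gametes one by one with replacement
is distributionally identical to the single multinomial draw used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np

from .core import AlleleFreqs
from .exceptions import InvalidFrequencyError

__all__ = ["DriftParameters", "drift_sample"]

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator, None]


@dataclass
class DriftParameters:
    """Drift configuration: pool size and a reproducible random stream.

    ``ne`` is the number of gene copies sampled each generation (must be
    >= 1).  ``seed`` may be an integer, a :class:`numpy.random.SeedSequence`,
    an existing :class:`numpy.random.Generator`, or ``None`` for fresh OS
    entropy; identical seed and parameters give bit-identical output.
    """

    ne: int
    seed: SeedLike = None
    _rng: Optional[np.random.Generator] = field(
        default=None, init=False, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.ne = int(self.ne)
        if self.ne < 1:
            raise ValueError(f"ne must be >= 1, got {self.ne}")

    @property
    def rng(self) -> np.random.Generator:
        if self._rng is None:
            if isinstance(self.seed, np.random.Generator):
                self._rng = self.seed
            else:
                self._rng = np.random.default_rng(self.seed)
        return self._rng


def drift_sample(expected: Iterable[float], params: DriftParameters) -> AlleleFreqs:
    """Realized next-generation allele frequencies in a finite pool.

    Draws counts ``(n_A, n_B, n_O)`` from a three-category multinomial with
    ``params.ne`` trials and the expected frequencies as probabilities, and
    returns the counts divided by the pool size.  Output components are
    exact multiples of ``1/ne``; an expected frequency of zero yields an
    output of zero with probability one (lost alleles stay lost).
    """
    a = AlleleFreqs.of(expected).validate()
    counts = params.rng.multinomial(params.ne, _pvals(a))
    ne = params.ne
    return AlleleFreqs(int(counts[0]) / ne, int(counts[1]) / ne, int(counts[2]) / ne)


def _pvals(a: AlleleFreqs) -> tuple[float, float, float]:
    # Guard against float drift so the trailing probability is never negative.
    r = 1.0 - a.p - a.q
    if r < 0.0:
        if r < -1e-9:
            raise InvalidFrequencyError(f"p + q = {a.p + a.q!r} exceeds 1")
        r = 0.0
    return (a.p, a.q, r)
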