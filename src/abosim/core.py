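"""Deterministic machinery of asymmetric negative frequency-dependent
selection (NFDS) at a tri-allelic ABO-like locus.

The model tracks the frequencies ``(p, q, r)`` of the A, B and O alleles.
Random mating turns them into Hardy-Weinberg zygote frequencies, and each
genotype's fitness declines with the summed frequency of genotypes that
express the same antigen phenotype: pathogens adapted to a phenotype in the
previous generation infect carriers of that phenotype more easily, so a
common phenotype is a liability.  Because A and B are dominant over O, the
AA/AO and BB/BO genotype pairs each form one phenotype class and share one
fitness, the co-dominant AB phenotype overlaps both classes, and OO is
penalised only by its own frequency.  This asymmetry gives the recessive O
allele a systematic edge, sustaining the familiar O-rich interior
equilibrium near (0.19, 0.19, 0.62).

The selection strength ``z`` in [0, 1] scales every frequency-dependent
penalty; ``z = 0`` is strict neutrality.  ``z`` cancels from the condition
that marginal allele fitnesses be equal, so the interior equilibrium is the
same for every ``z > 0`` -- only the speed of approach changes.

There is no mutation: a lost allele stays lost, and monomorphic states are
absorbing.
"""

from __future__ import annotations

import math
from typing import Iterable, NamedTuple

from .exceptions import (
    ConvergenceError,
    DegeneratePopulationError,
    InvalidFrequencyError,
)

__all__ = [
    "AlleleFreqs",
    "GenotypeFreqs",
    "GenotypeFitnesses",
    "SIMPLEX_TOL",
    "hw_genotype_frequencies",
    "genotype_fitnesses",
    "select",
    "deterministic_equilibrium",
    "selection_coefficient",
]

#: Tolerance for "sums to one" checks on frequency vectors.
SIMPLEX_TOL = 1e-9


class AlleleFreqs(NamedTuple):
    """Allele-frequency triple for the A, B and O alleles.

    Components must be non-negative and sum to one within :data:`SIMPLEX_TOL`.
    The same type is used before and after selection.
    """

    p: float
    q: float
    r: float

    @classmethod
    def of(cls, values: Iterable[float]) -> "AlleleFreqs":
        vals = tuple(float(v) for v in values)
        if len(vals) != 3:
            raise InvalidFrequencyError(
                f"expected three allele frequencies, got {len(vals)}"
            )
        return cls(*vals)

    def validate(self, tol: float = SIMPLEX_TOL) -> "AlleleFreqs":
        """Return ``self`` if it lies on the frequency simplex, else raise."""
        for name, v in zip("pqr", self):
            if not (0.0 <= v <= 1.0) or math.isnan(v):
                raise InvalidFrequencyError(f"{name}={v!r} is outside [0, 1]")
        if abs(sum(self) - 1.0) > tol:
            raise InvalidFrequencyError(
                f"allele frequencies sum to {sum(self)!r}, not 1"
            )
        return self

    def normalized(self) -> "AlleleFreqs":
        s = sum(self)
        if s <= 0.0:
            raise InvalidFrequencyError("cannot normalize a zero vector")
        return AlleleFreqs(self.p / s, self.q / s, self.r / s)

    @property
    def n_present(self) -> int:
        """Number of alleles currently segregating (frequency > 0)."""
        return int(self.p > 0.0) + int(self.q > 0.0) + int(self.r > 0.0)


class GenotypeFreqs(NamedTuple):
    """Zygote frequencies of the six ordered-pair genotypes."""

    f_AA: float
    f_AO: float
    f_BB: float
    f_BO: float
    f_AB: float
    f_OO: float


class GenotypeFitnesses(NamedTuple):
    """Absolute genotype fitnesses under NFDS plus the population mean.

    All six fitnesses lie in ``[1 - z, 1]`` because each penalty is ``z``
    times a sum of genotype frequencies, which is at most one.
    """

    w_AA: float
    w_AO: float
    w_BB: float
    w_BO: float
    w_AB: float
    w_OO: float
    w_bar: float


def _check_z(z: float) -> float:
    z = float(z)
    if not (0.0 <= z <= 1.0) or math.isnan(z):
        raise InvalidFrequencyError(f"selection strength z={z!r} must be in [0, 1]")
    return z


def hw_genotype_frequencies(
    alleles: Iterable[float], *, validate: bool = True
) -> GenotypeFreqs:
    """Hardy-Weinberg zygote frequencies from an allele-frequency triple.

    Returns ``(p^2, 2pr, q^2, 2qr, 2pq, r^2)`` in the field order
    ``(f_AA, f_AO, f_BB, f_BO, f_AB, f_OO)``.
    """
    a = AlleleFreqs.of(alleles)
    if validate:
        a.validate()
    p, q, r = a
    return GenotypeFreqs(p * p, 2 * p * r, q * q, 2 * q * r, 2 * p * q, r * r)


def genotype_fitnesses(genotypes: GenotypeFreqs, z: float) -> GenotypeFitnesses:
    """Frequency-dependent fitness of each genotype.

    A genotype's fitness is one minus ``z`` times the summed frequency of
    genotypes sharing its antigen phenotype:

    * ``w_AA = w_AO = 1 - z (f_AA + f_AO)`` (the A phenotype class),
    * ``w_BB = w_BO = 1 - z (f_BB + f_BO)`` (the B phenotype class),
    * ``w_AB = 1 - z (f_AB + f_AA + f_BB + f_AO + f_BO)`` (AB overlaps both),
    * ``w_OO = 1 - z f_OO``.

    ``w_bar`` is the genotype-frequency-weighted mean fitness.
    """
    z = _check_z(z)
    f_AA, f_AO, f_BB, f_BO, f_AB, f_OO = genotypes
    w_A = 1.0 - z * (f_AA + f_AO)
    w_B = 1.0 - z * (f_BB + f_BO)
    w_AB = 1.0 - z * (f_AB + f_AA + f_BB + f_AO + f_BO)
    w_O = 1.0 - z * f_OO
    w_bar = (f_AA + f_AO) * w_A + (f_BB + f_BO) * w_B + f_AB * w_AB + f_OO * w_O
    return GenotypeFitnesses(w_A, w_A, w_B, w_B, w_AB, w_O, w_bar)


def _step(p: float, q: float, r: float, z: float) -> tuple[float, float, float]:
    # Hot path shared by select() and the replicate loop: one deterministic
    # generation of random mating + NFDS, renormalised onto the simplex.
    f_AA = p * p
    f_AO = 2.0 * p * r
    f_BB = q * q
    f_BO = 2.0 * q * r
    f_AB = 2.0 * p * q
    f_OO = r * r
    w_A = 1.0 - z * (f_AA + f_AO)
    w_B = 1.0 - z * (f_BB + f_BO)
    w_AB = 1.0 - z * (f_AB + f_AA + f_BB + f_AO + f_BO)
    w_O = 1.0 - z * f_OO
    w_bar = (f_AA + f_AO) * w_A + (f_BB + f_BO) * w_B + f_AB * w_AB + f_OO * w_O
    if w_bar <= 0.0:
        raise DegeneratePopulationError(
            f"mean fitness {w_bar!r} at (p={p}, q={q}, r={r}, z={z})"
        )
    pn = p * (p * w_A + q * w_AB + r * w_A)
    qn = q * (q * w_B + p * w_AB + r * w_B)
    rn = r * (r * w_O + p * w_A + q * w_B)
    s = pn + qn + rn
    return pn / s, qn / s, rn / s


def select(alleles: Iterable[float], z: float, *, validate: bool = True) -> AlleleFreqs:
    """One generation of selection: post-selection allele frequencies.

    Zygotes are formed in Hardy-Weinberg proportions from the input
    frequencies, weighted by their NFDS fitnesses, and the resulting gamete
    frequencies are renormalised.  Neutrality (``z = 0``) is the identity
    map, monomorphic states are absorbing, and an allele at frequency zero
    stays at zero (no mutation).
    """
    a = AlleleFreqs.of(alleles)
    if validate:
        a.validate()
        _check_z(z)
    if z == 0.0 or a.n_present <= 1:
        return a
    return AlleleFreqs(*_step(a.p, a.q, a.r, z))


def deterministic_equilibrium(
    z: float,
    start: Iterable[float] = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0),
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> AlleleFreqs:
    """Interior fixed point of the selection recursion for ``z > 0``.

    Iterates :func:`select` from ``start`` until the maximum per-component
    change drops below ``tol``.  From any interior start the iteration
    converges to the O-rich equilibrium, which is identical for every
    ``z > 0`` (``z`` cancels from the marginal-fitness equality) and rounds
    to ``(0.19, 0.19, 0.62)`` at two decimals.

    Raises :class:`ConvergenceError` (with the last iterate attached) if
    ``max_iter`` is exhausted.
    """
    z = _check_z(z)
    if z == 0.0:
        raise InvalidFrequencyError("equilibrium is undefined at z=0 (neutrality)")
    a = AlleleFreqs.of(start).validate()
    if a.n_present < 3:
        raise InvalidFrequencyError("start must be an interior point (all alleles present)")
    p, q, r = a
    for _ in range(max_iter):
        pn, qn, rn = _step(p, q, r, z)
        if max(abs(pn - p), abs(qn - q), abs(rn - r)) < tol:
            return AlleleFreqs(pn, qn, rn)
        p, q, r = pn, qn, rn
    raise ConvergenceError(
        f"no fixed point within {max_iter} iterations (z={z}, tol={tol})",
        last_iterate=AlleleFreqs(p, q, r),
    )


def selection_coefficient(z: float, generations: int = 100) -> float:
    """Classical selection coefficient implied by a given ``z``.

    ``z`` is a tuning dial, not a selection coefficient.  To express the
    model on the familiar scale, the deterministic model is held at its
    interior equilibrium and ``|w_OO - w_AA|`` is recorded each generation;
    the average over ``generations`` generations is returned.  The statistic
    is exactly linear in ``z`` because the equilibrium does not move with
    ``z``; at ``z = 1`` it is about 0.1, i.e. roughly one tenth of ``z``.
    """
    z = _check_z(z)
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if z == 0.0:
        return 0.0
    state = deterministic_equilibrium(z, tol=1e-13)
    total = 0.0
    for _ in range(generations):
        w = genotype_fitnesses(hw_genotype_frequencies(state, validate=False), z)
        total += abs(w.w_OO - w.w_AA)
        state = select(state, z, validate=False)
    return total / generations
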