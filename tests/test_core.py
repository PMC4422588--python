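"""Deterministic selection machinery: Hardy-Weinberg zygotes, NFDS
fitnesses, the post-selection recursion, equilibrium and the implied
selection coefficient."""

import math
from fractions import Fraction

import pytest
from hypothesis import given

from abosim import (
    AlleleFreqs,
    ConvergenceError,
    InvalidFrequencyError,
    deterministic_equilibrium,
    genotype_fitnesses,
    hw_genotype_frequencies,
    select,
    selection_coefficient,
)
from strategies import allele_triples, boundary_triples, selection_strengths


def select_oracle(p, q, r, z):
    """Transcription of the model's printed recursions in exact rational
    arithmetic: genotype frequencies, phenotype-class fitnesses, mean
    fitness, and the three post-selection allele frequencies divided by
    the mean fitness.  Independent of the package's float implementation."""
    p, q, r, z = Fraction(p), Fraction(q), Fraction(r), Fraction(z)
    f_AA, f_AO, f_BB, f_BO, f_AB, f_OO = p * p, 2 * p * r, q * q, 2 * q * r, 2 * p * q, r * r
    w_AA = 1 - z * f_AA - z * f_AO
    w_BB = 1 - z * f_BB - z * f_BO
    w_BO = w_BB
    w_AB = 1 - z * f_AB - z * f_AA - z * f_BB - z * f_AO - z * f_BO
    w_OO = 1 - z * f_OO
    w_AO = w_AA
    w_bar = (
        f_AA * w_AA + f_AO * w_AO + f_BB * w_BB + f_BO * w_BO + f_AB * w_AB + f_OO * w_OO
    )
    pn = (p * p * w_AA + p * q * w_AB + p * r * w_AO) / w_bar
    qn = (q * q * w_BB + p * q * w_AB + q * r * w_BO) / w_bar
    rn = (r * r * w_OO + p * r * w_AO + q * r * w_BO) / w_bar
    assert pn + qn + rn == 1  # the recursion conserves probability exactly
    return (pn, qn, rn)


class TestHardyWeinberg:
    @pytest.mark.parametrize(
        "alleles, expected",
        [
            ((0.0, 0.0, 1.0), (0.0, 0.0, 0.0, 0.0, 0.0, 1.0)),
            ((0.5, 0.5, 0.0), (0.25, 0.0, 0.25, 0.0, 0.5, 0.0)),
            ((0.19, 0.19, 0.62), (0.0361, 0.2356, 0.0361, 0.2356, 0.0722, 0.3844)),
        ],
    )
    def test_zygote_frequencies(self, alleles, expected):
        got = hw_genotype_frequencies(alleles)
        assert got == pytest.approx(expected, abs=1e-15)

    @given(allele_triples())
    def test_zygotes_sum_to_one(self, alleles):
        assert sum(hw_genotype_frequencies(alleles)) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("bad", [(0.5, 0.5, 0.5), (-0.1, 0.5, 0.6), (0.2, 0.2, 0.2)])
    def test_invalid_input_rejected(self, bad):
        with pytest.raises(InvalidFrequencyError):
            hw_genotype_frequencies(bad)


class TestGenotypeFitnesses:
    def test_neutrality_gives_unit_fitness(self):
        w = genotype_fitnesses(hw_genotype_frequencies((0.3, 0.3, 0.4)), 0.0)
        assert all(v == 1.0 for v in w[:6])
        assert w.w_bar == pytest.approx(1.0, abs=1e-12)

    def test_equilibrium_start_strong_selection(self):
        w = genotype_fitnesses(hw_genotype_frequencies((0.19, 0.19, 0.62)), 1.0)
        assert w.w_AA == pytest.approx(1 - 0.0361 - 0.2356, abs=1e-12)
        assert w.w_AO == w.w_AA
        assert w.w_AB == pytest.approx(0.3844, abs=1e-12)
        assert w.w_OO == pytest.approx(0.6156, abs=1e-12)

    def test_monomorphic_o_has_zero_fitness_at_full_strength(self):
        w = genotype_fitnesses(hw_genotype_frequencies((0.0, 0.0, 1.0)), 1.0)
        assert w.w_OO == 0.0
        assert w.w_bar == 0.0

    @given(boundary_triples(), selection_strengths)
    def test_bounds_and_mean(self, alleles, z):
        g = hw_genotype_frequencies(alleles)
        w = genotype_fitnesses(g, z)
        for v in w[:6]:
            assert 1.0 - z - 1e-12 <= v <= 1.0 + 1e-12
        weighted = sum(fg * wg for fg, wg in zip(g, w[:6]))
        assert w.w_bar == pytest.approx(weighted, abs=1e-12)


class TestSelect:
    def test_exact_step_from_uniform_start(self):
        # Oracle value frozen from exact rational evaluation of the
        # recursions at (1/3, 1/3, 1/3), z = 1/2.
        assert select_oracle(Fraction(1, 3), Fraction(1, 3), Fraction(1, 3), Fraction(1, 2)) == (
            Fraction(40, 127),
            Fraction(40, 127),
            Fraction(47, 127),
        )
        got = select((1 / 3, 1 / 3, 1 / 3), 0.5)
        assert got == pytest.approx((40 / 127, 40 / 127, 47 / 127), abs=1e-14)
        assert got.r > 1 / 3  # O gains ground from a symmetric start

    @pytest.mark.parametrize(
        "alleles, z",
        [
            ((0.19, 0.19, 0.62), 1.0),
            ((0.7, 0.1, 0.2), 0.25),
            ((0.05, 0.6, 0.35), 0.75),
        ],
    )
    def test_matches_rational_oracle(self, alleles, z):
        exact = select_oracle(*(Fraction(a).limit_denominator(10**6) for a in alleles), z)
        got = select(alleles, z)
        for g, e in zip(got, exact):
            assert g == pytest.approx(float(e), abs=1e-12)

    @given(boundary_triples())
    def test_neutrality_is_identity(self, alleles):
        assert select(alleles, 0.0) == alleles

    @given(selection_strengths)
    def test_monomorphic_states_absorb(self, z):
        for mono in [(1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)]:
            assert select(mono, z) == mono

    @given(boundary_triples(), selection_strengths)
    def test_probability_conserved(self, alleles, z):
        out = select(alleles, z)
        assert sum(out) == pytest.approx(1.0, abs=1e-12)
        assert all(v >= 0.0 for v in out)

    @given(allele_triples(), selection_strengths)
    def test_ab_symmetry(self, alleles, z):
        sym = AlleleFreqs(alleles.p, alleles.p, 1.0 - 2 * alleles.p)
        if sym.r < 0:
            return
        out = select(sym, z)
        assert out.p == out.q

    @given(boundary_triples(), selection_strengths)
    def test_lost_alleles_stay_lost(self, alleles, z):
        edge = AlleleFreqs(alleles.p, 0.0, alleles.q + alleles.r).normalized()
        out = select(edge, z)
        assert out.q == 0.0


class TestEquilibrium:
    def test_interior_fixed_point_rounds_to_reference(self):
        eq = deterministic_equilibrium(0.5)
        assert (round(eq.p, 2), round(eq.q, 2), round(eq.r, 2)) == (0.19, 0.19, 0.62)
        assert eq.r > eq.p and eq.r > eq.q  # recessive-O advantage

    @pytest.mark.parametrize("z", [0.1, 0.25, 0.75, 1.0])
    def test_fixed_point_is_z_invariant(self, z):
        ref = deterministic_equilibrium(0.5, tol=1e-12)
        eq = deterministic_equilibrium(z, tol=1e-12)
        assert eq == pytest.approx(ref, abs=1e-8)

    @pytest.mark.parametrize("start", [(0.6, 0.2, 0.2), (0.1, 0.2, 0.7), (0.02, 0.9, 0.08)])
    def test_start_independence(self, start):
        ref = deterministic_equilibrium(1.0)
        assert deterministic_equilibrium(1.0, start=start) == pytest.approx(ref, abs=1e-8)

    def test_near_fixed_point_start_stays_put(self):
        eq = deterministic_equilibrium(0.5, tol=1e-12)
        refined = deterministic_equilibrium(0.5, start=eq, tol=1e-10)
        assert refined == pytest.approx(eq, abs=1e-9)

    def test_nonconvergence_carries_last_iterate(self):
        with pytest.raises(ConvergenceError) as err:
            deterministic_equilibrium(0.01, tol=1e-15, max_iter=3)
        last = err.value.last_iterate
        assert last is not None and sum(last) == pytest.approx(1.0, abs=1e-12)

    def test_neutral_equilibrium_rejected(self):
        with pytest.raises(InvalidFrequencyError):
            deterministic_equilibrium(0.0)


class TestSelectionCoefficient:
    def test_neutral_is_zero(self):
        assert selection_coefficient(0.0) == 0.0

    def test_full_strength_is_about_one_tenth(self):
        assert round(selection_coefficient(1.0, generations=100), 1) == 0.1

    def test_linear_in_z(self):
        s_full = selection_coefficient(1.0)
        assert 2 * selection_coefficient(0.5) == pytest.approx(s_full, abs=1e-10)
        assert 4 * selection_coefficient(0.25) == pytest.approx(s_full, abs=1e-10)

    def test_constant_along_the_equilibrium_trajectory(self):
        # Held at the fixed point, the per-generation statistic is static,
        # so the average cannot depend on the horizon.
        assert selection_coefficient(0.75, generations=1) == pytest.approx(
            selection_coefficient(0.75, generations=50), abs=1e-12
        )


def test_step_sanity_against_math():
    # w_bar > 0 guaranteed for interior points even at z = 1.
    out = select((0.01, 0.01, 0.98), 1.0)
    assert math.isfinite(sum(out))
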