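"""Hardy-Weinberg chi-square test, exact variant, and the exclusion rule."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

import urateburden as ub
from urateburden.hwe import hwe_matrix

import published


def brute_force_hwe(n_aa, n_ab, n_bb):
    """Independent recomputation: expectations from scratch, then the chi2 CDF."""
    n = n_aa + n_ab + n_bb
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1 - p
    expected = [n * p * p, 2 * n * p * q, n * q * q]
    chi = 0.0
    for obs, exp in zip((n_aa, n_ab, n_bb), expected):
        if exp > 0:
            chi += (obs - exp) ** 2 / exp
    return chi, stats.chi2.sf(chi, 1)


def test_expected_counts_example():
    g = ub.GenotypeCounts("rs1183201", "Filipino", 7, 59, 109)
    expected = ub.hwe_expected_counts(g)
    assert expected == pytest.approx((7.61, 57.78, 109.61), abs=0.01)
    assert sum(expected) == pytest.approx(g.n_total, abs=1e-9)


def test_perfect_hwe_counts_give_zero_statistic():
    result = ub.hwe_chi_square_test(ub.GenotypeCounts("rs1", "P", 25, 50, 25))
    assert result.chi_square == 0.0
    assert result.p_value == 1.0
    assert (result.expected_aa, result.expected_ab, result.expected_bb) == (25, 50, 25)


def test_monomorphic_convention():
    result = ub.hwe_chi_square_test(ub.GenotypeCounts("rs734553", "Marshallese", 0, 0, 121))
    assert result.monomorphic
    assert result.chi_square == 0.0
    assert result.p_value == 1.0
    assert (result.expected_aa, result.expected_ab, result.expected_bb) == (0, 0, 121)


def test_empty_counts_rejected():
    with pytest.raises(ub.DegenerateInputError):
        ub.hwe_chi_square_test(ub.GenotypeCounts("rs1", "P", 0, 0, 0))


def test_published_hwe_parity(counts_by):
    """All published HWE p-values reproduce at the printed 4-decimal precision.

    The source software truncates to 4 decimals, so the check is
    floor(p * 1e4) / 1e4 == printed.  The one monomorphic cell is excluded:
    a fixed allele cannot deviate from equilibrium, so the printed 0.0000
    there is a software artifact and this package reports p = 1.
    """
    for rs_id, row in published.HWE_P_VALUES.items():
        for population, printed in row.items():
            result = ub.hwe_chi_square_test(counts_by[(rs_id, population)])
            if (rs_id, population) in published.HWE_MONOMORPHIC_CELLS:
                assert result.monomorphic and result.p_value == 1.0
                continue
            truncated = math.floor(result.p_value * 1e4) / 1e4
            assert truncated == pytest.approx(printed, abs=1e-9), (rs_id, population)


def test_chi_square_matches_brute_force_oracle():
    rng = np.random.default_rng(3)
    for _ in range(200):
        counts = rng.integers(0, 167, size=3)
        if counts.sum() == 0:
            continue
        g = ub.GenotypeCounts("rs1", "P", *map(int, counts))
        if g.is_monomorphic:
            continue
        chi, p = brute_force_hwe(*map(int, counts))
        result = ub.hwe_chi_square_test(g)
        assert result.chi_square == pytest.approx(chi, abs=1e-10)
        assert result.p_value == pytest.approx(p, abs=1e-10)


def test_p_value_decreases_with_statistic():
    results = []
    for n_ab in (50, 40, 30, 20, 10):
        n_het_deficit = (100 - n_ab) // 2
        g = ub.GenotypeCounts("rs1", "P", 25 + n_het_deficit, n_ab, 25 + n_het_deficit)
        results.append(ub.hwe_chi_square_test(g))
    chis = [r.chi_square for r in results]
    ps = [r.p_value for r in results]
    assert chis == sorted(chis)
    assert ps == sorted(ps, reverse=True)


def exact_hwe_by_pairing(n_aa, n_ab, n_bb):
    """Oracle: enumerate every ordered pairing of the 2n allele copies.

    Each permutation of the allele multiset, read off as consecutive pairs,
    is an equally likely outcome of random mating conditional on the allele
    counts; the p-value sums the probability of heterozygote counts no more
    probable than the observed one.
    """
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    alleles = "a" * n_a + "b" * n_b
    tallies: dict[int, int] = {}
    total = 0
    for perm in set(itertools.permutations(alleles)):
        # distinct arrangements are equiprobable for an exchangeable multiset
        hets = sum(perm[i] != perm[i + 1] for i in range(0, len(perm), 2))
        tallies[hets] = tallies.get(hets, 0) + 1
        total += 1
    probs = {h: c / total for h, c in tallies.items()}
    observed = probs[n_ab]
    return sum(p for p in probs.values() if p <= observed + 1e-12)


@pytest.mark.parametrize("genotypes", [(2, 1, 1), (1, 2, 1), (0, 4, 0), (3, 0, 1)])
def test_exact_test_matches_pairing_enumeration(genotypes):
    g = ub.GenotypeCounts("rs1", "P", *genotypes)
    result = ub.hwe_exact_test(g)
    assert result.p_value == pytest.approx(exact_hwe_by_pairing(*genotypes), abs=1e-12)


def test_exact_test_monomorphic_convention():
    result = ub.hwe_exact_test(ub.GenotypeCounts("rs1", "P", 0, 0, 7))
    assert result.monomorphic and result.p_value == 1.0


# ---------------------------------------------------------------------------
# calibration under simulation

def _rejection_rate(inbreeding, n=500, replicates=500, freq=0.3, alpha=0.05, seed=5):
    rng = np.random.default_rng(seed)
    p, q, f = freq, 1 - freq, inbreeding
    probs = [p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q]
    draws = rng.multinomial(n, probs, size=replicates)
    rejections = 0
    for n_aa, n_ab, n_bb in draws:
        result = ub.hwe_chi_square_test(
            ub.GenotypeCounts("rs1", "P", int(n_aa), int(n_ab), int(n_bb)))
        rejections += result.p_value < alpha
    return rejections / replicates


def test_type_i_error_near_nominal_alpha():
    replicates = 2000
    rate = _rejection_rate(0.0, replicates=replicates)
    low = stats.binom.ppf(0.005, replicates, 0.05) / replicates
    high = stats.binom.ppf(0.995, replicates, 0.05) / replicates
    assert low <= rate <= high


def test_power_increases_with_inbreeding():
    assert _rejection_rate(0.3) > _rejection_rate(0.0)


# ---------------------------------------------------------------------------
# exclusion rule

def _results(rs_id, p_values):
    return [
        ub.HweResult(rs_id, pop, 1.0, 1, p, 1.0, 1.0, 1.0, False)
        for pop, p in p_values.items()
    ]


def test_exclude_only_when_deviant_everywhere():
    everywhere = {p: 0.0001 for p in "ABCDEF"}
    decision = ub.hwe_exclusion_filter(_results("rs12129861", everywhere))
    assert decision.exclude
    assert all(decision.deviant.values())


def test_single_deviation_keeps_locus():
    p_values = {"Filipino": 0.4439, "Japanese": 0.9076, "Samoan": 0.4465,
                "Marshallese": 0.0109, "Native Hawaiian": 0.3224, "Korean": 0.9926}
    decision = ub.hwe_exclusion_filter(_results("rs17300741", p_values), threshold=0.006)
    assert not decision.exclude
    assert not any(decision.deviant.values())


def test_single_population_keep():
    decision = ub.hwe_exclusion_filter(_results("rs1", {"P": 0.5}))
    assert not decision.exclude


def test_exclusion_rejects_empty_and_mixed_input():
    with pytest.raises(ub.ValidationError):
        ub.hwe_exclusion_filter([])
    mixed = _results("rs1", {"P": 0.5}) + _results("rs2", {"P": 0.5})
    with pytest.raises(ub.ValidationError):
        ub.hwe_exclusion_filter(mixed)


def test_hwe_matrix_shape(cohort_counts):
    results = [ub.hwe_chi_square_test(g) for g in cohort_counts]
    matrix = hwe_matrix(results)
    assert matrix.shape == (9, 6)
    assert ((matrix >= 0) & (matrix <= 1)).all().all()
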