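"""Frequencies, confidence intervals, function-class aggregates and the
Hardy-Weinberg chi-square, cross-checked against independent oracles."""

from __future__ import annotations

import math
from fractions import Fraction

import pytest
from hypothesis import given, strategies as st

from cyp2d6pop import (
    Cohort,
    allele_frequency_table,
    chi_square_upper_tail,
    count_genotypes,
    count_haplotypes,
    expected_genotype_counts,
    function_class_frequencies,
    hwe_chi_square,
    load_allele_definitions,
    predicted_pm_fraction,
)
from cyp2d6pop.popgen import round_half_away

from conftest import TABLE1


def test_count_haplotypes_reproduces_published_counts(cohort):
    counts = count_haplotypes(cohort)
    assert sum(counts.values()) == 2 * cohort.n_subjects == 422
    for label, (count, *_rest) in TABLE1.items():
        assert counts[label] == count, label
    # tandem arrangements are atomic units, never split into components
    assert "*36" not in counts
    assert counts["*36+*10"] == 51


def test_count_haplotypes_single_subject():
    c = Cohort.from_labels([("s1", "*1/*1")])
    assert count_haplotypes(c) == {"*1": 2}


def test_frequency_table_matches_published_cis(cohort):
    recs = {r.haplotype_label: r for r in allele_frequency_table(count_haplotypes(cohort), z=2.0)}
    r41 = recs["*41"]
    assert (round_half_away(100 * r41.frequency), round_half_away(100 * r41.ci_low),
            round_half_away(100 * r41.ci_high)) == (3.55, 1.75, 5.36)
    r5 = recs["*5"]
    assert (round_half_away(100 * r5.ci_low), round_half_away(100 * r5.ci_high)) == (0.42, 2.90)
    # singleton allele: lower bound truncated at 0
    r1x2 = recs["*1x2"]
    assert r1x2.ci_low == 0.0
    assert round_half_away(100 * r1x2.ci_high) == 0.71


def test_frequency_table_degenerate_single_label():
    (rec,) = allele_frequency_table({"*1": 10}, z=2.0)
    assert rec.frequency == rec.ci_low == rec.ci_high == 1.0


def test_frequency_table_rejects_empty():
    with pytest.raises(ValueError):
        allele_frequency_table({})


@given(
    st.dictionaries(
        st.sampled_from(["*1", "*2", "*4", "*10", "*17", "*36+*10"]),
        st.integers(0, 50),
        min_size=1,
    ).filter(lambda d: sum(d.values()) > 0)
)
def test_frequency_table_invariants(counts):
    recs = allele_frequency_table(counts, z=1.96)
    assert sum(r.count for r in recs) == sum(counts.values())
    assert math.isclose(sum(r.frequency for r in recs), 1.0, abs_tol=1e-12)
    for r in recs:
        assert 0.0 <= r.ci_low <= r.frequency <= r.ci_high <= 1.0


def test_expected_counts_against_direct_arithmetic():
    freqs = {"*1": 151 / 422, "*10": 72 / 422, "other": 1 - 151 / 422 - 72 / 422}
    exp = expected_genotype_counts(freqs, 211, ["*1/*1", "*1/*10"])
    assert exp["*1/*1"] == pytest.approx((151 / 422) ** 2 * 211)
    assert exp["*1/*1"] == pytest.approx(27.015, abs=1e-3)
    assert exp["*1/*10"] == pytest.approx(2 * (151 / 422) * (72 / 422) * 211)


def test_expected_counts_edge_cases():
    exp = expected_genotype_counts({"A": 0.5, "B": 0.5}, 100, ["A/B"])
    assert exp["A/B"] == pytest.approx(50.0)
    exp = expected_genotype_counts({"A": 1.0, "B": 0.0}, 10, ["A/B", "B/B"])
    assert exp["A/B"] == 0.0 and exp["B/B"] == 0.0
    with pytest.raises(KeyError):
        expected_genotype_counts({"A": 1.0}, 10, ["A/C"])
    with pytest.raises(ValueError):
        expected_genotype_counts({"A": 0.6}, 10, ["A/A"])


@given(
    st.lists(st.sampled_from(["*1", "*4", "*10", "*17", "*36+*10"]), min_size=2, max_size=40),
)
def test_expected_counts_over_all_genotypes_sum_to_n(units):
    """Over every possible genotype, HWE expectations total exactly N."""
    if len(units) % 2:
        units = units[:-1]
    n_subjects = len(units) // 2
    total = len(units)
    labels = sorted(set(units))
    freqs = {lab: units.count(lab) / total for lab in labels}
    all_genotypes = [
        f"{labels[i]}/{labels[j]}" for i in range(len(labels)) for j in range(i, len(labels))
    ]
    exp = expected_genotype_counts(freqs, n_subjects, all_genotypes)
    assert math.isclose(sum(exp.values()), n_subjects, abs_tol=1e-9)


def _brute_force_chi2(cohort: Cohort) -> Fraction:
    """Exact-rational (O-E)^2/E over observed genotypes, from first principles."""
    unit_counts: dict[str, int] = {}
    for _, d in cohort.subjects:
        for h in d.haplotypes():
            unit_counts[h.label] = unit_counts.get(h.label, 0) + 1
    total = sum(unit_counts.values())
    n = cohort.n_subjects
    obs = count_genotypes(cohort)
    chi2 = Fraction(0)
    for label, o in obs.items():
        a, b = label.split("/")
        pa = Fraction(unit_counts[a], total)
        pb = Fraction(unit_counts[b], total)
        e = pa * pb * n if a == b else 2 * pa * pb * n
        chi2 += (o - e) ** 2 / e
    return chi2


def test_hwe_chi_square_matches_exact_rational_oracle():
    labels = ["*1/*1"] * 4 + ["*1/*4"] * 3 + ["*4/*4"] * 2 + ["*1/*10"] * 2 + ["*10/*17"]
    cohort = Cohort.from_labels([(f"s{i}", lab) for i, lab in enumerate(labels)])
    counts = count_haplotypes(cohort)
    total = sum(counts.values())
    freqs = {lab: c / total for lab, c in counts.items()}
    obs = count_genotypes(cohort)
    exp = expected_genotype_counts(freqs, cohort.n_subjects, list(obs))
    res = hwe_chi_square(obs, exp, num_alleles=len(counts), df_rule="conventional")
    assert res.cumulative_chi2 == pytest.approx(float(_brute_force_chi2(cohort)), abs=1e-12)
    assert res.cumulative_chi2 == pytest.approx(sum(r[3] for r in res.rows))


def test_hwe_chi_square_null_and_single_cases():
    res = hwe_chi_square({"A/A": 25, "A/B": 50, "B/B": 25},
                         {"A/A": 25.0, "A/B": 50.0, "B/B": 25.0},
                         num_alleles=2, df_rule="conventional")
    assert res.cumulative_chi2 == 0.0
    assert res.p_value == 1.0
    assert res.flagged_genotypes() == ()

    res = hwe_chi_square({"A/A": 10, "A/B": 1}, {"A/A": 5.0, "A/B": 1.0},
                         num_alleles=2, df_rule="conventional")
    # single-genotype contribution (10-5)^2/5 = 5.0 exceeds the 3.841 flag threshold
    assert dict((r[0], r[3]) for r in res.rows)["A/A"] == pytest.approx(5.0)
    assert res.flagged_genotypes() == ("A/A",)


def test_hwe_chi_square_error_cases():
    with pytest.raises(ValueError):
        hwe_chi_square({"A/A": 1}, {"B/B": 1.0}, num_alleles=1)
    with pytest.raises(ValueError):
        hwe_chi_square({"A/A": 1}, {"A/A": 0.0}, num_alleles=1, df_rule="conventional")
    with pytest.raises(ValueError):
        hwe_chi_square({"A/A": 1, "A/B": 1}, {"A/A": 1.0, "A/B": 1.0},
                       num_alleles=2, df_rule="bogus")


def _gammq(a: float, x: float) -> float:
    """Regularized upper incomplete gamma Q(a, x) via series / continued
    fraction (independent of scipy); chi-square sf(x, df) = Q(df/2, x/2)."""
    if x < a + 1.0:
        # series for P(a, x), then Q = 1 - P
        ap, summ, delta = a, 1.0 / a, 1.0 / a
        for _ in range(500):
            ap += 1.0
            delta *= x / ap
            summ += delta
            if abs(delta) < abs(summ) * 1e-16:
                break
        p = summ * math.exp(-x + a * math.log(x) - math.lgamma(a)) if x > 0 else 0.0
        return 1.0 - p
    # Lentz continued fraction for Q(a, x)
    tiny = 1e-300
    b, c, d = x + 1.0 - a, 1.0 / tiny, 1.0 / (x + 1.0 - a)
    h = d
    for i in range(1, 500):
        an = -i * (i - a)
        b += 2.0
        d = an * d + b
        d = tiny if abs(d) < tiny else d
        c = b + an / c
        c = tiny if abs(c) < tiny else c
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < 1e-16:
            break
    return h * math.exp(-x + a * math.log(x) - math.lgamma(a))


@pytest.mark.parametrize("df", [1, 2, 3, 5, 10, 23, 50])
@pytest.mark.parametrize("x", [0.0, 0.5, 1.0, 3.841, 10.0, 30.0, 84.39])
def test_chi_square_upper_tail_vs_independent_evaluation(x, df):
    assert chi_square_upper_tail(x, df) == pytest.approx(_gammq(df / 2.0, x / 2.0), abs=1e-8)


def test_chi_square_upper_tail_reference_points():
    assert chi_square_upper_tail(0.0, 7) == 1.0
    assert chi_square_upper_tail(3.841, 1) == pytest.approx(0.05, abs=5e-4)
    assert chi_square_upper_tail(84.39, 23) < 1e-5
    with pytest.raises(ValueError):
        chi_square_upper_tail(1.0, 0)
    with pytest.raises(ValueError):
        chi_square_upper_tail(-1.0, 3)


def test_function_class_frequencies(cohort, defs):
    counts = count_haplotypes(cohort)
    classes = function_class_frequencies(counts, defs, reported_rounding=2)
    assert classes["none"].unit_count == 24
    assert classes["decreased"].rounded_sum_percent == pytest.approx(50.48)
    assert classes["decreased"].unit_count == 72 + 46 + 28 + 51 + 1 + 15

    all_normal = function_class_frequencies({"*1": 20}, load_allele_definitions())
    assert all_normal["normal"].raw_percent == 100.0
    assert set(all_normal) == {"normal"}


def test_predicted_pm_fraction(cohort, defs):
    counts = count_haplotypes(cohort)
    q = 24 / 422
    assert predicted_pm_fraction(counts, defs) == pytest.approx(q * q)
    assert round_half_away(100 * predicted_pm_fraction(counts, defs)) == 0.32
    assert predicted_pm_fraction({"*1": 5}, defs) == 0.0
    assert predicted_pm_fraction({"*4": 5}, defs) == 1.0


def test_cohort_rejects_duplicate_ids():
    with pytest.raises(ValueError):
        Cohort.from_labels([("s1", "*1/*1"), ("s1", "*1/*4")])
    with pytest.raises(ValueError):
        Cohort(())
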