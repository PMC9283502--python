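"""RAF arithmetic, exact association tests, odds ratios and pooling."""

from itertools import product
from math import exp, factorial, log

import numpy as np
import pytest
from scipy import stats as sps

from kdrmon.errors import DegenerateTableError, EmptySampleError, ValidationError
from kdrmon.stats import (
    AlleleCount,
    GenotypeCountTable,
    allele_or,
    fisher_exact_2xk,
    fit_allele_glm,
    genotype_shift,
    pooled_or,
    raf,
)
from tests.conftest import find_table


def margin_table(location, year, group, n, lf_counts, mi_counts=(0, 0, 0)):
    return GenotypeCountTable(
        location=location, year=year, group=group, n=n,
        margins={1014: lf_counts, 918: mi_counts},
    )


# ---------------------------------------------------------------------------
# RAF


@pytest.mark.parametrize(
    "counts, n, expected",
    [((51, 69, 0), 120, 28.8), ((14, 10, 86), 110, 82.7), ((0, 10, 0), 10, 50.0)],
)
def test_raf_examples(counts, n, expected):
    t = margin_table("x", 2019, "pre", n, counts, (n, 0, 0))
    assert round(raf(t, 1014), 1) == expected


def test_raf_empty_sample():
    t = margin_table("x", 2019, "pre", 0, (0, 0, 0), (0, 0, 0))
    with pytest.raises(EmptySampleError):
        raf(t, 1014)


def test_raf_invariant_to_nine_class_vs_margin_representation():
    counts = {"L/L:M/M": 3, "L/L:M/I": 2, "L/F:M/M": 4, "L/F:M/I": 1, "F/F:I/I": 2}
    nine = GenotypeCountTable("x", 2019, "pre", 12, counts=counts)
    margins = GenotypeCountTable(
        "x", 2019, "pre", 12,
        margins={1014: nine.locus_margin(1014), 918: nine.locus_margin(918)},
    )
    for aa in (1014, 918):
        assert raf(nine, aa) == raf(margins, aa)
        assert 0 <= raf(nine, aa) <= 100


def test_count_table_validation():
    with pytest.raises(ValidationError):
        GenotypeCountTable("x", 2019, "pre", 5, counts={"L/L:M/M": 4})
    with pytest.raises(ValidationError):
        margin_table("x", 2019, "pre", 5, (1, 1, 1), (5, 0, 0))
    with pytest.raises(ValidationError):
        GenotypeCountTable("x", 2019, "pre", 1, counts={"Z/Z:M/M": 1})


# ---------------------------------------------------------------------------
# exact test


def oracle_fisher(table):
    """Brute force over all fillings; row-wise multinomial integer weights."""
    r1, r2 = (int(sum(row)) for row in table)
    cols = [int(a + b) for a, b in zip(*table)]
    support = []
    for x in product(*[range(c + 1) for c in cols]):
        if sum(x) != r1:
            continue
        v = factorial(r1)
        for xi in x:
            v //= factorial(xi)
        w = factorial(r2)
        for ci, xi in zip(cols, x):
            w //= factorial(ci - xi)
        support.append((x, v * w))
    v_obs = next(v for x, v in support if x == tuple(table[0]))
    return sum(v for _, v in support if v <= v_obs) / sum(v for _, v in support)


def test_fisher_toy_2x2():
    assert fisher_exact_2xk([[3, 1], [1, 3]]) == pytest.approx(0.4857142857, abs=1e-9)


def test_fisher_identical_rows_p_one():
    assert fisher_exact_2xk([[4, 6, 2], [4, 6, 2]]) == pytest.approx(1.0)


def test_fisher_degenerate_zero_row():
    with pytest.raises(DegenerateTableError):
        fisher_exact_2xk([[0, 0, 0], [3, 1, 2]])


def test_fisher_drops_zero_columns():
    assert fisher_exact_2xk([[3, 0, 1], [1, 0, 3]]) == fisher_exact_2xk([[3, 1], [1, 3]])


def test_fisher_matches_scipy_on_2x2():
    rng = np.random.default_rng(42)
    for _ in range(50):
        t = rng.integers(0, 12, size=(2, 2))
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            continue
        _, p = sps.fisher_exact(t, alternative="two-sided")
        assert fisher_exact_2xk(t) == pytest.approx(p, rel=1e-9), t


def test_fisher_matches_bruteforce_on_random_2xk():
    rng = np.random.default_rng(7)
    for k in (2, 3, 4):
        for _ in range(25):
            t = rng.integers(0, 6, size=(2, k))
            if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).all():
                continue
            t = t[:, t.sum(axis=0) > 0]
            if t.shape[1] < 2:
                continue
            assert fisher_exact_2xk(t) == pytest.approx(oracle_fisher(t), rel=1e-12)


def test_fisher_monte_carlo_fallback_close_to_exact():
    t = [[11, 14, 81, 8, 4], [1, 3, 22, 9, 3]]
    exact = fisher_exact_2xk(t)
    mc = fisher_exact_2xk(t, mc_budget=1, mc_draws=200_000, mc_seed=99)
    assert mc == pytest.approx(exact, abs=0.01)


def test_fisher_row_and_column_permutation_invariance():
    rng = np.random.default_rng(3)
    for _ in range(20):
        t = rng.integers(0, 8, size=(2, 3))
        if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
            continue
        p = fisher_exact_2xk(t)
        assert fisher_exact_2xk(t[::-1]) == pytest.approx(p, rel=1e-12)
        perm = rng.permutation(3)
        assert fisher_exact_2xk(t[:, perm]) == pytest.approx(p, rel=1e-12)


# ---------------------------------------------------------------------------
# odds ratios


def test_allele_or_reference_examples():
    kanawha = allele_or(AlleleCount(918, 7, 233), AlleleCount(918, 32, 174))
    assert round(kanawha.estimate, 2) == 6.12
    nashua = allele_or(AlleleCount(918, 12, 208), AlleleCount(918, 38, 38))
    assert round(nashua.estimate, 2) == 17.33


def test_allele_or_null_and_correction():
    same = allele_or(AlleleCount(1014, 10, 30), AlleleCount(1014, 10, 30))
    assert same.estimate == pytest.approx(1.0)
    with pytest.warns(UserWarning, match="Haldane"):
        res = allele_or(AlleleCount(1014, 0, 40), AlleleCount(1014, 5, 35))
    assert res.corrected
    assert res.estimate > 1


# ---------------------------------------------------------------------------
# GLM and pooling

STRATA_2019_1014 = [
    ("Boone", AlleleCount(1014, 69, 171), AlleleCount(1014, 51, 43)),
    ("Kanawha", AlleleCount(1014, 138, 102), AlleleCount(1014, 125, 81)),
    ("Sutherland", AlleleCount(1014, 90, 140), AlleleCount(1014, 95, 95)),
]


def test_glm_time_coefficient_is_single_location_log_or():
    strata = STRATA_2019_1014[:1]
    fit = fit_allele_glm(strata)
    raw = allele_or(*strata[0][1:])
    assert fit.params["time_post"] == pytest.approx(log(raw.estimate), abs=1e-8)
    assert pooled_or(fit).estimate == pytest.approx(raw.estimate, abs=1e-8)
    assert pooled_or(fit).pooling == "single-location"


def test_glm_reproduces_per_location_raw_odds_ratios():
    fit = fit_allele_glm(STRATA_2019_1014)
    expected = {"Boone": 2.9394, "Kanawha": 1.1406, "Sutherland": 1.5556}
    for loc, val in expected.items():
        assert fit.location_or(loc) == pytest.approx(val, abs=2e-4)
        raw = allele_or(*[s[1:] for s in STRATA_2019_1014 if s[0] == loc][0])
        assert fit.location_or(loc) == pytest.approx(raw.estimate, abs=1e-8)


def test_glm_null_data_zero_coefficients():
    strata = [
        ("A", AlleleCount(1014, 30, 70), AlleleCount(1014, 30, 70)),
        ("B", AlleleCount(1014, 30, 70), AlleleCount(1014, 30, 70)),
    ]
    fit = fit_allele_glm(strata)
    for name, val in fit.params.items():
        if name != "intercept":
            assert val == pytest.approx(0.0, abs=1e-7)


def test_pooled_or_is_geometric_mean_of_location_ors():
    fit = fit_allele_glm(STRATA_2019_1014)
    pooled = pooled_or(fit)
    gm = exp(
        np.mean([log(fit.location_or(l)) for l in fit.locations])
    )
    assert pooled.estimate == pytest.approx(gm, abs=1e-8)
    assert round(pooled.estimate, 2) == 1.73


def test_pooled_or_permutation_invariant_and_shrinks_toward_one():
    fit = fit_allele_glm(STRATA_2019_1014)
    reordered = fit_allele_glm(STRATA_2019_1014[::-1])
    assert pooled_or(fit).estimate == pytest.approx(
        pooled_or(reordered).estimate, abs=1e-8
    )
    null_loc = ("Null", AlleleCount(1014, 50, 50), AlleleCount(1014, 50, 50))
    augmented = fit_allele_glm(STRATA_2019_1014 + [null_loc])
    base, aug = pooled_or(fit).estimate, pooled_or(augmented).estimate
    assert abs(log(aug)) < abs(log(base))  # moved toward 1 on the log scale


# ---------------------------------------------------------------------------
# genotype shift


def test_genotype_shift_super_kdr_increase(association_tables):
    mor = find_table(association_tables, "All", "moribund", 2019, "bifenthrin")
    sur = find_table(association_tables, "All", "survivor", 2019, "bifenthrin")
    shift = genotype_shift(mor, sur).set_index("genotype")
    row = shift.loc["L/F:M/I"]
    assert (row["before_pct"], row["after_pct"]) == (6.8, 23.7)
    assert row["change"] == pytest.approx(16.9)


def test_genotype_shift_identical_tables_all_zero():
    t = GenotypeCountTable(
        "x", 2019, "moribund", 10, counts={"L/L:M/M": 4, "L/F:M/M": 6}
    )
    shift = genotype_shift(t, t)
    assert (shift["change"].abs() < 1e-12).all()


def test_lambda_survivor_super_kdr_percentage(association_tables):
    sur = find_table(association_tables, "All", "survivor", 2019, "lambda-cyhalothrin")
    assert round(100 * sur.counts["L/F:M/I"] / sur.n, 1) == 42.6
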