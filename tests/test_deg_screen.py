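"""Exact-test correctness, FDR adjustment and the significance screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import nbinom

from dgeflow.deg_screen import (
    ScreenThresholds,
    ac_probability,
    ac_pvalue_two_sided,
    bh_adjust,
    deg_summary,
    log2_ratio,
    screen_degs,
)
from dgeflow.errors import ValidationError
from dgeflow.evaluation import ac_pvalue_bruteforce
from dgeflow.expression import CountMatrix


# ---------------------------------------------------------------------------
# Conditional probability P(y|x)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "y, x, expected",
    [
        (0, 0, 0.5),                 # reduces to 1/2^(x+y+1) at equal sizes
        (2, 2, 6 / 32),              # C(4,2)/2^5
        (5, 0, 1 / 2**6),
    ],
)
def test_conditional_probability_equal_sizes(y, x, expected):
    assert ac_probability(y, x, 1e6, 1e6) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("x", [0, 1, 7, 25])
@pytest.mark.parametrize("ratio", [0.5, 1.0, 2.0])
def test_conditional_probability_is_normalized(x, ratio):
    """sum_y P(y|x) = 1 for any x and library-size ratio."""
    n1, n2 = 1e6, ratio * 1e6
    total = sum(ac_probability(y, x, n1, n2) for y in range(40 * (x + 10)))
    assert total == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("x", [0, 3, 12])
@pytest.mark.parametrize("ratio", [0.5, 2.0])
def test_conditional_matches_negative_binomial(x, ratio):
    """The conditional law is NB(r=x+1, p=N1/(N1+N2)) — an independent
    route through scipy's distribution machinery."""
    n1, n2 = 1e6, ratio * 1e6
    p = n1 / (n1 + n2)
    for y in range(0, 40):
        assert ac_probability(y, x, n1, n2) == pytest.approx(
            nbinom.pmf(y, x + 1, p), rel=1e-10
        )


def test_probability_rejects_negative_counts():
    with pytest.raises(ValidationError):
        ac_probability(-1, 0, 1e6, 1e6)
    with pytest.raises(ValidationError):
        ac_pvalue_two_sided(0, 0, 0, 1e6)


def test_large_counts_do_not_overflow():
    p = ac_probability(500_000, 500_000, 1e6, 1e6)
    assert 0 < p < 1


# ---------------------------------------------------------------------------
# Two-sided p-value
# ---------------------------------------------------------------------------

def test_pvalue_balanced_observation_is_one():
    assert ac_pvalue_two_sided(2, 2, 1e6, 1e6) == 1.0
    assert ac_pvalue_two_sided(50, 50, 1e6, 1e6) == 1.0


def test_pvalue_extreme_tail_closed_form():
    # P(Y <= 0 | x=100) = 1/2^101 at equal sizes, doubled
    assert ac_pvalue_two_sided(100, 0, 1e6, 1e6) == pytest.approx(
        2 / 2**101, rel=1e-10
    )


def test_pvalue_agrees_with_bruteforce_on_spot_grid():
    """Spot panel of the full acceptance grid (exhaustive version in the
    acceptance suite)."""
    for ratio in (0.5, 1.0, 2.0):
        n1, n2 = 1e6, ratio * 1e6
        for x, y in [(0, 0), (0, 10), (10, 0), (3, 17), (30, 30), (25, 4)]:
            assert ac_pvalue_two_sided(x, y, n1, n2) == pytest.approx(
                ac_pvalue_bruteforce(x, y, n1, n2), abs=1e-10
            )


@settings(derandomize=True, max_examples=60)
@given(x=st.integers(0, 200), y=st.integers(0, 200), n=st.integers(10**5, 10**7))
def test_conditional_probability_exchange_symmetry_equal_sizes(x, y, n):
    """At equal library sizes P(y|x) = P(x|y): the conditional probability
    reduces to C(x+y, y) / 2^(x+y+1), symmetric in the two counts."""
    assert ac_probability(y, x, n, n) == pytest.approx(
        ac_probability(x, y, n, n), rel=1e-9, abs=1e-300
    )


def test_pvalue_near_symmetry_between_orientations():
    """The p-value conditions on whichever count is 'x', so the two
    orientations are not identical for small or size-imbalanced counts;
    for informative counts they agree in magnitude."""
    for x, y, ratio in [(30, 120, 2.0), (100, 20, 0.5), (10, 80, 3.0), (40, 160, 1.0)]:
        n1, n2 = 1e6, ratio * 1e6
        a = ac_pvalue_two_sided(x, y, n1, n2)
        b = ac_pvalue_two_sided(y, x, n2, n1)
        assert 0.5 < a / b < 2.0


def test_pvalue_monotone_in_imbalance():
    """At fixed x+y and equal sizes, a more lopsided split is never less
    significant."""
    total = 40
    previous = None
    for y in range(total // 2, total + 1):
        p = ac_pvalue_two_sided(total - y, y, 1e6, 1e6)
        if previous is not None:
            assert p <= previous + 1e-12
        previous = p


# ---------------------------------------------------------------------------
# BH adjustment and log2 ratio
# ---------------------------------------------------------------------------

def test_bh_hand_worked_step_up():
    got = bh_adjust([0.001, 0.008, 0.039, 0.041])
    assert np.allclose(got, [0.004, 0.016, 0.041, 0.041])


def test_bh_constant_and_single_inputs():
    assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)
    assert bh_adjust([0.03])[0] == pytest.approx(0.03)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValidationError):
        bh_adjust([0.1, 1.5])


def test_bh_monotone_when_sorted_by_p():
    rng = np.random.default_rng(0)
    p = rng.random(200)
    q = bh_adjust(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


@pytest.mark.parametrize(
    "x, y, expected",
    [(10, 10, 0.0), (10, 20, np.log2(21 / 11)), (0, 63, 6.0)],
)
def test_log2_ratio_pseudocounted(x, y, expected):
    assert log2_ratio(x, y, 1e6, 1e6, pseudocount=1.0) == pytest.approx(expected)


def test_log2_ratio_accounts_for_library_size():
    # same counts, double-size test library -> halved normalized expression
    assert log2_ratio(10, 10, 1e6, 2e6) == pytest.approx(-1.0)


# ---------------------------------------------------------------------------
# Screen
# ---------------------------------------------------------------------------

def _matrix(xs, ys, n=10**6):
    genes = [f"g{i}" for i in range(len(xs))]
    return CountMatrix(
        pd.DataFrame({"A": xs, "B": ys}, index=genes),
        pd.Series({"A": n, "B": n}),
    )


def test_screen_excludes_double_zero_genes():
    table = screen_degs(_matrix([0, 5, 0], [0, 5, 3]), ("A", "B"))
    assert set(table["gene_id"]) == {"g1", "g2"}


def test_screen_unknown_library_is_lookup_error():
    with pytest.raises(KeyError):
        screen_degs(_matrix([1], [1]), ("A", "C"))


def test_screen_calls_planted_gene_with_high_power():
    """An 8-fold change on a gene with ~10 expected reference tags at N=1e6
    is called 'up' in at least 95 of 100 seeded draws."""
    rng = np.random.default_rng(2024)
    n = 10**6
    hits = 0
    for _ in range(100):
        xs = rng.poisson(10.0, size=51)
        ys = rng.poisson(10.0, size=51)
        ys[0] = rng.poisson(80.0)  # planted log2 fold 3 at baseline rate 1e-5
        table = screen_degs(_matrix(xs, ys, n), ("A", "B"))
        row = table[table["gene_id"] == "g0"]
        if len(row) and row["direction"].iloc[0] == "up":
            hits += 1
    assert hits >= 95


def test_deg_summary_counts_directions():
    table = pd.DataFrame({"direction": ["up"] * 3 + ["down"] * 2 + ["ns"] * 5})
    assert deg_summary(table) == (3, 2)
    assert deg_summary(table.iloc[:0]) == (0, 0)


def test_thresholds_validate():
    with pytest.raises(ValidationError):
        ScreenThresholds(fdr_max=0.0)
    with pytest.raises(ValidationError):
        ScreenThresholds(pseudocount=0.0)
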