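"""Contingency-test primitives against brute-force oracles and known values."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h
from scipy.special import comb

from evoko.stats import (
    ContingencyTable2x2,
    bh_adjust,
    chisq_2x2,
    fisher_exact,
    hypergeom_tail,
    mann_whitney_u,
)


def round_2sf(x: float) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + 1)


# ---------------------------------------------------------------- oracles


def hypergeom_pmf_exact(k, N, K, n):
    return comb(K, k, exact=True) * comb(N - K, n - k, exact=True) / comb(N, n, exact=True)


def hypergeom_tail_brute(k, n, K, N):
    return sum(hypergeom_pmf_exact(j, N, K, n) for j in range(k, min(n, K) + 1))


def bh_brute(p):
    m = len(p)
    idx = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = idx[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top, 1.0)
        adj[i] = val
        prev = val
    return adj


def mwu_enumerate(x, y):
    """Exact two-sided MWU P by enumerating all group assignments."""
    pooled = list(x) + list(y)
    nx = len(x)
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    u_obs = sum(ranks[v] for v in x) - nx * (nx + 1) / 2
    mu = nx * len(y) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        u = sum(ranks[pooled[i]] for i in combo) - nx * (nx + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------- fisher


@pytest.mark.parametrize(
    "table, alternative, expected_2sf",
    [
        # heritability-significance contrast: 17/65 clustered vs 1/130 distributed
        ([[17, 48], [1, 129]], "two_sided", 2.1e-8),
        # direct-target enrichment: 12/65 vs 1/130
        ([[12, 53], [1, 129]], "two_sided", 8.6e-6),
        # morphology sharing, one-tailed: 14/24 vs 18/54
        ([[14, 10], [18, 36]], "greater", 0.035),
    ],
)
def test_fisher_reproduces_printed_values(table, alternative, expected_2sf):
    assert round_2sf(fisher_exact(table, alternative)) == expected_2sf


def test_fisher_degenerate_margin_is_uninformative():
    assert fisher_exact([[0, 5], [0, 7]]) == 1.0
    assert fisher_exact([[0, 5], [0, 7]], "greater") == 1.0


def test_fisher_rejects_negative_cells():
    with pytest.raises(ValueError):
        fisher_exact([[1, -2], [3, 4]])


@given(
    a=st_h.integers(0, 12), b=st_h.integers(0, 12), c=st_h.integers(0, 12), d=st_h.integers(0, 12)
)
@settings(max_examples=60, derandomize=True, deadline=None)
def test_fisher_symmetry_and_tail_overlap(a, b, c, d):
    if a + b + c + d == 0:
        return
    t = [[a, b], [c, d]]
    swapped = [[d, c], [b, a]]  # simultaneous row + column swap
    assert fisher_exact(t) == pytest.approx(fisher_exact(swapped), rel=1e-9)
    # the observed table is counted in both one-sided tails
    assert fisher_exact(t, "greater") + fisher_exact(t, "less") >= 1.0 - 1e-12


# ---------------------------------------------------------------- chi-square


def test_chisq_reproduces_printed_conservation_contrast():
    # 18/65 clustered vs 7/130 distributed conserved effects
    assert round_2sf(chisq_2x2([[18, 47], [7, 123]], correction=True)) == 3.1e-5


def test_chisq_without_correction_matches_pearson_formula():
    obs = np.array([[7.0, 123.0], [18.0, 47.0]])
    exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    stat = ((obs - exp) ** 2 / exp).sum()
    from scipy.stats import chi2

    assert chisq_2x2([[7, 123], [18, 47]], correction=False) == pytest.approx(
        chi2.sf(stat, 1), rel=1e-12
    )
    assert round_2sf(chisq_2x2([[7, 123], [18, 47]], correction=False)) == 1.1e-5


def test_chisq_at_expectation_is_one():
    assert chisq_2x2([[10, 10], [10, 10]]) == 1.0


def test_chisq_rejects_zero_margin():
    with pytest.raises(ValueError):
        chisq_2x2([[0, 0], [5, 7]])


# ---------------------------------------------------------------- hypergeometric


def test_hypergeom_reproduces_printed_direct_target_value():
    # 10 direct targets among 20 overlapped effects vs 33/5146 background
    assert round_2sf(hypergeom_tail(10, 20, 33, 5146)) == 4.6e-18


@pytest.mark.parametrize("k,n,K,N,expected", [(0, 5, 10, 30, 1.0), (5, 5, 5, 5, 1.0)])
def test_hypergeom_trivial_tails(k, n, K, N, expected):
    assert hypergeom_tail(k, n, K, N) == expected


@given(
    N=st_h.integers(5, 60),
    data=st_h.data(),
)
@settings(max_examples=60, derandomize=True, deadline=None)
def test_hypergeom_matches_brute_force_summation(N, data):
    K = data.draw(st_h.integers(1, N))
    n = data.draw(st_h.integers(1, N))
    k = data.draw(st_h.integers(0, min(n, K)))
    assert hypergeom_tail(k, n, K, N) == pytest.approx(
        hypergeom_tail_brute(k, n, K, N), rel=1e-10
    )


def test_hypergeom_rejects_inconsistent_arguments():
    with pytest.raises(ValueError):
        hypergeom_tail(6, 5, 10, 30)
    with pytest.raises(ValueError):
        hypergeom_tail(1, 10, 5, 8)


# ---------------------------------------------------------------- Mann-Whitney


def test_mwu_exact_small_samples():
    assert mann_whitney_u([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


def test_mwu_identical_samples():
    x = [1.0, 2.0, 3.0, 4.0]
    assert mann_whitney_u(x, x) >= 0.99
    assert mann_whitney_u([1, 2], [1, 2]) == pytest.approx(1.0, abs=1e-9)


def test_mwu_rejects_empty():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


def test_mwu_exact_path_agrees_with_enumeration(rng):
    for _ in range(15):
        nx, ny = rng.integers(2, 7, size=2)
        pooled = rng.permutation(rng.normal(size=nx + ny))
        x, y = pooled[:nx], pooled[nx:]
        assert mann_whitney_u(x, y) == pytest.approx(mwu_enumerate(x, y), rel=1e-9)


# ---------------------------------------------------------------- BH


@pytest.mark.parametrize(
    "raw, expected",
    [
        ([0.05], [0.05]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([1.0, 1.0], [1.0, 1.0]),
    ],
)
def test_bh_known_values(raw, expected):
    assert bh_adjust(raw).adjusted == pytest.approx(expected)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.2, 1.5])


@given(
    p=st_h.lists(st_h.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=50)
)
@settings(max_examples=80, derandomize=True, deadline=None)
def test_bh_matches_brute_force_and_statsmodels(p):
    got = bh_adjust(p).adjusted
    assert got == pytest.approx(bh_brute(p), abs=1e-12)
    from statsmodels.stats.multitest import multipletests

    sm = multipletests(p, method="fdr_bh")[1]
    assert got == pytest.approx(list(sm), abs=1e-12)
    assert all(g >= r for g, r in zip(got, p))
    assert all(g <= 1.0 for g in got)


def test_contingency_table_validation():
    with pytest.raises(ValueError):
        ContingencyTable2x2(0, 0, 0, 0)
    t = ContingencyTable2x2(1, 2, 3, 4)
    assert t.as_array().sum() == 10
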