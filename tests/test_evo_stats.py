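"""Distances, grouping, dating and correlation against closed-form oracles."""
from __future__ import annotations

import numpy as np
import pytest

from crispratlas.evo_stats import (
    DistanceMatrix,
    DivergenceParams,
    clock_years,
    distance_matrix,
    divergence_estimate,
    group_close_strains,
    neutral_generations,
    p_distance,
    repeat_correlation,
)


def test_p_distance_basic():
    assert p_distance("ACGT", "ACGT") == 0.0
    assert p_distance("ACGT", "ACGA") == 0.25
    # gap / N columns excluded from the denominator
    assert p_distance("AC-T", "ACGT") == 0.0
    assert p_distance("ACNT", "ACGA") == pytest.approx(1 / 3)
    with pytest.raises(ValueError):
        p_distance("ACG", "ACGT")
    with pytest.raises(ValueError):
        p_distance("NNN", "NNN")


def test_jukes_cantor_negligible_at_small_d():
    # at the distances of interest the correction is < 0.1% relative
    seq_a = "A" * 10_000
    seq_b = "C" * 2 + "A" * 9_998       # p = 2e-4
    p = p_distance(seq_a, seq_b)
    jc = p_distance(seq_a, seq_b, jukes_cantor=True)
    assert p == pytest.approx(2e-4)
    assert jc == pytest.approx(p, rel=1e-3)
    assert jc > p


def test_distance_matrix_symmetry_and_get():
    D = distance_matrix({"a": "ACGT", "b": "ACGA", "c": "ACGT"})
    assert D.labels == ["a", "b", "c"]
    assert D.get("a", "b") == D.get("b", "a") == 0.25
    assert D.get("a", "c") == 0.0


def test_distance_matrix_validation():
    with pytest.raises(ValueError):
        DistanceMatrix(labels=["a", "b"], d=np.array([[0.0, 1.0], [0.5, 0.0]]))


def test_grouping_partitions_and_threshold_is_strict():
    labels = ["a", "b", "c", "d"]
    d = np.zeros((4, 4))
    d[0, 1] = d[1, 0] = 1e-5          # grouped
    d[2, 3] = d[3, 2] = 2e-4          # exactly at threshold: NOT grouped
    d[0, 2] = d[2, 0] = d[0, 3] = d[3, 0] = 1e-3
    d[1, 2] = d[2, 1] = d[1, 3] = d[3, 1] = 1e-3
    groups = group_close_strains(DistanceMatrix(labels, d), threshold=2e-4)
    members = sorted(tuple(g.members) for g in groups)
    assert members == [("a", "b"), ("c",), ("d",)]
    assert sorted(m for g in groups for m in g.members) == labels


def test_grouping_single_linkage_transitivity():
    labels = ["a", "b", "c"]
    d = np.zeros((3, 3))
    d[0, 1] = d[1, 0] = 1e-5
    d[1, 2] = d[2, 1] = 1e-5
    d[0, 2] = d[2, 0] = 5e-4          # far, but linked through b
    groups = group_close_strains(DistanceMatrix(labels, d), threshold=2e-4)
    assert [g.members for g in groups] == [["a", "b", "c"]]


def test_dating_linear_and_zero_at_zero():
    assert clock_years(0.0) == 0.0
    assert neutral_generations(0.0)[0] == 0.0
    assert clock_years(4e-4) == pytest.approx(2 * clock_years(2e-4))
    g1, _ = neutral_generations(4e-4)
    g2, _ = neutral_generations(2e-4)
    assert g1 == pytest.approx(2 * g2)


def test_dating_closed_forms():
    assert clock_years(2e-4) == pytest.approx(2e-4 / 7.6e-10)
    gens, years = neutral_generations(2e-4)
    r = (1e-3 / 5e6) * 3.5
    assert gens == pytest.approx(2e-4 / r)
    assert years == pytest.approx(gens * 40.0 / 8766.0)
    est = divergence_estimate(2e-4)
    assert est.generations_neutral == pytest.approx(gens)
    assert est.years_clock == pytest.approx(clock_years(2e-4))


def test_divergence_params_validation():
    with pytest.raises(ValueError):
        DivergenceParams(mu_year=0.0)
    with pytest.raises(ValueError):
        DivergenceParams(G=-1)


def test_correlation_exact_linear():
    res = repeat_correlation([1, 2, 3, 4, 5], [3, 5, 7, 9, 11], n_perm=200, seed=1)
    assert res.r_squared == pytest.approx(1.0)
    assert res.n == 5


def test_correlation_matches_covariance_formula():
    x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
    y = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0])
    res = repeat_correlation(x, y, n_perm=100, seed=0)
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    expected = (cov / (x.std() * y.std())) ** 2
    assert res.r_squared == pytest.approx(expected)


def test_correlation_independent_has_large_p():
    rng = np.random.default_rng(7)
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    res = repeat_correlation(x, y, n_perm=2000, seed=2)
    assert res.p_perm > 0.05


def test_correlation_rejects_degenerate_input():
    with pytest.raises(ValueError):
        repeat_correlation([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError):
        repeat_correlation([1, 2], [1, 2])
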