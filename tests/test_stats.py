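"""Tests of the proportion, Kruskal–Wallis and Dunn implementations against
independent oracles (closed-form 2x2 formula, brute-force rank computation,
scipy's reference Kruskal–Wallis) and their type-I error behaviour."""

import numpy as np
import pytest
import scipy.stats

from dropfreeze.stats import dunn_posthoc, kruskal_wallis, prop_test_2x2


# ---------------------------------------------------------------- oracles


def yates_2x2(a, b, c, d):
    """Closed-form Yates chi-squared for a 2x2 table, evaluated directly."""
    n = a + b + c + d
    dev = max(abs(a * d - b * c) - n / 2, 0.0)
    return n * dev**2 / ((a + b) * (c + d) * (a + c) * (b + d))


def midranks(values):
    """Mid-ranks by explicit sorting — independent of scipy.rankdata."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_force_kw(groups):
    """H via the alternative algebraic form 12/(N(N+1)) * sum(R_i^2/n_i) - 3(N+1),
    with the tie-correction divisor."""
    pooled = [v for g in groups for v in g]
    ranks = midranks(pooled)
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = sum(ranks[start : start + len(g)])
        h += r**2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    tie_sum = sum(t**3 - t for t in ties.values())
    corr = 1 - tie_sum / (n**3 - n)
    return 0.0 if corr == 0 else h / corr


def brute_force_dunn_z(groups, i, j):
    pooled = [v for g in groups for v in g]
    ranks = midranks(pooled)
    n = len(pooled)
    means = []
    start = 0
    for g in groups:
        means.append(sum(ranks[start : start + len(g)]) / len(g))
        start += len(g)
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    tie_sum = sum(t**3 - t for t in ties.values())
    var = n * (n + 1) / 12 - tie_sum / (12 * (n - 1))
    se = (var * (1 / len(groups[i]) + 1 / len(groups[j]))) ** 0.5
    return (means[i] - means[j]) / se


# ----------------------------------------------------------- prop_test_2x2


def test_prop_test_matches_closed_form_on_random_tables():
    rng = np.random.default_rng(7)
    for _ in range(100):
        n1, n2 = rng.integers(2, 60, size=2)
        k1 = int(rng.integers(0, n1 + 1))
        k2 = int(rng.integers(0, n2 + 1))
        if k1 + k2 == 0 or (n1 - k1) + (n2 - k2) == 0:
            continue
        res = prop_test_2x2(k1, int(n1), k2, int(n2))
        expected = yates_2x2(k1, n1 - k1, k2, n2 - k2)
        assert res.statistic == pytest.approx(expected, abs=1e-10)
        assert res.df == 1


def test_prop_test_agrees_with_reference_contingency_test():
    table = np.array([[10, 22], [0, 17]])
    res = prop_test_2x2(10, 32, 0, 17)
    ref = scipy.stats.chi2_contingency(table, correction=True)
    assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)


def test_equal_proportions_give_zero_statistic():
    res = prop_test_2x2(5, 10, 10, 20)
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_continuity_correction_shrinks_the_statistic():
    with_c = prop_test_2x2(10, 32, 0, 17, continuity=True)
    without = prop_test_2x2(10, 32, 0, 17, continuity=False)
    assert without.statistic > with_c.statistic


def test_degenerate_margins_warn_and_return_null():
    with pytest.warns(UserWarning, match="degenerate"):
        res = prop_test_2x2(0, 10, 0, 12)
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_prop_test_rejects_bad_counts():
    with pytest.raises(ValueError):
        prop_test_2x2(5, 4, 1, 10)
    with pytest.raises(ValueError):
        prop_test_2x2(0, 0, 1, 10)


# ---------------------------------------------------------- kruskal_wallis


def test_kw_identical_values_give_zero():
    res = kruskal_wallis([[3.0, 3.0], [3.0, 3.0], [3.0]])
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_kw_df_is_group_count_minus_one():
    res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
    assert res.df == 2


def test_kw_matches_brute_force_and_scipy():
    groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
    res = kruskal_wallis(groups)
    assert res.statistic == pytest.approx(brute_force_kw(groups), abs=1e-12)
    ref = scipy.stats.kruskal(*groups)
    assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)


def test_kw_matches_oracles_on_small_random_inputs_with_ties():
    rng = np.random.default_rng(11)
    for _ in range(50):
        sizes = rng.integers(2, 4, size=3)
        while sizes.sum() > 9:
            sizes = rng.integers(2, 4, size=3)
        groups = [list(rng.integers(0, 5, size=s).astype(float)) for s in sizes]
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            continue
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(brute_force_kw(groups), abs=1e-10)
        ref = scipy.stats.kruskal(*groups)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)


def test_kw_invariant_under_monotone_transforms():
    rng = np.random.default_rng(3)
    groups = [list(rng.normal(size=6)) for _ in range(3)]
    base = kruskal_wallis(groups).statistic
    for f in (np.exp, lambda x: x**3, lambda x: 5 * np.asarray(x) - 2):
        transformed = [list(f(np.asarray(g))) for g in groups]
        assert kruskal_wallis(transformed).statistic == pytest.approx(base, abs=1e-10)


def test_kw_input_validation():
    with pytest.raises(ValueError):
        kruskal_wallis([[1.0, 2.0]])
    with pytest.raises(ValueError):
        kruskal_wallis([[1.0], []])


# ------------------------------------------------------------ dunn_posthoc


def test_dunn_identical_groups_give_zero_z():
    results = dunn_posthoc([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
    assert all(r.statistic == 0.0 and r.p_value == 1.0 for r in results)


def test_dunn_pair_count_is_k_choose_2():
    assert len(dunn_posthoc([[1, 2], [3, 4], [5, 6]])) == 3
    assert len(dunn_posthoc([[1, 2], [3, 4], [5, 6], [7, 8]])) == 6


def test_dunn_matches_brute_force_on_worked_dataset():
    groups = [[1.0, 2.0, 4.0], [3.0, 5.0, 6.0], [7.0, 8.0, 9.0]]
    results = {(r.group_a, r.group_b): r for r in dunn_posthoc(groups)}
    for i, j in ((0, 1), (0, 2), (1, 2)):
        assert results[(i, j)].statistic == pytest.approx(
            brute_force_dunn_z(groups, i, j), abs=1e-12
        )


def test_dunn_matches_brute_force_with_ties():
    rng = np.random.default_rng(23)
    for _ in range(30):
        groups = [list(rng.integers(0, 4, size=3).astype(float)) for _ in range(3)]
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            continue
        results = {(r.group_a, r.group_b): r for r in dunn_posthoc(groups)}
        for (i, j), r in results.items():
            assert r.statistic == pytest.approx(
                brute_force_dunn_z(groups, i, j), abs=1e-10
            )


def test_holm_adjustment_never_smaller_than_raw():
    rng = np.random.default_rng(5)
    groups = [list(rng.normal(loc=m, size=5)) for m in (0, 0.5, 2.0)]
    raw = dunn_posthoc(groups, adjustment="none")
    holm = dunn_posthoc(groups, adjustment="holm")
    for r, h in zip(raw, holm):
        assert h.p_adjusted >= r.p_adjusted - 1e-15


def test_dunn_unknown_adjustment_rejected():
    with pytest.raises(ValueError):
        dunn_posthoc([[1, 2], [3, 4]], adjustment="bonferroni")


# ------------------------------------------------------------ type-I error


def test_prop_test_type_I_error_is_conservative():
    """Under equal binomials the Yates-corrected test rejects at most ~5 %."""
    rng = np.random.default_rng(101)
    n_sim = 2000
    rejections = 0
    for _ in range(n_sim):
        k1 = int(rng.binomial(30, 0.4))
        k2 = int(rng.binomial(25, 0.4))
        if k1 + k2 == 0 or (30 - k1) + (25 - k2) == 0:
            continue
        rejections += prop_test_2x2(k1, 30, k2, 25).p_value < 0.05
    mc_err = np.sqrt(0.05 * 0.95 / n_sim)
    assert rejections / n_sim <= 0.05 + 3 * mc_err


def test_kw_type_I_error_near_nominal():
    rng = np.random.default_rng(202)
    n_sim = 2000
    rejections = sum(
        kruskal_wallis([rng.normal(size=8) for _ in range(3)]).p_value < 0.05
        for _ in range(n_sim)
    )
    mc_err = np.sqrt(0.05 * 0.95 / n_sim)
    assert abs(rejections / n_sim - 0.05) <= 3 * mc_err


def test_dunn_pairwise_type_I_error_near_nominal():
    rng = np.random.default_rng(303)
    n_sim = 1000
    rejections = sum(
        dunn_posthoc([rng.normal(size=10) for _ in range(3)])[0].p_value < 0.05
        for _ in range(n_sim)
    )
    mc_err = np.sqrt(0.05 * 0.95 / n_sim)
    assert abs(rejections / n_sim - 0.05) <= 3 * mc_err
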