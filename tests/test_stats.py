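"""Size tests, multiplicity correction and Pillai-trace MANOVA."""

import itertools

import numpy as np
import pytest

from phalanxgmm.stats import (
    benjamini_hochberg,
    kruskal_wallis,
    manova_pillai,
    pairwise_manova,
    pairwise_wilcoxon_bh,
)


# ---------------------------------------------------------------------------
# Kruskal–Wallis


def test_kw_identical_groups_zero():
    res = kruskal_wallis([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
    assert res.chi_square == pytest.approx(0.0, abs=1e-12)
    assert res.df == 1


def test_kw_two_separated_pairs():
    # rank formula: H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2 = 2.4
    res = kruskal_wallis([1, 2, 3, 4], ["a", "a", "b", "b"])
    assert res.chi_square == pytest.approx(2.4)


def test_kw_df_four_levels(rng):
    values = rng.normal(size=20)
    groups = np.repeat(["a", "b", "c", "d"], 5)
    assert kruskal_wallis(values, groups).df == 3


def test_kw_rank_formula_oracle(rng):
    values = rng.normal(size=18)
    groups = rng.choice(["a", "b", "c"], size=18)
    while len(set(groups)) < 3:
        groups = rng.choice(["a", "b", "c"], size=18)
    from scipy.stats import rankdata

    ranks = rankdata(values)
    n = len(values)
    h = 0.0
    for g in "abc":
        r = ranks[groups == g]
        h += len(r) * (r.mean() - (n + 1) / 2) ** 2
    h *= 12 / (n * (n + 1))
    # no ties with continuous data, so no tie correction enters
    assert kruskal_wallis(values, groups).chi_square == pytest.approx(h, rel=1e-12)


def test_kw_all_tied_returns_p_one():
    res = kruskal_wallis([5.0] * 8, ["a"] * 4 + ["b"] * 4)
    assert res.chi_square == 0.0
    assert res.p == 1.0


# ---------------------------------------------------------------------------
# pairwise Wilcoxon + BH


def test_wilcoxon_exact_small_sample_enumeration():
    """x={1,2} vs y={3,4}: of the C(4,2)=6 equally likely rank assignments,
    the observed rank sum is the most extreme in both tails -> p = 2/6."""
    out = pairwise_wilcoxon_bh([1, 2, 3, 4], ["x", "x", "y", "y"])
    assert out.loc["x", "y"] == pytest.approx(1 / 3)


def test_bh_step_up_oracle():
    raw = np.array([0.01, 0.04, 0.03, 0.002])
    np.testing.assert_allclose(
        benjamini_hochberg(raw), [0.02, 0.04, 0.04, 0.008], atol=1e-12
    )


def test_bh_single_pair_unchanged():
    np.testing.assert_allclose(benjamini_hochberg([0.037]), [0.037])


def test_bh_monotone_and_not_below_raw(rng):
    raw = rng.uniform(size=25)
    adj = benjamini_hochberg(raw)
    assert np.all(adj >= raw - 1e-15)
    order = np.argsort(raw)
    assert np.all(np.diff(adj[order]) >= -1e-15)


def test_pairwise_matrix_shape(rng):
    values = rng.normal(size=30)
    groups = np.repeat(["a", "b", "c"], 10)
    out = pairwise_wilcoxon_bh(values, groups)
    assert out.shape == (3, 3)
    assert np.isnan(np.diag(out)).all()
    np.testing.assert_allclose(out.to_numpy(), out.to_numpy().T, equal_nan=True)


# ---------------------------------------------------------------------------
# MANOVA / Pillai


def _random_design(rng, n, g, p):
    scores = rng.normal(size=(n, p))
    labels = np.array(
        [f"g{i}" for i in np.sort(rng.integers(0, g, size=n - g)).tolist()]
        + [f"g{i}" for i in range(g)]
    )
    return scores, labels


@pytest.mark.parametrize(
    "p,q,n,g,num_df,den_df",
    [
        # overall tests, both limbs (composite 7-group factor)
        (12, 6, 34, 7, 72, 126),
        (14, 6, 44, 7, 84, 174),
        # overall subspecies / habitat / mobility designs
        (12, 3, 34, 4, 36, 63),
        (12, 2, 34, 3, 24, 42),
        (14, 3, 44, 4, 42, 87),
        (14, 2, 44, 3, 28, 58),
        (12, 5, 34, 6, 60, 105),
        (14, 5, 44, 6, 70, 145),
        (12, 3, 34, 4, 36, 63),
        (14, 3, 44, 4, 42, 87),
        # single-subspecies families
        (9, 2, 24, 3, 18, 28),
        (9, 3, 24, 4, 27, 42),
        (12, 2, 36, 3, 24, 46),
        (12, 3, 36, 4, 36, 69),
        # pairwise contrasts (q = 1, pooled full-model error)
        (12, 1, 34, 7, 12, 16),
        (14, 1, 44, 7, 14, 24),
        (9, 1, 24, 3, 9, 13),
        (12, 1, 36, 3, 12, 22),
        (12, 1, 36, 4, 12, 21),
    ],
)
def test_pillai_approximate_f_dfs(p, q, n, g, num_df, den_df):
    """The Pillai approximate-F df rule reproduces every printed (num, den)
    pair for the designs implied by the analyses."""
    rng = np.random.default_rng(p * 1000 + n)
    scores, labels = _random_design(rng, n, g, p)
    if q == g - 1:
        table = manova_pillai(scores, labels)
    else:  # pairwise contrast designs
        table = pairwise_manova(scores, labels)[0]
        assert all(t.den_df == den_df for t in pairwise_manova(scores, labels))
    assert (table.num_df, table.den_df) == (num_df, den_df)


def test_pillai_scalar_reduction_oracle(rng):
    """With p = 1 and two groups, Pillai's trace is SSB/(SSB+SSW)."""
    x = np.concatenate([rng.normal(size=6), rng.normal(loc=1.0, size=5)])
    labels = np.array(["a"] * 6 + ["b"] * 5)
    grand = x.mean()
    ssb = 6 * (x[:6].mean() - grand) ** 2 + 5 * (x[6:].mean() - grand) ** 2
    ssw = ((x[:6] - x[:6].mean()) ** 2).sum() + ((x[6:] - x[6:].mean()) ** 2).sum()
    table = manova_pillai(x[:, None], labels)
    assert table.pillai == pytest.approx(ssb / (ssb + ssw), rel=1e-12)


def test_pillai_range_property(rng):
    """0 <= V <= min(p, q) over many random datasets."""
    for _ in range(1000):
        p = int(rng.integers(1, 5))
        g = int(rng.integers(2, 5))
        n = int(rng.integers(g * 2 + p, g * 2 + p + 10))
        scores, labels = _random_design(rng, n, g, p)
        t = manova_pillai(scores, labels)
        assert -1e-10 <= t.pillai <= min(p, g - 1) + 1e-10


def test_pairwise_duplicate_group_null(rng):
    block = rng.normal(size=(6, 3))
    scores = np.vstack([block, block, rng.normal(size=(6, 3)) + 5])
    labels = np.array(["a"] * 6 + ["b"] * 6 + ["c"] * 6)
    tables = pairwise_manova(scores, labels)
    ab = next(t for t in tables if t.term == "a—b")
    assert ab.pillai == pytest.approx(0.0, abs=1e-12)
    assert ab.p_adjusted == pytest.approx(1.0)


def test_manova_rank_deficiency_guard(rng):
    scores = rng.normal(size=(10, 9))
    labels = np.repeat(["a", "b"], 5)
    with pytest.raises(ValueError, match="fewer PCs"):
        manova_pillai(scores, labels)
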