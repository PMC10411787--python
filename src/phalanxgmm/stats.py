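"""Group tests on size and shape: Kruskal–Wallis, pairwise rank tests with
Benjamini–Hochberg correction, and MANOVA with Pillai's trace.

Size (log centroid size) is compared across groups nonparametrically.
Shape is compared on PC scores: Pillai's trace
:math:`V = \\mathrm{tr}(H (H + E)^{-1})` from the between-group (H) and
within-group (E) cross-product matrices, with the standard approximate-F
transformation.  With ``p`` response variables, hypothesis df ``q`` and
error df :math:`n_e = n - g`:

.. math::
    s = \\min(p, q), \\quad m = (|p - q| - 1)/2, \\quad n' = (n_e - p - 1)/2

    F = \\frac{2n' + s + 1}{2m + s + 1} \\cdot \\frac{V/s}{1 - V/s},
    \\qquad \\mathrm{df} = \\bigl(s(2m + s + 1),\\; s(2n' + s + 1)\\bigr).

Pairwise shape contrasts are single-df comparisons (q = 1) tested against
the pooled within-group error of the full model, so the denominator df is
the same for every pair; their p-values are multiplied by the number of
pairs and capped at 1 (Bonferroni) by default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SizeTestResult",
    "ManovaTable",
    "kruskal_wallis",
    "pairwise_wilcoxon_bh",
    "benjamini_hochberg",
    "manova_pillai",
    "pairwise_manova",
]


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (false-discovery rate)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 1:
        return pvalues.copy()
    return multipletests(pvalues, method="fdr_bh")[1]


@dataclass
class SizeTestResult:
    factor: str
    df: int
    chi_square: float
    p: float
    pairwise: pd.DataFrame | None = None


@dataclass
class ManovaTable:
    term: str
    df: int
    pillai: float
    approx_f: float
    num_df: int
    den_df: int
    p: float
    n_pcs: int = 0
    p_adjusted: float | None = None

    def as_row(self) -> dict:
        row = {
            "term": self.term,
            "Df": self.df,
            "Pillai": self.pillai,
            "approx F": self.approx_f,
            "num Df": self.num_df,
            "den Df": self.den_df,
            "Pr(>F)": self.p,
            "n PCs": self.n_pcs,
        }
        if self.p_adjusted is not None:
            row["adj Pr(>F)"] = self.p_adjusted
        return row


def _as_groups(values, groups) -> tuple[np.ndarray, np.ndarray, list]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape[0] != groups.shape[0]:
        raise ValueError("values and group labels differ in length")
    levels = sorted(pd.unique(groups).tolist())
    return values, groups, levels


def kruskal_wallis(values, groups, factor: str = "") -> SizeTestResult:
    """Tie-corrected Kruskal–Wallis H test; df = number of groups - 1.

    An all-tied sample is reported as H = 0, p = 1 (no evidence of a
    location difference) rather than as undefined.
    """
    values, groups, levels = _as_groups(values, groups)
    if len(levels) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    samples = [values[groups == lv] for lv in levels]
    df = len(levels) - 1
    if np.all(values == values[0]):
        return SizeTestResult(factor=factor, df=df, chi_square=0.0, p=1.0)
    h, p = sps.kruskal(*samples)
    return SizeTestResult(factor=factor, df=df, chi_square=float(h), p=float(p))


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for small tie-free samples,
    normal approximation with continuity correction otherwise."""
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) <= 10 and len(y) <= 10 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def pairwise_wilcoxon_bh(values, groups) -> pd.DataFrame:
    """All unordered pairwise rank-sum tests, BH-adjusted over the family.

    Returns a symmetric DataFrame of adjusted p-values (diagonal NaN).
    Empty groups are excluded.
    """
    values, groups, levels = _as_groups(values, groups)
    levels = [lv for lv in levels if np.any(groups == lv)]
    if len(levels) < 2:
        raise ValueError("pairwise tests need at least 2 non-empty groups")
    pairs = list(itertools.combinations(levels, 2))
    raw = np.array(
        [_ranksum_p(values[groups == a], values[groups == b]) for a, b in pairs]
    )
    adjusted = benjamini_hochberg(raw)
    out = pd.DataFrame(np.nan, index=levels, columns=levels)
    for (a, b), p in zip(pairs, adjusted):
        out.loc[a, b] = out.loc[b, a] = p
    return out


def _cross_products(scores: np.ndarray, groups: np.ndarray, levels: list):
    grand = scores.mean(axis=0)
    p = scores.shape[1]
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    means = {}
    for lv in levels:
        block = scores[groups == lv]
        m = block.mean(axis=0)
        means[lv] = m
        d = (m - grand)[:, None]
        H += block.shape[0] * (d @ d.T)
        r = block - m
        E += r.T @ r
    return H, E, means


def _pillai_f(V: float, p: int, q: int, n_e: int):
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    n_prime = (n_e - p - 1) / 2.0
    num_df = int(round(s * (2 * m + s + 1)))
    den_df = int(round(s * (2 * n_prime + s + 1)))
    denom = s - V
    if denom <= 0:
        f = np.inf
    else:
        f = (den_df / num_df) * V / denom
    p_value = float(sps.f.sf(f, num_df, den_df)) if np.isfinite(f) else 0.0
    return f, num_df, den_df, p_value


def _check_scores(scores, factor):
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    groups = np.asarray(factor)
    if scores.shape[0] != groups.shape[0]:
        raise ValueError("scores and factor labels differ in length")
    levels = sorted(pd.unique(groups).tolist())
    return scores, groups, levels


def manova_pillai(scores, factor, term: str = "") -> ManovaTable:
    """One-way MANOVA with Pillai's trace on PC scores.

    ``factor`` may be any grouping (including a composite cross-
    classification, in which case the cells act as the groups and the
    hypothesis df is #cells - 1).
    """
    scores, groups, levels = _check_scores(scores, factor)
    n, p = scores.shape
    g = len(levels)
    if g < 2:
        raise ValueError("MANOVA needs at least 2 groups")
    n_e = n - g
    if n_e < 1:
        raise ValueError("error degrees of freedom n - g must be >= 1")
    if p > n_e:
        raise ValueError(
            f"{p} response variables with only {n_e} error df: the within "
            "matrix is rank-deficient; use fewer PCs"
        )
    H, E, _ = _cross_products(scores, groups, levels)
    T = H + E
    try:
        V = float(np.trace(np.linalg.solve(T, H)))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular total cross-product matrix; use fewer PCs"
        ) from exc
    q = g - 1
    f, num_df, den_df, p_value = _pillai_f(V, p, q, n_e)
    return ManovaTable(
        term=term or "group", df=q, pillai=V, approx_f=f,
        num_df=num_df, den_df=den_df, p=p_value, n_pcs=p,
    )


def pairwise_manova(
    scores, factor, p_adjust: str = "bonferroni"
) -> list[ManovaTable]:
    """Pairwise single-df MANOVA contrasts against the pooled full-model error.

    Each unordered pair of groups is tested with q = 1; the error matrix E
    and its df ``n - g`` come from the full model with all g groups, so
    ``den Df`` is constant across pairs.  ``p_adjust`` is ``"bonferroni"``
    (multiply by the number of pairs, cap at 1 — the default) or ``"bh"``.
    """
    scores, groups, levels = _check_scores(scores, factor)
    n, p = scores.shape
    g = len(levels)
    if g < 2:
        raise ValueError("pairwise MANOVA needs at least 2 groups")
    n_e = n - g
    if p > n_e:
        raise ValueError(
            f"{p} response variables with only {n_e} error df; use fewer PCs"
        )
    _, E, means = _cross_products(scores, groups, levels)
    sizes = {lv: int(np.sum(groups == lv)) for lv in levels}
    tables = []
    for a, b in itertools.combinations(levels, 2):
        d = (means[a] - means[b])[:, None]
        w = sizes[a] * sizes[b] / (sizes[a] + sizes[b])
        Hp = w * (d @ d.T)
        V = float(np.trace(np.linalg.solve(Hp + E, Hp)))
        f, num_df, den_df, p_value = _pillai_f(V, p, 1, n_e)
        tables.append(
            ManovaTable(
                term=f"{a}—{b}", df=1, pillai=V, approx_f=f,
                num_df=num_df, den_df=den_df, p=p_value, n_pcs=p,
            )
        )
    raw = np.array([t.p for t in tables])
    if p_adjust == "bonferroni":
        adjusted = np.minimum(raw * len(raw), 1.0)
    elif p_adjust == "bh":
        adjusted = multipletests(raw, method="fdr_bh")[1]
    else:
        raise ValueError("p_adjust must be 'bonferroni' or 'bh'")
    for t, adj in zip(tables, adjusted):
        t.p_adjusted = float(adj)
    return tables
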