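"""Selection-bias-corrected over-representation analysis.

Detection in mass-spectrometry experiments favours abundant proteins, and
classification outcomes inherit that bias, so a naive hypergeometric test of
a selected protein set (e.g. the unclassified proteome) against functional
categories confounds biology with abundance.  The correction follows the
probability-weight-function approach: estimate P(selected | abundance) with a
monotone (isotonic) fit on log abundance, then approximate the null
distribution of a category's overlap by drawing selected-set-sized samples
without replacement with inclusion probability proportional to the fitted
weights.  The empirical p-value compares the observed overlap to that null;
Benjamini-Hochberg adjustment and a size filter (adjusted p < 0.01, >= 5
proteins by default) flag significant categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Pwf",
    "fit_pwf",
    "draw_null_sets",
    "category_test",
    "enrichment_analysis",
    "adjust_bh",
    "filter_significant",
    "detection_bias_check",
]


@dataclass
class Pwf:
    """Fitted probability weight function: P(selected | abundance) per protein."""

    weights: pd.Series  # accession -> weight in [0, 1]
    increasing: bool

    def __post_init__(self) -> None:
        w = self.weights.to_numpy()
        if w.min() < -1e-12 or w.max() > 1 + 1e-12:
            raise ValueError("PWF weights must lie in [0, 1]")


def fit_pwf(selected: pd.Series, abundance: pd.Series) -> Pwf:
    """Isotonic fit of selection probability against log abundance.

    ``selected`` is a boolean Series over the universe; ``abundance`` must be
    positive.  Proteins lacking abundance are excluded before calling.  The
    monotonicity direction is the sign of the Spearman correlation between
    abundance and selection.  The pool-adjacent-violators fit preserves the
    overall selection rate (fitted mean equals observed rate).
    """
    common = selected.index.intersection(abundance.index)
    if len(common) < 50:
        raise ValueError(f"need >= 50 proteins with abundance, got {len(common)}")
    sel = selected.loc[common].astype(float)
    ab = abundance.loc[common].astype(float)
    if (ab <= 0).any():
        raise ValueError("abundance values must be positive")
    rate = sel.mean()
    if rate in (0.0, 1.0):
        raise ValueError("degenerate selection: all or none selected")
    x = np.log(ab.to_numpy())
    y = sel.to_numpy()
    rho = stats.spearmanr(x, y).statistic
    increasing = bool(rho >= 0)
    iso = IsotonicRegression(increasing=increasing, y_min=0.0, y_max=1.0, out_of_bounds="clip")
    fitted = iso.fit_transform(x, y)
    return Pwf(weights=pd.Series(fitted, index=common), increasing=increasing)


def draw_null_sets(
    pwf: Pwf, n_selected: int, n_draws: int, seed: int, chunk: int = 256
) -> np.ndarray:
    """Boolean membership matrix (n_draws x universe) of weighted null sets.

    Each null set has ``n_selected`` proteins drawn without replacement with
    inclusion probability proportional to the PWF weights.  Pareto
    probability-proportional-to-size sampling is used: the target inclusion
    probabilities are the weights rescaled to sum to ``n_selected``, each
    protein gets the ranking variable ``Q = (U / (1-U)) / (lam / (1-lam))``
    with U uniform, and the ``n_selected`` smallest Q are taken.  This keeps
    realised inclusion frequencies essentially equal to the target
    probabilities even when the selected fraction is large, where sequential
    (successive-sampling) schemes distort them.  Vectorised in chunks.
    """
    w = pwf.weights.to_numpy(dtype=float)
    n = len(w)
    if not 0 < n_selected <= n:
        raise ValueError("n_selected must lie in (0, universe size]")
    lam = np.clip(w * n_selected / w.sum(), 1e-9, 1 - 1e-9)
    base = lam / (1.0 - lam)
    rng = np.random.default_rng(seed)
    member = np.zeros((n_draws, n), dtype=bool)
    for start in range(0, n_draws, chunk):
        m = min(chunk, n_draws - start)
        U = rng.uniform(size=(m, n))
        Q = (U / (1.0 - U)) / base
        topk = np.argpartition(Q, n_selected - 1, axis=1)[:, :n_selected]
        member[np.arange(start, start + m)[:, None], topk] = True
    return member


def category_test(
    category: set | list,
    selected: set | list,
    pwf: Pwf,
    n_null: int = 10_000,
    seed: int = 0,
    null_member: np.ndarray | None = None,
) -> dict:
    """Empirical over-representation p-value for one category.

    ``p = (1 + #{null overlap >= observed}) / (1 + n_null)`` — never zero.
    ``null_member`` lets callers reuse one set of null draws across many
    categories (the null does not depend on the category).
    """
    if n_null < 1000:
        raise ValueError("n_null must be >= 1000 for a stable empirical p")
    universe = pwf.weights.index
    category = [a for a in category if a in universe]
    if not category:
        raise ValueError("category is empty (or disjoint from the universe)")
    selected = set(selected) & set(universe)
    observed = len(selected & set(category))
    if null_member is None:
        null_member = draw_null_sets(pwf, len(selected), n_null, seed)
    cat_idx = universe.get_indexer(pd.Index(category))
    null_overlap = null_member[:, cat_idx].sum(axis=1)
    n_draws = null_member.shape[0]
    p = (1 + int(np.sum(null_overlap >= observed))) / (1 + n_draws)
    return {
        "size": len(category),
        "observed": observed,
        "expected": float(null_overlap.mean()),
        "p": p,
    }


def enrichment_analysis(
    categories: dict[str, list],
    selected,
    pwf: Pwf,
    n_null: int = 10_000,
    seed: int = 0,
    alpha: float = 0.01,
    min_size: int = 5,
) -> pd.DataFrame:
    """PWF-corrected over-representation test of many categories.

    One weighted null ensemble is drawn and shared by all categories; BH
    adjustment and the significance filter are applied to the results.
    """
    selected = set(selected) & set(pwf.weights.index)
    null_member = draw_null_sets(pwf, len(selected), n_null, seed)
    rows = {}
    for name, members in categories.items():
        rows[name] = category_test(
            members, selected, pwf, n_null=n_null, seed=seed, null_member=null_member
        )
    result = pd.DataFrame(rows).T
    result.index.name = "category"
    result["adj_p"] = adjust_bh(result["p"].to_numpy())
    return filter_significant(result, alpha=alpha, min_size=min_size)


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_significant(
    results: pd.DataFrame, alpha: float = 0.01, min_size: int = 5
) -> pd.DataFrame:
    """Flag categories with adjusted p strictly below alpha and enough members."""
    out = results.copy()
    out["significant"] = (out["adj_p"] < alpha) & (out["size"] >= min_size)
    return out


def detection_bias_check(detected: pd.Series, abundance: pd.Series, n_bins: int = 10) -> dict:
    """Rank correlation between abundance and detection, plus a binned rate table.

    Confirms (or refutes) that more abundant proteins are more likely to be
    detected.  With constant detection the correlation is undefined and
    reported as NaN.
    """
    common = detected.index.intersection(abundance.index)
    det = detected.loc[common].astype(float)
    ab = abundance.loc[common].astype(float)
    if det.nunique() < 2:
        rho, pval = np.nan, np.nan
    else:
        res = stats.spearmanr(ab, det)
        rho, pval = float(res.statistic), float(res.pvalue)
    bins = pd.qcut(np.log(ab), q=n_bins, duplicates="drop")
    table = det.groupby(bins, observed=True).agg(["mean", "size"])
    table.columns = ["detection_rate", "n"]
    return {"spearman_rho": rho, "p_value": pval, "binned_rates": table}
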