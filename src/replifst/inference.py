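"""Statistical machinery: correlations, resampling null, contingency tests,
median split and forward stepwise regression.

These are the building blocks the full analysis orchestrates: Spearman
correlations between gene FST and the discordance index phi; a
gene-resampling test comparing disease-gene mean FST with genome-wide
background sets; the median split of associations by replicability; the
Yates-corrected chi-square on ancestral/derived major-allele counts; and a
forward stepwise OLS with probability-of-F entry/removal reporting
standardized coefficients and tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

__all__ = [
    "spearman_correlation",
    "ResamplingResult",
    "resampling_mean_fst_test",
    "median_split",
    "derived_allele_test",
    "StepwiseModel",
    "forward_stepwise",
    "mann_whitney",
]


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rho with its t-approximation p-value (ties -> average ranks).

    Requires at least 4 paired observations; pairs with a missing value are
    dropped first.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError(f"need >= 4 complete pairs, got {x.size}")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass(frozen=True)
class ResamplingResult:
    """Empirical p-value from a gene-resampling null.

    ``k`` of ``n_resamples`` random gene sets had a mean FST as or more
    extreme than the observed set (in the stated tail).  ``p`` is k/N;
    when k = 0 the resolution of the test is exhausted and the honest
    report is the bound "< 1/N" (``is_bound`` is then True and ``p`` is 0).
    """

    k: int
    n_resamples: int
    tail: str
    observed: float
    null_mean: float

    @property
    def p(self) -> float:
        return self.k / self.n_resamples

    @property
    def is_bound(self) -> bool:
        return self.k == 0

    def __str__(self) -> str:
        if self.is_bound:
            return f"< {1.0 / self.n_resamples:g}"
        return f"{self.p:g}"


def resampling_mean_fst_test(
    observed_mean: float,
    pool: np.ndarray,
    set_size: int,
    n_resamples: int = 10_000,
    seed: int | np.random.Generator = 0,
    tail: str = "lower",
    chunk: int = 2_000,
) -> ResamplingResult:
    """Compare an observed gene-set mean FST against random genome sets.

    Draws ``n_resamples`` sets of ``set_size`` genes without replacement
    from ``pool`` (per-gene mean FST values of the genome-wide background)
    and counts how many have a mean as or more extreme than
    ``observed_mean``: ``tail="lower"`` counts means <= observed,
    ``"upper"`` counts means >= observed.
    """
    pool = np.asarray(pool, float)
    pool = pool[~np.isnan(pool)]
    if set_size > pool.size:
        raise ValueError(f"set_size {set_size} exceeds pool of {pool.size} genes")
    if tail not in ("lower", "upper"):
        raise ValueError("tail must be 'lower' or 'upper'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    k = 0
    done = 0
    while done < n_resamples:
        c = min(chunk, n_resamples - done)
        # c independent draws without replacement: argpartition of random keys
        keys = rng.random((c, pool.size))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        means = pool[idx].mean(axis=1)
        if tail == "lower":
            k += int((means <= observed_mean).sum())
        else:
            k += int((means >= observed_mean).sum())
        done += c
    return ResamplingResult(
        k=k,
        n_resamples=n_resamples,
        tail=tail,
        observed=float(observed_mean),
        null_mean=float(pool.mean()),
    )


def median_split(
    summaries: pd.DataFrame, column: str = "replicability_pct"
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Split associations at the median replicability, ties in BOTH strata.

    Returns ``(low, high, median)`` where low holds values <= median and
    high values >= median; an association exactly at the median appears in
    both, so the strata need not partition the input.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 associations to split")
    med = float(np.median(summaries[column]))
    low = summaries[summaries[column] <= med].reset_index(drop=True)
    high = summaries[summaries[column] >= med].reset_index(drop=True)
    return low, high, med


def derived_allele_test(table) -> tuple[float, float]:
    """Yates-corrected chi-square on a 2x2 (stratum x ANC/DER) count table.

    Returns ``(chi2, p)`` with 1 df, two-sided.  The continuity correction
    matches the convention used for this test throughout the analysis.
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    res = stats.chi2_contingency(t, correction=True)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U via the tie-corrected normal approximation."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# forward stepwise regression


@dataclass
class StepwiseModel:
    """Result of a forward stepwise OLS.

    ``predictors`` in order of entry; ``betas`` are standardized
    coefficients (fit on z-scored predictors and response); ``tolerances``
    are 1 - R^2 of each selected predictor on the other selected ones
    (1.0 for a single-predictor model); ``f_value`` and ``f_df`` describe
    the overall model F against the intercept-only model.
    """

    predictors: list[str] = field(default_factory=list)
    betas: dict[str, float] = field(default_factory=dict)
    pvalues: dict[str, float] = field(default_factory=dict)
    tolerances: dict[str, float] = field(default_factory=dict)
    f_value: float = float("nan")
    f_pvalue: float = float("nan")
    f_df: tuple[int, int] = (0, 0)
    r2: float = float("nan")
    adj_r2: float = float("nan")
    n: int = 0

    @property
    def empty(self) -> bool:
        return not self.predictors

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": self.predictors,
                "beta": [self.betas[p] for p in self.predictors],
                "p_value": [self.pvalues[p] for p in self.predictors],
                "tolerance": [self.tolerances[p] for p in self.predictors],
            }
        )


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(ddof=1, axis=0)
    if np.any(sd == 0):
        raise ValueError("constant column cannot be standardized")
    return (a - a.mean(axis=0)) / sd


def forward_stepwise(
    X: pd.DataFrame,
    y,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_steps: int = 100,
) -> StepwiseModel:
    """Forward stepwise OLS with probability-of-F entry and removal.

    At each step the candidate whose partial-F p-value (equivalently the
    two-sided t-test of its coefficient in the augmented model) is smallest
    and below ``p_enter`` is added; after every addition any included
    predictor whose p-value rose above ``p_remove`` is dropped (worst
    first).  Predictors and response are z-scored before fitting, so the
    reported coefficients are standardized betas.

    Requires ``n > n_candidates + 2`` rows.  Returns an empty model (with a
    warning via logging) when no candidate passes ``p_enter``.
    """
    y = np.asarray(y, float)
    if len(X) != y.size:
        raise ValueError("X and y disagree in length")
    if len(X) <= X.shape[1] + 2:
        raise ValueError("need n rows > number of candidates + 2")
    cols = list(X.columns)
    Z = pd.DataFrame(_zscore(X.to_numpy(float)), columns=cols)
    yz = _zscore(y)

    def _fit(included: list[str]):
        return sm.OLS(yz, sm.add_constant(Z[included])).fit()

    included: list[str] = []
    for _ in range(max_steps):
        remaining = [c for c in cols if c not in included]
        best, best_p = None, p_enter
        for cand in remaining:
            p = _fit(included + [cand]).pvalues[cand]
            if p < best_p:
                best, best_p = cand, p
        if best is None:
            break
        included.append(best)
        # backward purge
        while len(included) > 1:
            pv = _fit(included).pvalues.drop("const")
            worst = pv.idxmax()
            if pv[worst] > p_remove:
                included.remove(worst)
            else:
                break

    model = StepwiseModel(n=len(X))
    if not included:
        import logging

        logging.getLogger(__name__).warning(
            "forward stepwise: no candidate passed p_enter=%g", p_enter
        )
        return model

    fit = _fit(included)
    model.predictors = included
    model.betas = {c: float(fit.params[c]) for c in included}
    model.pvalues = {c: float(fit.pvalues[c]) for c in included}
    for c in included:
        others = [o for o in included if o != c]
        if not others:
            model.tolerances[c] = 1.0
        else:
            aux = sm.OLS(Z[c].to_numpy(), sm.add_constant(Z[others])).fit()
            model.tolerances[c] = float(1.0 - aux.rsquared)
    model.f_value = float(fit.fvalue)
    model.f_pvalue = float(fit.f_pvalue)
    model.f_df = (int(fit.df_model), int(fit.df_resid))
    model.r2 = float(fit.rsquared)
    model.adj_r2 = float(fit.rsquared_adj)
    return model
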