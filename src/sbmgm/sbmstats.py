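"""Group and biomarker statistics on ICA loading coefficients.

Mirrors the statistical layer of a two-group source-based morphometry
study: loadings are standardized per component, groups are compared with
pooled-variance two-tailed t-tests under Bonferroni control, effect sizes
are absolute pooled-SD Cohen's d, and a biomarker covariate (serum
cortisol, nmol/L) is related to the loadings by Spearman rank correlation
within each group.  Every test is also computable from printed summary
statistics (means, SDs, counts), so published tables can be recomputed
without subject-level data.

Notes on two deliberate conventions: the loading "Z-score" transform is
plain column standardization by default (an ``atanh`` variant is provided
behind a flag, but loadings are not correlations and routinely exceed 1 in
magnitude, and published group summaries like 0.43 +/- 0.54 are consistent
with plain z-scoring); and the t-test pools variances because the printed
Cohen's d values are exactly the pooled-SD ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateSourceError, InsufficientDataError


@dataclass
class ComponentStats:
    """One row of a group-comparison table (per component)."""

    component_id: int
    mean_hs: float
    sd_hs: float
    mean_mdd: float
    sd_mdd: float
    n_hs: int
    n_mdd: int
    t_value: float
    df: int
    p_two_tailed: float
    cohens_d: float
    bonferroni_m: int
    significant_after_bonferroni: bool


@dataclass
class CorrStats:
    """Spearman correlation of one component's loadings with a covariate."""

    component_id: int
    group: str
    rho: float
    p_raw: float
    p_adjusted: float
    n: int


def standardize_loadings(mixing: np.ndarray, mode: str = "zscore") -> np.ndarray:
    """Column-wise standardization of the mixing matrix.

    mode="zscore": center and scale each column to unit SD (default).
    mode="atanh": rescale columns to max |value| just below 1, apply the
    inverse hyperbolic tangent, then z-score — a Fisher-style variant for
    users who want the variance-stabilizing curve.  Both are monotone per
    column, so rank-based statistics are identical between modes.
    """
    x = np.asarray(mixing, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        if mode == "atanh":
            peak = np.abs(col).max()
            if peak == 0:
                raise DegenerateSourceError(f"component {j} has zero variance")
            col = np.arctanh(col / peak * (1.0 - 1e-6))
        sd = col.std(ddof=0)
        if sd == 0:
            raise DegenerateSourceError(
                f"component {j} has zero loading variance"
            )
        out[:, j] = (col - col.mean()) / sd
    return out


def summary_ttest(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float, float]:
    """Pooled-variance two-sample t-test from printed summaries.

    Returns ``(t, df, p_two_tailed, cohens_d)`` with
    ``d = |mean1 - mean2| / pooled SD`` and
    ``pooled SD = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2))``.
    """
    if min(n1, n2) < 2:
        raise InsufficientDataError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise InsufficientDataError("standard deviations must be >= 0")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    pooled_sd = math.sqrt(pooled_var)
    se = pooled_sd * math.sqrt(1.0 / n1 + 1.0 / n2)
    diff = mean1 - mean2
    if se == 0:
        t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    else:
        t = diff / se
    p = float(2.0 * stats.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
    if diff == 0:
        p = 1.0
    d = abs(diff) / pooled_sd if pooled_sd > 0 else 0.0
    return float(t), int(df), p, float(d)


def compare_groups(
    loadings_z: np.ndarray,
    groups: np.ndarray | pd.Series,
    alpha: float = 0.05,
    m: int | None = None,
    component_ids: list[int] | None = None,
    group_order: tuple[str, str] = ("HS", "MDD"),
) -> list[ComponentStats]:
    """Per-component two-tailed pooled-variance t-test with Bonferroni flag.

    ``m`` defaults to the number of components tested; significance means
    ``p < alpha / m``.
    """
    x = np.asarray(loadings_z, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    groups = np.asarray(groups)
    g1, g2 = group_order
    idx1, idx2 = groups == g1, groups == g2
    if idx1.sum() < 2 or idx2.sum() < 2:
        raise InsufficientDataError(
            f"both groups need n >= 2 (got {int(idx1.sum())} {g1}, "
            f"{int(idx2.sum())} {g2})"
        )
    n_comp = x.shape[1]
    m_eff = int(m) if m is not None else n_comp
    if m_eff < 1:
        raise InsufficientDataError("Bonferroni m must be >= 1")
    ids = component_ids if component_ids is not None else list(range(n_comp))
    out = []
    for j in range(n_comp):
        a, b = x[idx1, j], x[idx2, j]
        t, df, p, d = summary_ttest(
            a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
        )
        out.append(
            ComponentStats(
                component_id=ids[j],
                mean_hs=float(a.mean()),
                sd_hs=float(a.std(ddof=1)),
                mean_mdd=float(b.mean()),
                sd_mdd=float(b.std(ddof=1)),
                n_hs=int(a.size),
                n_mdd=int(b.size),
                t_value=t,
                df=df,
                p_two_tailed=p,
                cohens_d=d,
                bonferroni_m=m_eff,
                significant_after_bonferroni=bool(p < alpha / m_eff),
            )
        )
    return out


def spearman_with_covariate(
    loadings_z: np.ndarray,
    covariate: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    m: int = 2,
    component_ids: list[int] | None = None,
) -> list[CorrStats]:
    """Spearman rho of each component's loadings with the covariate, per
    group, with Bonferroni-adjusted p (``p_adj = min(1, m * p)``).

    p-values use the t-approximation
    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` with average-rank ties, as
    implemented by :func:`scipy.stats.spearmanr`.
    """
    x = np.asarray(loadings_z, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    cov = np.asarray(covariate, dtype=float)
    if not np.all(np.isfinite(cov)):
        raise DegenerateSourceError("covariate contains non-finite values")
    groups = np.asarray(groups)
    ids = component_ids if component_ids is not None else list(range(x.shape[1]))
    out = []
    for g in pd.unique(groups):
        sel = groups == g
        n = int(sel.sum())
        if n < 4:
            raise InsufficientDataError(
                f"group {g!r} has n={n} < 4; Spearman correlation unstable"
            )
        if np.ptp(cov[sel]) == 0:
            raise DegenerateSourceError(
                f"covariate is constant within group {g!r}"
            )
        for j in range(x.shape[1]):
            res = stats.spearmanr(x[sel, j], cov[sel])
            rho, p = float(res.statistic), float(res.pvalue)
            out.append(
                CorrStats(
                    component_id=ids[j],
                    group=str(g),
                    rho=rho,
                    p_raw=p,
                    p_adjusted=min(1.0, m * p),
                    n=n,
                )
            )
    return out


def sex_chi2_from_counts(table: np.ndarray) -> tuple[float, float]:
    """Yates-corrected chi-square on a 2x2 sex-by-group table -> (chi2, p)."""
    res = stats.chi2_contingency(np.asarray(table), correction=True)
    return float(res.statistic), float(res.pvalue)


def demographics_tests(subject_table: pd.DataFrame) -> dict:
    """Table-1-style demographics comparison of the two groups.

    Age: pooled two-sample t-test.  Cortisol: two-sided Mann-Whitney U,
    tie-corrected normal approximation.  Sex: 2x2 chi-square with Yates
    continuity correction.
    """
    for col in ("group", "age", "sex", "cortisol_nmol_l"):
        if col not in subject_table.columns:
            raise InsufficientDataError(f"subject table lacks column {col!r}")
    groups = subject_table["group"].unique()
    if len(groups) != 2:
        raise InsufficientDataError("expected exactly 2 groups")
    g1, g2 = sorted(groups)
    a = subject_table[subject_table["group"] == g1]
    b = subject_table[subject_table["group"] == g2]
    if a.empty or b.empty:
        raise InsufficientDataError("a group is empty")

    t, df, p_age, _ = summary_ttest(
        a["age"].mean(), a["age"].std(ddof=1), len(a),
        b["age"].mean(), b["age"].std(ddof=1), len(b),
    )
    mwu = stats.mannwhitneyu(
        a["cortisol_nmol_l"], b["cortisol_nmol_l"],
        alternative="two-sided", method="asymptotic",
    )
    sex_counts = np.array(
        [
            [(a["sex"] == "M").sum(), (a["sex"] == "F").sum()],
            [(b["sex"] == "M").sum(), (b["sex"] == "F").sum()],
        ]
    )
    chi2, p_sex = sex_chi2_from_counts(sex_counts)
    return {
        "groups": (str(g1), str(g2)),
        "n": (len(a), len(b)),
        "age": {
            "mean": (float(a["age"].mean()), float(b["age"].mean())),
            "sd": (float(a["age"].std(ddof=1)), float(b["age"].std(ddof=1))),
            "t": t, "df": df, "p": p_age,
        },
        "cortisol_nmol_l": {
            "mean": (
                float(a["cortisol_nmol_l"].mean()),
                float(b["cortisol_nmol_l"].mean()),
            ),
            "sd": (
                float(a["cortisol_nmol_l"].std(ddof=1)),
                float(b["cortisol_nmol_l"].std(ddof=1)),
            ),
            "u": float(mwu.statistic), "p": float(mwu.pvalue),
        },
        "sex": {
            "counts_m_f": sex_counts.tolist(),
            "chi2": chi2, "p": p_sex,
        },
    }


def stats_table(results: list[ComponentStats]) -> pd.DataFrame:
    """Group-comparison results as a tidy table (TSV-ready)."""
    return pd.DataFrame(
        {
            "component": [r.component_id for r in results],
            "mean_hs": [r.mean_hs for r in results],
            "sd_hs": [r.sd_hs for r in results],
            "mean_mdd": [r.mean_mdd for r in results],
            "sd_mdd": [r.sd_mdd for r in results],
            "t": [r.t_value for r in results],
            "df": [r.df for r in results],
            "p_two_tailed": [r.p_two_tailed for r in results],
            "cohens_d": [r.cohens_d for r in results],
            "bonferroni_m": [r.bonferroni_m for r in results],
            "significant": [r.significant_after_bonferroni for r in results],
        }
    )


def corr_table(results: list[CorrStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "component": [r.component_id for r in results],
            "group": [r.group for r in results],
            "rho": [r.rho for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "n": [r.n for r in results],
        }
    )
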