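"""Demographic/clinical group comparisons for the cohort table.

Continuous variables are screened for normality with a one-sample
Kolmogorov-Smirnov test, then compared with a Welch two-sample t-test
(normal) or a tie-corrected Mann-Whitney U (non-normal); gender uses a
Pearson chi-square without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import CLINICAL_COLUMNS


@dataclass(frozen=True)
class GroupSummary:
    """n, mean and sample SD (n-1 denominator) of one group's variable."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def ks_normality(values: np.ndarray) -> tuple[float, float]:
    """One-sample KS statistic of ``values`` against N(mean, sd) of the sample.

    The reference normal uses the sample's own mean and SD. Note the p-value
    does not correct for parameter estimation (Lilliefors), matching common
    screening practice; it is conservative for near-normal data.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 5:
        raise ValueError("KS normality screen needs n >= 5")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant input: KS against a fitted normal is undefined")
    res = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(res.statistic), float(res.pvalue)


def welch_t_from_summaries(a: GroupSummary, b: GroupSummary) -> tuple[float, float, float]:
    """Welch t and Welch-Satterthwaite df from group summaries.

    t = (mean_a - mean_b) / sqrt(sd_a^2/n_a + sd_b^2/n_b). Returns (t, df, p)
    with a two-sided p.
    """
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    if va + vb == 0:
        raise ValueError("both groups have zero variance")
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def pooled_t_from_summaries(a: GroupSummary, b: GroupSummary) -> tuple[float, float, float]:
    """Student (pooled-variance) two-sample t from summaries; returns (t, df, p)."""
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if sp2 == 0:
        raise ValueError("both groups have zero variance")
    t = (a.mean - b.mean) / np.sqrt(sp2 * (1 / a.n + 1 / b.n))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (1 df, no Yates continuity correction) for a 2x2 table."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("all marginals must be positive")
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), float(p)


def mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Mann-Whitney U with tie-corrected normal approximation.

    Returns (U_a, Z, p). U_a counts pairs where group a precedes group b
    (plus half-ties). Z is positive when group a's rank sum exceeds its null
    expectation; p is the two-sided normal approximation.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    u_a = float(stats.mannwhitneyu(x, y, alternative="two-sided").statistic)
    # tie-corrected variance of U
    combined = np.concatenate([x, y])
    _, tie_counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    mu_u = n1 * n2 / 2.0
    if var_u == 0:
        z = 0.0
    else:
        z = (u_a - mu_u) / np.sqrt(var_u)
    p = 2 * stats.norm.sf(abs(z)) if var_u > 0 else 1.0
    return u_a, float(z), float(p)


def summarize_group(values: np.ndarray) -> GroupSummary:
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    return GroupSummary(n=int(x.size), mean=float(x.mean()), sd=float(x.std(ddof=1)))


def demographic_table(cohort: pd.DataFrame, alpha_normal: float = 0.05) -> pd.DataFrame:
    """Table-1-style group comparison of demographics and clinical scores.

    Each continuous variable is KS-screened in the pooled sample: normal
    variables get a Welch t, non-normal ones a Mann-Whitney Z. Gender gets
    the 2x2 chi-square.
    """
    cs = cohort[cohort["group"] == "CS"]
    nc = cohort[cohort["group"] == "NC"]
    rows = []
    for var in ("age", "tiv", *CLINICAL_COLUMNS):
        if var not in cohort.columns:
            continue
        x = cs[var].to_numpy(dtype=float)
        y = nc[var].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        y = y[np.isfinite(y)]
        if x.size < 2 or y.size < 2:
            continue
        pooled = np.concatenate([x, y])
        try:
            _, p_ks = ks_normality(pooled)
        except ValueError:
            p_ks = 0.0
        if p_ks > alpha_normal:
            t, _, p = welch_t_from_summaries(summarize_group(x), summarize_group(y))
            stat_name, stat = "t", t
        else:
            _, z, p = mann_whitney(x, y)
            stat_name, stat = "Z", z
        rows.append(
            {
                "variable": var,
                "cs_mean": x.mean(),
                "cs_sd": x.std(ddof=1),
                "nc_mean": y.mean(),
                "nc_sd": y.std(ddof=1),
                "statistic_name": stat_name,
                "statistic": stat,
                "p_value": p,
            }
        )
    # gender 2x2
    tab = np.array(
        [
            [(cs["gender"] == "male").sum(), (cs["gender"] == "female").sum()],
            [(nc["gender"] == "male").sum(), (nc["gender"] == "female").sum()],
        ]
    )
    chi2, p = chi_square_2x2(tab)
    rows.append(
        {
            "variable": "gender",
            "cs_mean": np.nan,
            "cs_sd": np.nan,
            "nc_mean": np.nan,
            "nc_sd": np.nan,
            "statistic_name": "chi2",
            "statistic": chi2,
            "p_value": p,
        }
    )
    return pd.DataFrame(rows)
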