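"""Statistical procedures: Pearson correlations (per band and per
frequency), paired t tests, Bonferroni correction, and the matched-pairs
noncentral-t sample-size search.

All two-sample comparisons in this study are within-subject (eyes open
vs eyes closed, or month vs month on the overlapping participants), so
the paired t test is the workhorse; correlations against the PSQI are
plain product-moment correlations with Fisher-z confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA_LEVEL = 0.05


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    ci95: tuple[float, float]
    feature: str = ""
    grouping: str = ""

    def __post_init__(self) -> None:
        if not -1 <= self.r <= 1:
            raise ValueError("r outside [-1, 1]")
        if not 0 <= self.p <= 1:
            raise ValueError("p outside [0, 1]")
        if self.n < 3:
            raise ValueError("need n >= 3")

    @property
    def significant(self) -> bool:
        return self.p < ALPHA_LEVEL


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    n: int

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if not 0 <= self.p <= 1:
            raise ValueError("p outside [0, 1]")


def pearson(x, y, feature: str = "", grouping: str = "") -> CorrelationResult:
    """Pearson r with two-sided p and Fisher-z 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    res = sps.pearsonr(x, y)
    ci = res.confidence_interval(0.95)
    return CorrelationResult(
        r=float(res.statistic), p=float(res.pvalue), n=n,
        ci95=(float(ci.low), float(ci.high)), feature=feature, grouping=grouping,
    )


def paired_t(a, b) -> PairedTestResult:
    """Two-sided paired t test of a vs b (positive t means a > b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D and of equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.allclose(d, 0):
            return PairedTestResult(t=0.0, df=len(a) - 1, p=1.0,
                                    mean_diff=0.0, n=len(a))
        raise ValueError("zero difference variance")
    res = sps.ttest_rel(a, b)
    return PairedTestResult(
        t=float(res.statistic), df=len(a) - 1, p=float(res.pvalue),
        mean_diff=float(d.mean()), n=len(a),
    )


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, m*p)."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("m must be >= number of tests")
    return np.minimum(1.0, m * p)


def sample_size_matched_pairs(
    dz: float, alpha: float = 0.05, power: float = 0.95, tails: int = 1
) -> int:
    """Smallest n with matched-pairs t-test power >= target.

    Power at sample size n is computed from the noncentral t
    distribution with df = n−1 and noncentrality dz·√n against the
    central-t critical value; for two tails both rejection regions
    count. The search iterates n upward from 2 (power is monotone in n).
    """
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    if dz <= 0:
        raise ValueError("effect size dz must be positive")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    n = 2
    while True:
        if _matched_pairs_power(n, dz, alpha, tails) >= power:
            return n
        n += 1
        if n > 10**6:  # pragma: no cover - unreachable for valid inputs
            raise RuntimeError("sample-size search did not terminate")


def _matched_pairs_power(n: int, dz: float, alpha: float, tails: int) -> float:
    df = n - 1
    ncp = dz * np.sqrt(n)
    if tails == 1:
        t_crit = sps.t.ppf(1 - alpha, df)
        return float(sps.nct.sf(t_crit, df, ncp))
    t_crit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(t_crit, df, ncp) + sps.nct.cdf(-t_crit, df, ncp))


def correlation_spectrum(
    bin_powers: pd.DataFrame,
    psqi_totals: pd.Series,
) -> pd.DataFrame:
    """Per-frequency-bin correlations with the PSQI total.

    Parameters
    ----------
    bin_powers : DataFrame
        One row per recording; index (participant, month, condition) or
        columns for them; one column per frequency-bin center (float
        column labels, Hz) holding relative power.
    psqi_totals : Series
        Indexed by (participant, month).

    Returns a tidy frame with one row per (grouping, bin): columns
    condition, grouping, freq_hz, r, p, n, significant — per-month
    groupings, the pooled grouping, and the across-month mean-r rows
    (mean of the three monthly r values; its significance flag tests the
    pooled sample).
    """
    rows = []
    bin_cols = [c for c in bin_powers.columns if isinstance(c, float)]
    for cond, sub in bin_powers.groupby("condition"):
        psqi = np.array([
            psqi_totals.loc[(p, m)]
            for p, m in zip(sub["participant"], sub["month"])
        ], dtype=float)
        month_r: dict[float, list[float]] = {c: [] for c in bin_cols}
        for month, msub in sub.groupby("month"):
            mp = np.array([
                psqi_totals.loc[(p, month)] for p in msub["participant"]
            ], dtype=float)
            for c in bin_cols:
                res = pearson(msub[c].to_numpy(), mp)
                month_r[c].append(res.r)
                rows.append(dict(condition=cond, grouping=f"month{month}",
                                 freq_hz=c, r=res.r, p=res.p, n=res.n,
                                 significant=res.significant))
        for c in bin_cols:
            res = pearson(sub[c].to_numpy(), psqi)
            rows.append(dict(condition=cond, grouping="pooled", freq_hz=c,
                             r=res.r, p=res.p, n=res.n,
                             significant=res.significant))
            rows.append(dict(condition=cond, grouping="month_mean", freq_hz=c,
                             r=float(np.mean(month_r[c])), p=res.p, n=res.n,
                             significant=res.significant))
    return pd.DataFrame(rows)


def band_correlations(
    band_powers: pd.DataFrame,
    psqi_totals: pd.Series,
    complete_participants: list[str] | None = None,
) -> pd.DataFrame:
    """Band-power vs PSQI correlations over all requested groupings.

    ``band_powers`` is tidy: columns participant, month, condition,
    band, component, rel_power. Groupings are the cross product of
    {month1..3, pooled} × condition × {all, complete}; the complete
    subgroup restricts to participants present in all three months.
    """
    rows = []
    subsets = {"all": None, "complete": complete_participants}
    for subset_name, keep in subsets.items():
        df = band_powers
        if keep is not None:
            df = df[df["participant"].isin(keep)]
        for (cond, band, comp), sub in df.groupby(["condition", "band", "component"]):
            groups: list[tuple[str, pd.DataFrame]] = [("pooled", sub)]
            groups += [(f"month{m}", g) for m, g in sub.groupby("month")]
            for gname, g in groups:
                if len(g) < 3:
                    continue
                psqi = np.array([
                    psqi_totals.loc[(p, m)]
                    for p, m in zip(g["participant"], g["month"])
                ], dtype=float)
                res = pearson(g["rel_power"].to_numpy(), psqi,
                              feature=f"{band}:{comp}", grouping=gname)
                rows.append(dict(subset=subset_name, condition=cond, band=band,
                                 component=comp, grouping=gname, r=res.r,
                                 p=res.p, n=res.n, ci_lo=res.ci95[0],
                                 ci_hi=res.ci95[1],
                                 significant=res.significant))
    return pd.DataFrame(rows)
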