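"""ROI responses, laterality indices and group statistics.

The laterality index is LI = (L − R)/(L + R) over the homologous ROI means;
positive values indicate left-hemisphere dominance. Channelwise activation
is a one-sample t map with Benjamini–Hochberg FDR control across channels.
Group inference uses paired/one-sample t-tests, a two-way repeated-measures
ANOVA (hemisphere × deviation) with Tukey-HSD post-hoc contrasts on the
interaction error term, Pearson correlation of the two tasks' laterality
indices (with regression-diagnostic outlier exclusion), a two-sample
Kolmogorov–Smirnov comparison of the LI distributions, and the
noncentral-t sample-size computation for the paired design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatTestResult", "ActivationMap", "roi_mean", "laterality_index",
    "channel_t_map", "bh_fdr", "t_test", "rm_anova2",
    "pearson_li_correlation", "ks_two_sample", "required_n_paired_t",
    "separation_inconsistency_cm",
]

LI_EPS = 1e-12


@dataclass
class StatTestResult:
    test: str
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    effect: dict = field(default_factory=dict)
    post_hoc: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {"test": self.test, "statistic": self.statistic, "df": self.df,
             "p_value": self.p_value, "effect": self.effect}
        if self.post_hoc is not None:
            d["post_hoc"] = self.post_hoc.to_dict(orient="records")
        return d


@dataclass
class ActivationMap:
    table: pd.DataFrame  # channel_id, t, p, significant

    @property
    def significant_channels(self) -> list[int]:
        return list(self.table.loc[self.table["significant"], "channel_id"])


# ---------------------------------------------------------------------------
# ROI response and laterality

def roi_mean(responses: pd.Series | dict[int, float], roi_channels) -> float:
    """Arithmetic mean of the per-channel responses over retained ROI
    channels; raises when every ROI channel was pruned."""
    if isinstance(responses, dict):
        responses = pd.Series(responses)
    present = [c for c in roi_channels if c in responses.index]
    if not present:
        raise ValueError("no retained channels in the ROI")
    return float(responses.loc[present].mean())


def laterality_index(L: float, R: float, eps: float = LI_EPS) -> float:
    """LI = (L − R)/(L + R); raises when |L + R| < eps (undefined)."""
    if abs(L + R) < eps:
        raise ValueError(f"laterality index undefined: |L+R| = {abs(L + R)} < {eps}")
    return (L - R) / (L + R)


# ---------------------------------------------------------------------------
# channelwise activation map

def channel_t_map(responses: pd.DataFrame, q: float = 0.05) -> ActivationMap:
    """One-sample t vs 0 per channel across subjects, BH-FDR at level q.

    ``responses``: rows = subjects, columns = channel ids. Zero-variance
    channels are recorded with infinite |t| and p = 0 flagged.
    """
    rows = []
    for cid in responses.columns:
        x = responses[cid].dropna().to_numpy(dtype=float)
        if len(x) < 3:
            # pruned in too many subjects to test
            rows.append({"channel_id": cid, "t": np.nan, "p": np.nan,
                         "n": len(x), "degenerate": True})
            continue
        if np.allclose(x.std(ddof=1), 0.0):
            if np.allclose(x.mean(), 0.0):
                rows.append({"channel_id": cid, "t": np.nan, "p": np.nan,
                             "n": len(x), "degenerate": True})
            else:
                rows.append({"channel_id": cid,
                             "t": np.inf * np.sign(x.mean()), "p": 0.0,
                             "n": len(x), "degenerate": True})
            continue
        t, p = sps.ttest_1samp(x, 0.0)
        rows.append({"channel_id": cid, "t": float(t), "p": float(p),
                     "n": len(x), "degenerate": False})
    table = pd.DataFrame(rows)
    valid = table["p"].notna()
    sig = np.zeros(len(table), dtype=bool)
    if valid.any():
        sig[valid.to_numpy()] = bh_fdr(table.loc[valid, "p"].to_numpy(), q=q)
    table["significant"] = sig
    return ActivationMap(table)


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up significance mask at FDR level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


# ---------------------------------------------------------------------------
# t-tests

def t_test(x, y=None, *, null_mean: float = 0.0, paired: bool = False) -> StatTestResult:
    """One-sample (vs ``null_mean``), paired, or two-sample t-test."""
    x = np.asarray(x, dtype=float)
    if paired or y is None:
        if paired:
            y = np.asarray(y, dtype=float)
            if x.shape != y.shape:
                raise ValueError("paired samples must have equal length")
            d = x - y
            name = "paired t-test"
        else:
            d = x - null_mean
            name = "one-sample t-test"
        n = len(d)
        if n < 3:
            raise ValueError("need n >= 3")
        sd = d.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance (of differences); t undefined")
        t = d.mean() / (sd / np.sqrt(n))
        df = n - 1
        p = 2.0 * sps.t.sf(abs(t), df)
        dz = d.mean() / sd
        return StatTestResult(name, float(t), df, float(p),
                              {"mean_diff": float(d.mean()), "cohen_dz": float(dz),
                               "n": n})
    y = np.asarray(y, dtype=float)
    t, p = sps.ttest_ind(x, y)
    return StatTestResult("two-sample t-test", float(t), len(x) + len(y) - 2,
                          float(p), {"n1": len(x), "n2": len(y)})


# ---------------------------------------------------------------------------
# two-way repeated-measures ANOVA with Tukey HSD post-hoc

def rm_anova2(data: pd.DataFrame, dv: str, within: tuple[str, str],
              subject: str, tukey: bool = True) -> dict[str, StatTestResult]:
    """Two-way fully-crossed within-subject ANOVA.

    Each effect is tested against its own effect × subject error term
    (uncorrected degrees of freedom). When ``tukey``, all pairwise cell
    contrasts are evaluated with the studentized range using the
    interaction error term.

    Returns a dict with keys = the two factor names and ``"interaction"``.
    """
    fa, fb = within
    cells = data.pivot_table(index=subject, columns=[fa, fb], values=dv,
                             aggfunc="mean")
    if cells.isna().any().any():
        raise ValueError("missing cells in the within-subject design")
    a_levels = sorted({c[0] for c in cells.columns})
    b_levels = sorted({c[1] for c in cells.columns})
    n, a, b = len(cells), len(a_levels), len(b_levels)
    if n < 2:
        raise ValueError("need at least 2 subjects for error degrees of freedom")
    y = np.empty((n, a, b))
    for i, ai in enumerate(a_levels):
        for j, bj in enumerate(b_levels):
            y[:, i, j] = cells[(ai, bj)].to_numpy(dtype=float)

    gm = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)

    ss_a = n * b * ((m_a - gm) ** 2).sum()
    ss_b = n * a * ((m_b - gm) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2).sum()
    ss_as = b * ((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2).sum()
    ss_bs = a * ((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2).sum()
    resid = (y - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_a[None, :, None] + m_b[None, None, :] + m_s[:, None, None] - gm)
    ss_abs = (resid ** 2).sum()

    def _f(ss_eff, df_eff, ss_err, df_err, name) -> StatTestResult:
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        if ms_err == 0:
            f = 0.0 if ms_eff == 0 else np.inf
            p = 1.0 if ms_eff == 0 else 0.0
        else:
            f = ms_eff / ms_err
            p = float(sps.f.sf(f, df_eff, df_err))
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        return StatTestResult(name, float(f), (df_eff, df_err), float(p),
                              {"partial_eta_sq": float(eta), "n": n})

    out = {
        fa: _f(ss_a, a - 1, ss_as, (a - 1) * (n - 1), f"rm-ANOVA main {fa}"),
        fb: _f(ss_b, b - 1, ss_bs, (b - 1) * (n - 1), f"rm-ANOVA main {fb}"),
        "interaction": _f(ss_ab, (a - 1) * (b - 1), ss_abs,
                          (a - 1) * (b - 1) * (n - 1), "rm-ANOVA interaction"),
    }

    if tukey:
        df_err = (a - 1) * (b - 1) * (n - 1)
        ms_err = ss_abs / df_err if df_err > 0 else np.nan
        k = a * b
        rows = []
        labels = [(ai, bj) for ai in a_levels for bj in b_levels]
        means = {(ai, bj): m_ab[i, j] for i, ai in enumerate(a_levels)
                 for j, bj in enumerate(b_levels)}
        se = np.sqrt(ms_err / n) if ms_err > 0 else np.nan
        for c1, c2 in combinations(labels, 2):
            diff = means[c1] - means[c2]
            if np.isfinite(se) and se > 0:
                qstat = abs(diff) / se
                p = float(sps.studentized_range.sf(qstat, k, df_err))
                tstat = diff / (se * np.sqrt(2))  # t = q/sqrt(2), signed
            else:
                qstat, p, tstat = np.nan, np.nan, np.nan
            rows.append({"cell_1": c1, "cell_2": c2, "mean_diff": float(diff),
                         "t": float(tstat), "q": float(qstat), "p_tukey": p})
        out["interaction"].post_hoc = pd.DataFrame(rows)
    return out


# ---------------------------------------------------------------------------
# LI correlation with outlier exclusion

def pearson_li_correlation(
    li_task1,
    li_task2,
    exclude_outliers: bool = False,
    cooks_factor: float = 4.0,
    resid_thresh: float = 2.5,
) -> StatTestResult:
    """Pearson correlation of the two tasks' laterality indices.

    With ``exclude_outliers``, a simple linear regression of task 2 on
    task 1 is fit and points with Cook's distance > ``cooks_factor``/n or
    |externally studentized residual| > ``resid_thresh`` are dropped before
    refitting; both correlations and the excluded index set are reported.
    """
    x = np.asarray(li_task1, dtype=float)
    y = np.asarray(li_task2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1-D vectors required")
    if len(x) < 4:
        raise ValueError("need n >= 4")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant vector: correlation undefined")
    r, p = sps.pearsonr(x, y)
    result = StatTestResult("pearson", float(r), len(x) - 2, float(p),
                            {"n": len(x)})
    if not exclude_outliers:
        return result

    import statsmodels.api as sm
    infl = sm.OLS(y, sm.add_constant(x)).fit().get_influence()
    cooks = infl.cooks_distance[0]
    studentized = infl.resid_studentized_external
    mask = (cooks > cooks_factor / len(x)) | (np.abs(studentized) > resid_thresh)
    excluded = np.flatnonzero(mask)
    result.effect["excluded"] = excluded.tolist()
    keep = ~mask
    if keep.sum() >= 4 and x[keep].std() > 0 and y[keep].std() > 0:
        r2, p2 = sps.pearsonr(x[keep], y[keep])
        result.effect.update({"r_post_exclusion": float(r2),
                              "p_post_exclusion": float(p2),
                              "n_post_exclusion": int(keep.sum())})
    return result


def ks_two_sample(sample1, sample2) -> StatTestResult:
    """Two-sample Kolmogorov–Smirnov test (D = sup |ECDF1 − ECDF2|)."""
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("samples must be nonempty")
    res = sps.ks_2samp(x, y, method="asymp")
    return StatTestResult("ks two-sample", float(res.statistic), None,
                          float(res.pvalue), {"n1": len(x), "n2": len(y)})


# ---------------------------------------------------------------------------
# design-stage computations

def paired_t_power(n: int, dz: float, alpha: float = 0.05) -> float:
    """Power of the two-sided paired t-test via the noncentral t."""
    df = n - 1
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    ncp = dz * np.sqrt(n)
    return float(1.0 - sps.nct.cdf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


def required_n_paired_t(dz: float, alpha: float = 0.05, power: float = 0.95,
                        n_max: int = 100000) -> int:
    """Smallest n whose paired-t power reaches ``power`` at ``alpha``."""
    if dz <= 0:
        raise ValueError("effect size dz must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not alpha < power < 1:
        raise ValueError("power must lie in (alpha, 1)")
    for n in range(2, n_max + 1):
        if paired_t_power(n, dz, alpha) >= power:
            return n
    raise ValueError("no n below n_max reaches the requested power")


def separation_inconsistency_cm(
    circ_min_cm: float = 53.5,
    circ_max_cm: float = 60.0,
    separation_cm: float = 3.0,
) -> float:
    """Across-participant optode-separation inconsistency.

    With head circumferences spanning ``circ_min_cm``–``circ_max_cm``, a cap
    with fixed optode spacing covers (max − min)/max of the separation
    differently across heads: (60 − 53.5)/60 × 3 cm ≈ 0.3 cm, rounded to
    one decimal.
    """
    if not 0 < circ_min_cm <= circ_max_cm:
        raise ValueError("need 0 < circ_min_cm <= circ_max_cm")
    return round((circ_max_cm - circ_min_cm) / circ_max_cm * separation_cm, 1)
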