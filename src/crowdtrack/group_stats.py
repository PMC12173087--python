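"""Group-level inference: paired t-tests, 2x2 within-subject ANOVA, Pearson r.

The 2x2 repeated-measures ANOVA is computed from closed-form sums of
squares (each within-subject effect has 1 numerator df and n-1 denominator
df; sphericity is moot with a single df). Effect size is partial eta
squared, SS_effect / (SS_effect + SS_error_effect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    cohen_d: float


@dataclass
class EffectResult:
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float


@dataclass
class RmAnovaResult:
    factor_a: EffectResult
    factor_b: EffectResult
    interaction: EffectResult


def paired_t(x, y) -> PairedTResult:
    """Paired-samples t-test with Cohen's d = mean(diff)/sd(diff)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 2")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return PairedTResult(0.0, x.size - 1, 1.0, 0.0)
        raise ValueError("zero-variance differences")
    res = stats.ttest_rel(x, y)
    return PairedTResult(float(res.statistic), int(x.size - 1), float(res.pvalue),
                         float(diff.mean() / sd))


def _effect(ss_eff: float, ss_err: float, df_den: int) -> EffectResult:
    ms_eff = ss_eff / 1.0
    ms_err = ss_err / df_den
    if ms_err == 0:
        f = np.inf if ss_eff > 0 else 0.0
        p = 0.0 if ss_eff > 0 else 1.0
    else:
        f = ms_eff / ms_err
        p = float(stats.f.sf(f, 1, df_den))
    denom = ss_eff + ss_err
    eta = ss_eff / denom if denom > 0 else 0.0
    return EffectResult(float(f), 1, df_den, p, float(eta))


def rm_anova_2x2(values) -> RmAnovaResult:
    """2x2 within-subject ANOVA on a (subjects, A, B) table.

    ``values`` is an array of shape (n, 2, 2): one value per subject and
    factor-level combination (complete, balanced). Returns F(1, n-1), p and
    partial eta squared per effect (A, B, AxB).
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 3 or y.shape[1:] != (2, 2):
        raise ValueError("values must have shape (n_subjects, 2, 2)")
    if not np.isfinite(y).all():
        raise ValueError("missing cells")
    n = y.shape[0]
    if n < 2:
        raise ValueError("need >= 2 subjects")
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))  # per subject
    m_a = y.mean(axis=(0, 2))  # per A level
    m_b = y.mean(axis=(0, 1))  # per B level
    m_as = y.mean(axis=2)  # (n, 2)
    m_bs = y.mean(axis=1)  # (n, 2)
    m_ab = y.mean(axis=0)  # (2, 2)

    ss_a = 2 * n * np.sum((m_a - grand) ** 2)
    ss_b = 2 * n * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = 2 * np.sum((m_as - m_a[None, :] - m_s[:, None] + grand) ** 2)
    ss_bs = 2 * np.sum((m_bs - m_b[None, :] - m_s[:, None] + grand) ** 2)
    resid = (y - m_ab[None, :, :] - m_as[:, :, None] - m_bs[:, None, :]
             + m_a[None, :, None] + m_b[None, None, :] + m_s[:, None, None] - grand)
    ss_abs = np.sum(resid**2)

    df = n - 1
    return RmAnovaResult(_effect(ss_a, ss_as, df), _effect(ss_b, ss_bs, df),
                         _effect(ss_ab, ss_abs, df))


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
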