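"""Within-subject inferential statistics for the tapping metrics.

Repeated-measures ANOVAs (one- and two-way) via the classical
subject-blocked sum-of-squares decompositions with partial eta-squared
effect sizes, paired / one-sample t-tests with Cohen's d, and Pearson
correlation. All tests are two-tailed by default, matching the study's
reporting convention; no sphericity correction is applied by default
(Greenhouse-Geisser is available behind a flag). Batch variants evaluate
many simulated tables at once, which makes large null calibrations cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "rm_anova_oneway",
    "rm_anova_twoway",
    "t_tests",
    "pearson_r",
    "rm_anova_oneway_batch",
    "rm_anova_twoway_batch",
]


@dataclass(frozen=True)
class StatResult:
    """One test's outcome: statistic, df, p, effect size."""

    statistic: float
    df: tuple[float, ...]
    p_value: float
    effect_size: float
    effect_size_name: str
    tails: str = "two"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the (n, k) within-subject covariance."""
    S = np.cov(data, rowvar=False)
    k = S.shape[0]
    dbar = np.diag(S).mean()
    gbar = S.mean()
    rowbar = S.mean(axis=1)
    num = (k * (dbar - gbar)) ** 2
    den = (k - 1) * ((S**2).sum() - 2 * k * (rowbar**2).sum() + k**2 * gbar**2)
    return float(num / den)


def rm_anova_oneway_batch(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized one-way repeated-measures ANOVA.

    ``data`` has shape ``(..., n_subjects, k_levels)``; returns
    ``(F, p, partial_eta_sq)`` over the leading axes.
    """
    data = np.asarray(data, float)
    n, k = data.shape[-2], data.shape[-1]
    grand = data.mean(axis=(-2, -1), keepdims=True)
    subj = data.mean(axis=-1, keepdims=True)
    lvl = data.mean(axis=-2, keepdims=True)
    ss_effect = n * ((lvl - grand) ** 2).sum(axis=(-2, -1))
    resid = data - subj - lvl + grand
    ss_error = (resid**2).sum(axis=(-2, -1))
    df1, df2 = k - 1, (k - 1) * (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ss_effect / df1) / (ss_error / df2)
        eta = ss_effect / (ss_effect + ss_error)
    # an effect SS at numerical zero means no effect, whatever the error SS
    ss_tot = ((data - grand) ** 2).sum(axis=(-2, -1))
    zero = ss_effect <= 1e-12 * ss_tot
    F = np.where(zero, 0.0, F)
    eta = np.where(zero, 0.0, eta)
    p = sps.f.sf(F, df1, df2)
    return F, p, eta


def rm_anova_oneway(
    data: np.ndarray, correction: str | None = None
) -> StatResult:
    """One-way repeated-measures ANOVA on a complete (n_subjects, k) table.

    ``correction='gg'`` applies the Greenhouse-Geisser adjustment to the
    degrees of freedom of the p-value (the reported df stay conventional).
    """
    data = np.asarray(data, float)
    if data.ndim != 2:
        raise ValueError("expected a 2-D subject x level table")
    if np.isnan(data).any():
        raise ValueError("missing cells are not supported (no imputation)")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 levels")
    F, p, eta = rm_anova_oneway_batch(data)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    if correction == "gg":
        eps = _gg_epsilon(data)
        p = float(sps.f.sf(F, eps * df1, eps * df2))
    return StatResult(float(F), (df1, df2), float(p), float(eta), "partial_eta_sq")


def rm_anova_twoway_batch(
    data: np.ndarray,
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Vectorized two-way repeated-measures ANOVA.

    ``data`` has shape ``(..., n_subjects, a, b)``; returns per effect
    (``'A'``, ``'B'``, ``'AxB'``) the ``(F, p, partial_eta_sq)`` arrays.
    Each effect is tested against its own subject-interaction error term.
    """
    data = np.asarray(data, float)
    n, a, b = data.shape[-3], data.shape[-2], data.shape[-1]
    grand = data.mean(axis=(-3, -2, -1), keepdims=True)
    m_s = data.mean(axis=(-2, -1), keepdims=True)  # subject means
    m_a = data.mean(axis=(-3, -1), keepdims=True)  # factor-A level means
    m_b = data.mean(axis=(-3, -2), keepdims=True)
    m_sa = data.mean(axis=-1, keepdims=True)
    m_sb = data.mean(axis=-2, keepdims=True)
    m_ab = data.mean(axis=-3, keepdims=True)

    ss_a = (n * b) * ((m_a - grand) ** 2).sum(axis=(-3, -2, -1))
    ss_b = (n * a) * ((m_b - grand) ** 2).sum(axis=(-3, -2, -1))
    ss_ab = n * ((m_ab - m_a - m_b + grand) ** 2).sum(axis=(-3, -2, -1))
    ss_as = b * ((m_sa - m_s - m_a + grand) ** 2).sum(axis=(-3, -2, -1))
    ss_bs = a * ((m_sb - m_s - m_b + grand) ** 2).sum(axis=(-3, -2, -1))
    resid = data - m_sa - m_sb - m_ab + m_a + m_b + m_s - grand
    ss_abs = (resid**2).sum(axis=(-3, -2, -1))

    ss_tot = ((data - grand) ** 2).sum(axis=(-3, -2, -1))
    out = {}
    for name, ss_eff, ss_err, df1, df2 in (
        ("A", ss_a, ss_as, a - 1, (a - 1) * (n - 1)),
        ("B", ss_b, ss_bs, b - 1, (b - 1) * (n - 1)),
        ("AxB", ss_ab, ss_abs, (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1)),
    ):
        with np.errstate(invalid="ignore", divide="ignore"):
            F = (ss_eff / df1) / (ss_err / df2)
            eta = ss_eff / (ss_eff + ss_err)
        zero = ss_eff <= 1e-12 * ss_tot
        F = np.where(zero, 0.0, F)
        eta = np.where(zero, 0.0, eta)
        out[name] = (F, sps.f.sf(F, df1, df2), eta)
    return out


def rm_anova_twoway(data: np.ndarray) -> dict[str, StatResult]:
    """Two-way repeated-measures ANOVA on an (n_subjects, a, b) table."""
    data = np.asarray(data, float)
    if data.ndim != 3:
        raise ValueError("expected a 3-D subject x factorA x factorB table")
    if np.isnan(data).any():
        raise ValueError("missing cells are not supported (no imputation)")
    n, a, b = data.shape
    if n < 2 or a < 2 or b < 2:
        raise ValueError("need at least 2 subjects and 2 levels per factor")
    raw = rm_anova_twoway_batch(data)
    dfs = {
        "A": (a - 1, (a - 1) * (n - 1)),
        "B": (b - 1, (b - 1) * (n - 1)),
        "AxB": ((a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1)),
    }
    return {
        name: StatResult(
            float(F), dfs[name], float(p), float(eta), "partial_eta_sq"
        )
        for name, (F, p, eta) in raw.items()
    }


def t_tests(
    x: np.ndarray,
    y: np.ndarray | float = 0.0,
    mode: str = "one_sample",
    tails: str = "two",
) -> StatResult:
    """Paired or one-sample t-test with Cohen's d.

    ``mode='paired'`` tests the mean of ``x - y``; ``mode='one_sample'``
    tests the mean of ``x`` against the reference value ``y``. Cohen's d is
    the mean difference divided by the SD of the differences.
    """
    x = np.asarray(x, float)
    if mode == "paired":
        y = np.asarray(y, float)
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        d = x - y
    elif mode == "one_sample":
        d = x - float(y)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:  # identical samples: trivially no effect
            return StatResult(0.0, (n - 1,), 1.0, 0.0, "cohen_d", tails)
        raise ValueError("zero variance; t-test undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = sps.t.sf(abs(t), n - 1) * (2 if tails == "two" else 1)
    return StatResult(
        float(t), (n - 1,), float(p), float(d.mean() / sd), "cohen_d", tails
    )


def pearson_r(x: np.ndarray, y: np.ndarray, tails: str = "two") -> StatResult:
    """Pearson product-moment correlation with a t-based p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two equal-length 1-D samples")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p = sps.t.sf(abs(t), n - 2) * (2 if tails == "two" else 1)
    return StatResult(r, (n - 2,), float(p), r, "r", tails)
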