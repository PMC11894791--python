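"""Follow-up statistics on cluster-averaged amplitudes.

A significant cluster is summarized by its per-subject, per-condition mean
amplitude; the 2x2 repeated-measures ANOVA and pairwise t-tests here
unravel which cells drive the interaction.  In a 2x2 within design every
effect has one numerator degree of freedom, so each F equals the squared
paired t of the corresponding per-subject contrast — main effects on the
marginal differences, the interaction on the difference of differences —
and partial eta squared is F / (F + df_denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

__all__ = ["TTestResult", "AnovaEffect", "rm_anova_2x2", "paired_t", "welch_t", "pooled_t"]


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    infinite: bool = False  # zero-variance degenerate case


@dataclass
class AnovaEffect:
    name: str
    F: float
    df: tuple[int, int]
    p: float
    eta_p2: float
    infinite: bool = False


def _one_sample(contrast: np.ndarray) -> TTestResult:
    contrast = np.asarray(contrast, dtype=float)
    n = contrast.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    m = contrast.mean()
    sd = contrast.std(ddof=1)
    if sd == 0:
        if m == 0:
            return TTestResult(t=0.0, df=n - 1, p=1.0)
        return TTestResult(t=np.inf if m > 0 else -np.inf, df=n - 1, p=0.0, infinite=True)
    t = m / (sd / np.sqrt(n))
    p = 2 * t_dist.sf(abs(t), n - 1)
    return TTestResult(t=float(t), df=n - 1, p=float(p))


def paired_t(x, y) -> TTestResult:
    """Paired t-test; zero-variance differences are flagged, not dropped."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    return _one_sample(x - y)


def _two_sample(x, y, pooled: bool) -> TTestResult:
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per sample")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    if pooled:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se2 = sp2 * (1 / n1 + 1 / n2)
    else:
        se2 = v1 / n1 + v2 / n2
        if se2 > 0:
            # Welch-Satterthwaite degrees of freedom (fractional)
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        else:
            df = n1 + n2 - 2
    if se2 == 0:
        if diff == 0:
            return TTestResult(t=0.0, df=float(df), p=1.0)
        return TTestResult(
            t=np.inf if diff > 0 else -np.inf, df=float(df), p=0.0, infinite=True
        )
    t = diff / np.sqrt(se2)
    p = 2 * t_dist.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p))


def welch_t(x, y) -> TTestResult:
    """Two-sample t with Welch-Satterthwaite (fractional) df."""
    return _two_sample(x, y, pooled=False)


def pooled_t(x, y) -> TTestResult:
    """Two-sample t with pooled variance, df n1 + n2 - 2."""
    return _two_sample(x, y, pooled=True)


def rm_anova_2x2(values: np.ndarray) -> dict[str, AnovaEffect]:
    """Univariate 2x2 repeated-measures ANOVA.

    ``values``: (n_subjects, 2, 2) cell means, first axis factor A, second
    factor B.  Returns effects keyed ``"A"``, ``"B"``, ``"A:B"``, each with
    df (1, n-1) and partial eta squared.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3 or values.shape[1:] != (2, 2):
        raise ValueError("values must be (n_subjects, 2, 2)")
    n = values.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if not np.all(np.isfinite(values)):
        raise ValueError("missing cells")
    contrasts = {
        "A": (values[:, 0, :].mean(axis=1) - values[:, 1, :].mean(axis=1)),
        "B": (values[:, :, 0].mean(axis=1) - values[:, :, 1].mean(axis=1)),
        "A:B": (values[:, 0, 0] - values[:, 0, 1]) - (values[:, 1, 0] - values[:, 1, 1]),
    }
    out: dict[str, AnovaEffect] = {}
    for name, c in contrasts.items():
        tt = _one_sample(c)
        F = tt.t**2 if np.isfinite(tt.t) else np.inf
        p = f_dist.sf(F, 1, n - 1) if np.isfinite(F) else 0.0
        eta = 1.0 if np.isinf(F) else F / (F + (n - 1))
        out[name] = AnovaEffect(
            name=name, F=float(F), df=(1, n - 1), p=float(p),
            eta_p2=float(eta), infinite=tt.infinite,
        )
    return out
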