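"""Differential expression versus the day-0 reference with a moderated t.

The per-feature variance of a small replicated design is unstable; the
moderated t shrinks each feature's pooled variance s^2 (d residual df)
towards an empirical-Bayes prior s0^2 (d0 prior df):

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)
    t_mod     = (mean_a - mean_b) / (s_tilde * sqrt(1/na + 1/nb))

with a two-sided p from the t distribution on d + d0 degrees of freedom.
The hyperparameters (d0, s0^2) are estimated by the method of moments on
log sample variances: under the scaled inverse-chi-square prior,
e_g = log s_g^2 - psi(d/2) + log(d/2) has mean log s0^2 - psi(d0/2) +
log(d0/2) and variance psi'(d/2) + psi'(d0/2), which identifies d0 through
the trigamma function and then s0^2 through the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import UndefinedStatisticError, ValidationError
from .expression import ExpressionStudy


@dataclass
class DEResult:
    feature_id: str
    day: float
    log2fc: float
    t_mod: float
    p_raw: float
    p_adj: float = np.nan
    is_de: bool = False


def moderated_t(group_a, group_b, prior_df: float = 0.0,
                prior_var: float = 1.0) -> tuple[float, float, float]:
    """Moderated two-sample t for one feature.

    Returns (t_mod, total df, two-sided p).  ``prior_df = 0`` reduces the
    statistic to the ordinary pooled two-sample t; ``prior_df = inf``
    replaces the sample variance entirely by ``prior_var``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValidationError("moderated_t needs >= 2 replicates per group")
    d = na + nb - 2
    s2 = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / d
    if np.isinf(prior_df):
        s_tilde2, df_total = prior_var, np.inf
    else:
        if prior_df < 0:
            raise ValidationError("prior_df must be >= 0")
        if prior_df == 0 and s2 == 0:
            raise UndefinedStatisticError(
                "pooled variance is zero and no prior is available")
        s_tilde2 = (prior_df * prior_var + d * s2) / (prior_df + d)
        df_total = d + prior_df
    t = (a.mean() - b.mean()) / np.sqrt(s_tilde2 * (1 / na + 1 / nb))
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(abs(t))
    else:
        p = 2 * stats.t.sf(abs(t), df_total)
    return float(t), float(df_total), float(p)


def _trigamma_inverse(y: float, iters: int = 64) -> float:
    """Solve psi'(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(iters):
        tri = special.polygamma(1, x)
        step = tri * (1 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(sample_variances, residual_df: float) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0^2) from per-feature pooled variances.

    Method of moments on log variances; returns ``d0 = inf`` when the
    observed spread of log variances does not exceed the sampling spread
    expected from ``residual_df`` alone (all features then share s0^2).
    """
    s2 = np.asarray(sample_variances, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 10:
        raise ValidationError("estimate_prior needs >= 10 positive variances")
    d = float(residual_df)
    z = np.log(s2)
    if np.allclose(z, z[0]):
        return np.inf, float(np.exp(z[0]))
    e = z - special.digamma(d / 2) + np.log(d / 2)
    evar = np.var(e, ddof=1) - special.polygamma(1, d / 2)
    if evar <= 0:
        return np.inf, float(np.exp(e.mean()))
    d0 = 2 * _trigamma_inverse(evar)
    s0sq = np.exp(e.mean() + special.digamma(d0 / 2) - np.log(d0 / 2))
    return float(d0), float(s0sq)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(results: list[DEResult], alpha: float = 1e-5, lfc_min: float = 2.0,
            strict: bool = True) -> list[DEResult]:
    """Flag results passing the joint adjusted-p and fold-change thresholds.

    Default comparisons are strict (<, >); ``strict=False`` switches to
    <=, >= for both thresholds.
    """
    for r in results:
        if strict:
            r.is_de = (r.p_adj < alpha) and (abs(r.log2fc) > lfc_min)
        else:
            r.is_de = (r.p_adj <= alpha) and (abs(r.log2fc) >= lfc_min)
    return results


def _moderated_t_matrix(A: np.ndarray, B: np.ndarray, d0: float, s0sq: float
                        ) -> tuple[np.ndarray, float, np.ndarray]:
    """Vectorised moderated t over features (rows of A and B)."""
    na, nb = A.shape[1], B.shape[1]
    d = na + nb - 2
    s2 = ((A - A.mean(1, keepdims=True)) ** 2).sum(1)
    s2 += ((B - B.mean(1, keepdims=True)) ** 2).sum(1)
    s2 /= d
    if np.isinf(d0):
        s_tilde2, df = np.full_like(s2, s0sq), np.inf
    else:
        s_tilde2, df = (d0 * s0sq + d * s2) / (d0 + d), d + d0
    delta = A.mean(1) - B.mean(1)
    t = delta / np.sqrt(s_tilde2 * (1 / na + 1 / nb))
    p = 2 * (stats.norm.sf(np.abs(t)) if np.isinf(df) else stats.t.sf(np.abs(t), df))
    return t, df, p


def de_table(study: ExpressionStudy, reference_day: float | None = None,
             alpha: float = 1e-5, lfc_min: float = 2.0,
             strict: bool = True) -> pd.DataFrame:
    """Moderated-t DE of every day versus the reference day, per feature.

    For each non-reference day the contrast is that day's replicates versus
    the reference day's; the variance prior is estimated per contrast from
    all features, and BH adjustment is applied within each contrast.
    Returns a long DataFrame: feature_id, day, log2fc, t_mod, p_raw, p_adj,
    is_de.
    """
    days = study.days
    ref = days[0] if reference_day is None else float(reference_day)
    if ref not in days:
        raise ValidationError(f"reference day {ref} not in study")
    ref_cols = study.samples_for_day(ref)
    B = study.values[ref_cols].to_numpy(dtype=float)
    frames = []
    for day in days:
        if day == ref:
            continue
        cols = study.samples_for_day(day)
        A = study.values[cols].to_numpy(dtype=float)
        d = A.shape[1] + B.shape[1] - 2
        s2 = (((A - A.mean(1, keepdims=True)) ** 2).sum(1)
              + ((B - B.mean(1, keepdims=True)) ** 2).sum(1)) / d
        # guard for degenerate (e.g. noise-free) data: a zero pooled variance
        # would leave the statistic undefined for every flat feature
        s2 = np.maximum(s2, 1e-12)
        d0, s0sq = estimate_prior(s2, d)
        t, df, p = _moderated_t_matrix(A, B, d0, s0sq)
        frames.append(pd.DataFrame({
            "feature_id": study.feature_ids,
            "day": day,
            "log2fc": A.mean(1) - B.mean(1),
            "t_mod": t,
            "p_raw": p,
            "p_adj": bh_adjust(p),
        }))
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["feature_id", "day", "log2fc", "t_mod", "p_raw", "p_adj"])
    if strict:
        table["is_de"] = (table["p_adj"] < alpha) & (table["log2fc"].abs() > lfc_min)
    else:
        table["is_de"] = (table["p_adj"] <= alpha) & (table["log2fc"].abs() >= lfc_min)
    return table
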