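"""Switch-like peak detection by cross-correlation with one-hot templates.

A miRNA that is expressed at baseline except for a single time point scores
a large positive Pearson correlation against the binary template that is 1
at that time point and 0 elsewhere; sliding the template across the grid
and taking the best day turns the correlation into a peak call.

Two correlation levels are supported.  ``"replicate"`` (default) correlates
the full replicate-level sample vector against the template expanded across
replicates; with r replicates per day this gives the statistic n_days*r - 2
degrees of freedom and makes the 0.6 cut-off selective.  ``"mean"``
correlates the day-mean profile against the bare template; with only a
handful of time points this mode is extremely permissive (a flat noisy
profile exceeds 0.6 at some day most of the time, regardless of the noise
level) and is retained for comparability rather than recommended.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .expression import ExpressionStudy, Profile

logger = logging.getLogger(__name__)


@dataclass
class PeakCall:
    """A miRNA's assigned peak day and its template correlations."""

    mirna_id: str
    peak_day: float
    r_peak: float
    all_r: np.ndarray  # one Pearson coefficient per day, day-ascending
    days: np.ndarray


def one_hot_vector(day_index: int, n_days: int) -> np.ndarray:
    """Binary peak template: 1 at ``day_index``, 0 at the other days."""
    if n_days < 3:
        raise ValidationError("one_hot_vector needs at least 3 days")
    if not 0 <= day_index < n_days:
        raise ValidationError(f"day_index {day_index} out of range for {n_days} days")
    v = np.zeros(n_days)
    v[day_index] = 1.0
    return v


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValidationError("Pearson undefined for a constant vector")
    return float((xc @ yc) / denom)


def peak_correlation(profile: Profile, day_index: int) -> float:
    """Pearson correlation of a day-mean profile with the one-hot template."""
    template = one_hot_vector(day_index, profile.n_days)
    return _pearson(profile.day_means, template)


def _template_correlations(study: ExpressionStudy, level: str) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Per-feature Pearson r against every day's template; vectorised.

    Returns (r matrix features x days, feature ids, days).
    """
    days = study.days
    n_days = days.size
    if level == "mean":
        data = study.day_means().to_numpy(dtype=float)
        reps = np.ones(n_days, dtype=int)
    elif level == "replicate":
        data = study.values.to_numpy(dtype=float)  # columns already day-ordered
        reps = np.array([len(study.samples_for_day(d)) for d in days])
    else:
        raise ValidationError(f"unknown correlation level: {level}")
    centred = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    rmat = np.full((data.shape[0], n_days), np.nan)
    for d in range(n_days):
        template = np.repeat(one_hot_vector(d, n_days), reps)
        tc = template - template.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            rmat[:, d] = (centred @ tc) / (norms * np.linalg.norm(tc))
    return rmat, study.feature_ids, days


def call_peaks(study: ExpressionStudy, r_min: float = 0.6,
               level: str = "replicate") -> list[PeakCall]:
    """Assign each miRNA its best-matching peak day if it clears ``r_min``.

    Every miRNA receives at most one peak day (the argmax over templates,
    earliest day on ties); constant profiles are skipped with a warning.
    """
    rmat, ids, days = _template_correlations(study, level)
    calls: list[PeakCall] = []
    for i, mid in enumerate(ids):
        row = rmat[i]
        if np.isnan(row).any():
            logger.warning("call_peaks: constant profile %s skipped", mid)
            continue
        best = int(np.argmax(row))  # argmax returns the first (earliest) maximum
        if row[best] >= r_min:
            calls.append(PeakCall(mirna_id=mid, peak_day=float(days[best]),
                                  r_peak=float(row[best]), all_r=row.copy(),
                                  days=days.copy()))
    return calls


def top_k_by_day(calls: list[PeakCall], k: int = 10) -> dict[float, list[str]]:
    """Per day, the up-to-``k`` miRNAs with the highest peak correlation.

    Ties on r are broken by miRNA id so the selection is deterministic.
    """
    by_day: dict[float, list[PeakCall]] = {}
    for call in calls:
        by_day.setdefault(call.peak_day, []).append(call)
    out: dict[float, list[str]] = {}
    for day, group in sorted(by_day.items()):
        group.sort(key=lambda c: (-c.r_peak, c.mirna_id))
        out[day] = [c.mirna_id for c in group[:k]]
    return out
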