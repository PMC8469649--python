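"""Expression matrices on the log2 scale: loading, filtering, collapsing,
day-mean profiles, Min-Max normalisation and fold changes.

The central container is :class:`ExpressionStudy`, a replicated multi-day
time course for one feature kind (mRNA or miRNA) of one study (in vitro or
in vivo).  All downstream correlation screens operate on day-mean profiles,
i.e. vectors with one entry per time point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ExpressionStudy:
    """A log2 expression matrix (features x samples) with sample annotations.

    Parameters
    ----------
    values
        DataFrame of log2 intensities; index = feature ids (unique),
        columns = sample ids.
    samples
        DataFrame with columns ``sample_id``, ``day`` (numeric), ``replicate``,
        one row per column of ``values``.
    feature_kind
        ``"mRNA"`` or ``"miRNA"``.
    probe_to_feature
        Optional probe -> gene/miRNA id map used by :func:`collapse_probes`.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    feature_kind: str = "mRNA"
    probe_to_feature: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValidationError("feature ids must be unique")
        required = {"sample_id", "day", "replicate"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValidationError(f"sample sheet lacks columns: {sorted(missing)}")
        sheet_ids = list(self.samples["sample_id"])
        if sorted(sheet_ids) != sorted(self.values.columns):
            raise ValidationError("sample sheet does not match matrix columns")
        # canonical column order: by day, then replicate
        order = self.samples.sort_values(["day", "replicate"])["sample_id"]
        self.samples = self.samples.set_index("sample_id").loc[order].reset_index()
        self.values = self.values[list(order)]
        counts = self.samples.groupby("day").size()
        if (counts < 1).any():
            raise ValidationError("every day needs at least one replicate")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def days(self) -> np.ndarray:
        """Distinct days in ascending order."""
        return np.asarray(sorted(self.samples["day"].unique()), dtype=float)

    def samples_for_day(self, day: float) -> list[str]:
        mask = self.samples["day"] == day
        return list(self.samples.loc[mask, "sample_id"])

    def day_means(self) -> pd.DataFrame:
        """Per-feature arithmetic mean of replicate log2 values for each day.

        Returns a features x days DataFrame with days ascending.
        """
        day_of = self.samples.set_index("sample_id")["day"]
        grouped = self.values.T.groupby(self.values.columns.map(day_of)).mean().T
        return grouped[sorted(grouped.columns)]


@dataclass
class Profile:
    """One feature's day-mean log2 profile (one value per time point)."""

    feature_id: str
    day_means: np.ndarray
    days: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.day_means = np.asarray(self.day_means, dtype=float)
        if self.days.size == 0:
            self.days = np.arange(self.day_means.size, dtype=float)
        self.days = np.asarray(self.days, dtype=float)
        if self.day_means.size != self.days.size:
            raise ValidationError("day_means and days must have equal length")

    @property
    def n_days(self) -> int:
        return int(self.day_means.size)


def filter_expressed(study: ExpressionStudy, floor: float = 5.0) -> ExpressionStudy:
    """Keep features whose maximum day-mean strictly exceeds ``floor``.

    The detection floor is compared against the per-day mean, so a feature
    only needs to clear the floor at one time point.  A value exactly equal
    to the floor does not qualify.
    """
    means = study.day_means()
    keep = means.max(axis=1) > floor
    if not keep.any():
        logger.warning("filter_expressed: no feature exceeds floor %.3g", floor)
    return replace(study, values=study.values.loc[keep], samples=study.samples.copy())


def collapse_probes(study: ExpressionStudy) -> ExpressionStudy:
    """Collapse probe-level rows to one row per mapped feature.

    The representative probe for each feature is the one with the highest
    mean log2 intensity over all samples; unmapped probes are dropped.
    """
    if study.probe_to_feature is None:
        raise ValidationError("collapse_probes requires a probe_to_feature map")
    mapping = pd.Series(dict(study.probe_to_feature))
    mapped = study.values.index.intersection(mapping.index)
    vals = study.values.loc[mapped]
    overall = vals.mean(axis=1)
    frame = pd.DataFrame(
        {"feature": mapping.loc[mapped].values, "mean": overall.values},
        index=mapped,
    )
    # highest-mean probe wins; stable order = first occurrence of each feature
    best = (
        frame.sort_values("mean", ascending=False)
        .groupby("feature", sort=False)
        .head(1)
    )
    best = best.loc[[p for p in mapped if p in best.index]]
    collapsed = vals.loc[best.index]
    collapsed.index = best["feature"].values
    return ExpressionStudy(
        values=collapsed,
        samples=study.samples.copy(),
        feature_kind=study.feature_kind,
        probe_to_feature=None,
    )


def day_mean_profile(study: ExpressionStudy, feature_id: str) -> Profile:
    """Day-mean profile of a single feature, days ascending."""
    if feature_id not in study.values.index:
        raise KeyError(f"unknown feature: {feature_id}")
    means = study.day_means()
    return Profile(
        feature_id=feature_id,
        day_means=means.loc[feature_id].to_numpy(dtype=float),
        days=np.asarray(means.columns, dtype=float),
    )


def minmax_normalize(profile: Profile) -> Profile:
    """Linearly rescale a profile to the [0, 1] interval.

    Constant profiles map to all zeros (with a logged warning) rather than
    raising, so a batch of features can be normalised without special-casing
    flat ones.
    """
    x = profile.day_means
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        logger.warning("minmax_normalize: constant profile %s", profile.feature_id)
        scaled = np.zeros_like(x)
    else:
        scaled = (x - lo) / (hi - lo)
    return Profile(profile.feature_id, scaled, profile.days.copy())


def log2_fold_changes(study: ExpressionStudy, reference_day: float) -> pd.DataFrame:
    """Per-feature log2 fold change of each day's mean versus a reference day.

    On the log2 scale the fold change is a plain difference of day means;
    the reference day's column is identically zero.
    """
    means = study.day_means()
    if reference_day not in means.columns:
        raise ConfigurationError(f"reference day {reference_day} not in study")
    return means.sub(means[reference_day], axis=0)


def expressed_feature_set(study: ExpressionStudy, floor: float = 5.0) -> set[str]:
    """Convenience: ids of features passing the expression floor."""
    return set(filter_expressed(study, floor).feature_ids)
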