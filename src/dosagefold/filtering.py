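"""Three-step untargeted-metabolomics feature filter and log2(x+1) transform.

The filter removes uninformative features in three passes, each audited in a
:class:`FilterReport`:

1. presence — keep a feature only if at least one strain x ploidy group has
   it detected (abundance > 0, non-missing) in every replicate;
2. repeatability — drop the fraction ``frac`` (default 20%) of features with
   the highest within-group relative standard deviation (sd/mean, aggregated
   across groups);
3. variability — drop the fraction ``frac`` of features with the lowest
   interquartile range across all biological samples.

Scores are computed on raw intensities; the log2(x+1) transform is applied
after filtering.  Pooled QC samples are carried through but excluded from
every score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureTable

RSD_AGGREGATES = ("mean", "median", "max")


@dataclass
class FilterStep:
    name: str
    features_in: int
    features_out: int
    removed_ids: list

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "features_in": self.features_in,
            "features_out": self.features_out,
            "removed_ids": list(self.removed_ids),
        }


@dataclass
class FilterReport:
    """Ordered per-step audit: feature counts in/out and the ids removed."""

    steps: list = field(default_factory=list)

    def add(self, step: FilterStep) -> None:
        if self.steps and step.features_in != self.steps[-1].features_out:
            raise ValueError(
                f"step {step.name!r} input count {step.features_in} does not "
                f"match previous output {self.steps[-1].features_out}"
            )
        if step.features_out > step.features_in:
            raise ValueError("feature counts must be non-increasing")
        self.steps.append(step)

    @property
    def counts(self) -> list:
        return [(s.name, s.features_in, s.features_out) for s in self.steps]

    def to_dict(self) -> dict:
        return {"steps": [s.to_dict() for s in self.steps]}


def _check_frac(frac: float) -> None:
    if not 0 <= frac < 1:
        raise ValueError(f"frac must be in [0, 1), got {frac}")


def presence_filter(table: FeatureTable) -> tuple[FeatureTable, FilterStep]:
    """Retain features detected in every replicate of >= 1 strain x ploidy group."""
    bio = table.non_qc()
    if bio.n_samples == 0:
        raise ValueError("no non-QC samples to evaluate presence on")
    present_somewhere = np.zeros(table.n_features, dtype=bool)
    for _, group in bio.iter_groups():
        vals = group.to_numpy()
        all_detected = np.all(np.nan_to_num(vals, nan=0.0) > 0, axis=0)
        present_somewhere |= all_detected
    kept = [f for f, ok in zip(table.feature_ids, present_somewhere) if ok]
    removed = [f for f, ok in zip(table.feature_ids, present_somewhere) if not ok]
    step = FilterStep("presence", table.n_features, len(kept), removed)
    return table.select_features(kept), step


def rsd_scores(table: FeatureTable, aggregate: str = "mean") -> pd.Series:
    """Within-group relative standard deviation (sd/mean, ddof=1 sd) per
    feature, aggregated over strain x ploidy groups; zero-mean groups are
    skipped."""
    if aggregate not in RSD_AGGREGATES:
        raise ValueError(f"aggregate must be one of {RSD_AGGREGATES}")
    per_group = []
    for _, group in table.non_qc().iter_groups():
        vals = group.to_numpy(dtype=float)
        if vals.shape[0] < 2:
            raise ValueError("every strain x ploidy group needs >= 2 replicates")
        mean = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rsd = np.where(mean > 0, sd / mean, np.nan)
        per_group.append(rsd)
    stacked = np.vstack(per_group)
    if np.isnan(stacked).all(axis=0).any():
        # cannot happen after the presence filter; reachable only standalone
        raise ValueError(
            "feature with zero mean in every group; run presence_filter first"
        )
    agg = {"mean": np.nanmean, "median": np.nanmedian, "max": np.nanmax}[aggregate]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        scores = agg(stacked, axis=0)
    return pd.Series(scores, index=table.feature_ids, name="rsd")


def _drop_by_rank(
    table: FeatureTable, scores: np.ndarray, frac: float, highest: bool, name: str
) -> tuple[FeatureTable, FilterStep]:
    n = table.n_features
    k = math.ceil(frac * n)
    # stable sort: ties resolved toward the lower feature index
    order = np.argsort(-scores if highest else scores, kind="stable")
    drop = np.zeros(n, dtype=bool)
    drop[order[:k]] = True
    kept = [f for f, d in zip(table.feature_ids, drop) if not d]
    removed = [f for f, d in zip(table.feature_ids, drop) if d]
    step = FilterStep(name, n, len(kept), removed)
    return table.select_features(kept), step


def rsd_filter(
    table: FeatureTable, frac: float = 0.20, aggregate: str = "mean"
) -> tuple[FeatureTable, FilterStep]:
    """Remove the ceil(frac*N) features with the highest within-group RSD."""
    _check_frac(frac)
    scores = rsd_scores(table, aggregate).to_numpy()
    return _drop_by_rank(table, scores, frac, highest=True, name="rsd")


def iqr_scores(table: FeatureTable) -> pd.Series:
    """Per-feature interquartile range over all non-QC samples (linear-
    interpolation quantiles, raw intensity scale)."""
    bio = table.non_qc()
    if bio.n_samples < 2:
        raise ValueError("IQR filter needs >= 2 non-QC samples")
    vals = bio.data.to_numpy(dtype=float)
    q75, q25 = np.nanpercentile(vals, [75, 25], axis=0)
    return pd.Series(q75 - q25, index=table.feature_ids, name="iqr")


def iqr_filter(
    table: FeatureTable, frac: float = 0.20
) -> tuple[FeatureTable, FilterStep]:
    """Remove the ceil(frac*N) features with the lowest IQR."""
    _check_frac(frac)
    scores = iqr_scores(table).to_numpy()
    return _drop_by_rank(table, scores, frac, highest=False, name="iqr")


def log2p1_normalize(table: FeatureTable) -> FeatureTable:
    """Replace every intensity x by log2(x + 1)."""
    vals = table.data.to_numpy(dtype=float)
    if np.nan_to_num(vals, nan=0.0).min() < 0:
        raise ValueError("log2(x+1) transform requires non-negative abundances")
    transformed = pd.DataFrame(
        np.log2(vals + 1.0), index=table.data.index, columns=table.data.columns
    )
    return FeatureTable(
        transformed, table.sample_meta, table.platform, table.attrs, scale="log2"
    )


def filter_pipeline(
    table: FeatureTable,
    rsd_frac: float = 0.20,
    iqr_frac: float = 0.20,
    rsd_aggregate: str = "mean",
) -> tuple[FeatureTable, FilterReport]:
    """presence -> RSD -> IQR -> log2(x+1), with a concatenated audit report."""
    report = FilterReport()
    table, step = presence_filter(table)
    report.add(step)
    table, step = rsd_filter(table, rsd_frac, rsd_aggregate)
    report.add(step)
    table, step = iqr_filter(table, iqr_frac)
    report.add(step)
    return log2p1_normalize(table), report
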