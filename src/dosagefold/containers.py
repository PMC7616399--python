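"""Core in-memory containers shared across the pipeline.

A :class:`FeatureTable` holds a samples x features intensity matrix from one
untargeted metabolomics platform together with the sample design (strain,
ploidy, replicate, QC flag).  Flow-cytometry and gravimetric observations are
small records kept as frozen dataclasses; list-of-record and DataFrame
representations interconvert via :mod:`dosagefold.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

PLOIDY_LEVELS = ("2n", "4n")


@dataclass
class FeatureTable:
    """Samples x features abundance matrix with the sample design attached.

    Parameters
    ----------
    data
        Non-negative intensities; index = sample ids, columns = feature ids.
    sample_meta
        One row per sample (same index as ``data``) with columns
        ``strain``, ``ploidy`` (``"2n"``/``"4n"``), ``replicate`` and
        ``is_qc`` (pooled quality-control samples, excluded from filtering).
    platform
        Free-form platform tag, e.g. ``"ESI-"``, ``"ESI+"``, ``"GCMS"``.
    attrs
        Optional provenance (simulation truth, seed, config hash).
    scale
        ``"raw"`` (non-negative intensities, enforced) or ``"log2"``
        (transformed values, may be negative).
    """

    data: pd.DataFrame
    sample_meta: pd.DataFrame
    platform: str = "ESI-"
    attrs: dict = field(default_factory=dict)
    scale: str = "raw"

    def __post_init__(self) -> None:
        if len(self.data) != len(self.sample_meta):
            raise ValueError(
                f"data has {len(self.data)} rows but sample_meta has "
                f"{len(self.sample_meta)}"
            )
        if not self.data.index.equals(self.sample_meta.index):
            raise ValueError("data and sample_meta must share the same sample index")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        for col in ("strain", "ploidy", "replicate"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta missing required column {col!r}")
        if "is_qc" not in self.sample_meta.columns:
            self.sample_meta = self.sample_meta.assign(is_qc=False)
        bad = ~self.sample_meta["ploidy"].isin(PLOIDY_LEVELS)
        bad &= ~self.sample_meta["is_qc"].astype(bool)
        if bad.any():
            sample = self.sample_meta.index[bad][0]
            raise ValueError(
                f"sample {sample!r}: ploidy must be one of {PLOIDY_LEVELS}"
            )
        values = self.data.to_numpy()
        neg = (np.nan_to_num(values, nan=0.0) < 0) if self.scale == "raw" else np.zeros_like(values, bool)
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValueError(
                f"negative abundance at sample {self.data.index[i]!r}, "
                f"feature {self.data.columns[j]!r}"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def feature_ids(self) -> list:
        return list(self.data.columns)

    def non_qc(self) -> "FeatureTable":
        """Return the table restricted to biological (non-QC) samples."""
        keep = ~self.sample_meta["is_qc"].astype(bool)
        return FeatureTable(
            self.data.loc[keep], self.sample_meta.loc[keep], self.platform,
            self.attrs, self.scale,
        )

    def iter_groups(self) -> Iterator[tuple[tuple[str, str], pd.DataFrame]]:
        """Iterate over (strain, ploidy) replicate groups of non-QC samples."""
        table = self.non_qc()
        for key, idx in table.sample_meta.groupby(
            ["strain", "ploidy"], observed=True, sort=True
        ).groups.items():
            yield key, table.data.loc[idx]

    def select_features(self, feature_ids) -> "FeatureTable":
        """Column subset preserving the original ordering of ``feature_ids``."""
        return FeatureTable(
            self.data.loc[:, feature_ids], self.sample_meta, self.platform,
            self.attrs, self.scale,
        )

    def strains(self) -> list:
        meta = self.non_qc().sample_meta
        return sorted(meta["strain"].unique().tolist())


@dataclass(frozen=True)
class FlowObservation:
    """One gated flow-cytometry sample.

    ``rmass`` is the tetraploid:diploid fresh-mass ratio of the mixed sample
    (0 encodes a pure-diploid sample used to pin the G2/endoreduplication
    intercept); ``count_2C``/``count_4C`` are nucleus counts in the two
    DNA-content peaks.
    """

    strain: str
    rmass: float
    count_2C: int
    count_4C: int

    def __post_init__(self) -> None:
        if self.rmass < 0:
            raise ValueError(f"rmass must be >= 0, got {self.rmass}")
        if self.count_2C < 0 or self.count_4C < 0:
            raise ValueError("nucleus counts must be >= 0")
        if self.count_2C + self.count_4C == 0:
            raise ValueError("at least one nucleus must be counted")

    @property
    def total(self) -> int:
        return self.count_2C + self.count_4C

    @property
    def p4n_hat(self) -> float:
        """Continuity-corrected observed 4C proportion, (k + 0.5)/(n + 1)."""
        return (self.count_4C + 0.5) / (self.total + 1)


@dataclass(frozen=True)
class MassObservation:
    """A fresh-mass / dry-mass pair for one strain x ploidy sample (mg)."""

    strain: str
    ploidy: str
    m: float
    dm: float

    def __post_init__(self) -> None:
        if self.ploidy not in PLOIDY_LEVELS:
            raise ValueError(f"ploidy must be one of {PLOIDY_LEVELS}")
        if not (0 < self.dm < self.m):
            raise ValueError(
                f"dry mass must satisfy 0 < dm < m, got dm={self.dm}, m={self.m}"
            )
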