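"""Sample-by-feature matrix container shared by all pipeline stages.

The matrix is stored as a pandas DataFrame (rows = samples, columns =
features) with ``NaN`` marking missing observations. A ``scale_tag``
documents which transformations have been applied so downstream operations
can enforce their preconditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError

SCALE_TAGS = ("raw", "log", "residual", "zscore")


@dataclass
class OmicsMatrix:
    """Samples x features matrix with optional missingness.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with feature ids as columns.
        ``NaN`` entries are treated as missing.
    scale_tag
        One of ``raw``, ``log``, ``residual``, ``zscore``.
    """

    values: pd.DataFrame
    scale_tag: str = "raw"

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.scale_tag == "raw":
            vals = self.values.to_numpy(dtype=float)
            if np.any(vals[~np.isnan(vals)] <= 0):
                raise DomainError("raw-scale observed values must be > 0")

    # -- basic introspection -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Per-feature fraction of missing entries."""
        return self.values.isna().mean(axis=0)

    # -- transforms ----------------------------------------------------------
    def log(self) -> "OmicsMatrix":
        """Natural-log transform (raw scale only)."""
        if self.scale_tag != "raw":
            raise DomainError("log transform requires raw scale")
        return OmicsMatrix(np.log(self.values), scale_tag="log")

    def zscore(self) -> "OmicsMatrix":
        """Per-feature z-scores over observed entries (ddof=1)."""
        mu = self.values.mean(axis=0)
        sd = self.values.std(axis=0, ddof=1)
        z = (self.values - mu) / sd
        return OmicsMatrix(z, scale_tag="zscore")

    def subset_features(self, features) -> "OmicsMatrix":
        return OmicsMatrix(self.values[list(features)].copy(), scale_tag=self.scale_tag)

    def subset_samples(self, samples) -> "OmicsMatrix":
        return OmicsMatrix(self.values.loc[list(samples)].copy(), scale_tag=self.scale_tag)
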