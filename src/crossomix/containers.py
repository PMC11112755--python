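"""Shared data containers for feature tables and sample metadata.

An :class:`OmicsMatrix` holds a features-by-samples intensity table together
with per-feature annotation (m/z, retention time, gene symbol) and a scale
flag distinguishing raw from log2 intensities.  Missing measurements are
encoded as NaN in the value table; the boolean missingness mask is derived.

Sample metadata travels as a plain :class:`pandas.DataFrame` with one row per
profile and a small set of required columns (participant, site, time point,
visit); :func:`validate_sample_meta` enforces the contract.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

#: Columns every sample-metadata table must carry (one row per profile).
REQUIRED_META_COLUMNS = ("participant", "site", "time_point", "visit")


class CrossomixError(Exception):
    """Base class for package-specific errors."""


class InvalidConfigError(CrossomixError, ValueError):
    """A configuration value violates its documented contract."""


class DimensionError(CrossomixError, ValueError):
    """Shapes of related tables do not agree."""


@dataclasses.dataclass
class OmicsMatrix:
    """Feature-by-sample intensity matrix with annotation and a scale flag.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample id.
        NaN entries are missing measurements.
    feature_meta
        Optional per-feature annotation indexed like ``values`` with any of
        the columns ``mz`` (Da), ``rt`` (min) and ``gene_symbol``.
    scale
        ``"raw"`` for non-negative intensities, ``"log2"`` after transform.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame | None = None
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise InvalidConfigError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        if self.feature_meta is not None:
            if not self.feature_meta.index.equals(self.values.index):
                raise DimensionError("feature_meta index does not match values index")
            if "mz" in self.feature_meta:
                mz = self.feature_meta["mz"].dropna()
                if (mz <= 0).any():
                    raise InvalidConfigError("m/z values must be positive")

    # -- basic introspection -------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where a measurement is missing."""
        return self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(
            values=self.values.copy(),
            feature_meta=None if self.feature_meta is None else self.feature_meta.copy(),
            scale=self.scale,
        )

    def select_features(self, feature_ids) -> "OmicsMatrix":
        meta = None if self.feature_meta is None else self.feature_meta.loc[feature_ids]
        return OmicsMatrix(self.values.loc[feature_ids], meta, self.scale)

    def select_samples(self, sample_ids) -> "OmicsMatrix":
        return OmicsMatrix(self.values[list(sample_ids)], self.feature_meta, self.scale)

    # -- I/O (TSV dialect: rows = features, blank cell = missing) ------------
    def to_tsv(self, path, meta_path=None) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature")
        if meta_path is not None and self.feature_meta is not None:
            self.feature_meta.to_csv(meta_path, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(cls, path, meta_path=None, scale: str = "raw") -> "OmicsMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        meta = None
        if meta_path is not None and Path(meta_path).exists():
            meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(values=values, feature_meta=meta, scale=scale)


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the sample-metadata contract and return the table unchanged."""
    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise InvalidConfigError(f"sample metadata lacks required columns: {missing}")
    return meta


def canonical_occasions(sites, time_points) -> list[tuple[str, str]]:
    """Ordered (site, time point) occasions: all time points of the first site,
    then of the second, matching the repeated-measures covariance layout."""
    return [(s, t) for s in sites for t in time_points]


def occasion_index(meta: pd.DataFrame, sites, time_points) -> np.ndarray:
    """Map each profile to its canonical occasion index (0..5)."""
    order = {occ: i for i, occ in enumerate(canonical_occasions(sites, time_points))}
    try:
        return np.array([order[(s, t)] for s, t in zip(meta["site"], meta["time_point"])])
    except KeyError as exc:  # pragma: no cover - defensive
        raise InvalidConfigError(f"profile with unknown occasion: {exc}") from exc
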