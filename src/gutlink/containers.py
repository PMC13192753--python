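"""Core data containers shared across the pipeline.

Both data modalities (16S genus counts and RNA-seq gene counts) live in the
same feature-by-sample :class:`FeatureTable`; per-sample metadata lives in a
:class:`SampleFrame`.  Distances use :class:`skbio.DistanceMatrix` directly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "SampleFrame", "Ordination", "read_feature_table"]

#: allowed values of FeatureTable.kind
KINDS = ("counts", "relative_abundance", "clr", "log_cpm", "residual")


class FeatureTable:
    """A features x samples matrix with typed semantics.

    Parameters
    ----------
    data : pandas.DataFrame
        Features as rows, samples as columns. The index holds feature ids,
        the columns hold sample ids; both must be unique.
    kind : str
        One of ``counts``, ``relative_abundance``, ``clr``, ``log_cpm``,
        ``residual``.  Counts must be non-negative; relative abundances must
        sum to one per sample; CLR columns must sum to zero.
    """

    def __init__(self, data: pd.DataFrame, kind: str = "counts", *, validate: bool = True):
        if not isinstance(data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame (features x samples)")
        if kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {kind!r}")
        self.data = data.copy()
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.kind = kind
        if validate:
            self._validate()

    def _validate(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        vals = self.data.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("feature table contains NaN")
        if self.kind == "counts":
            if (vals < 0).any():
                raise ValueError("counts must be non-negative")
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
        elif self.kind == "relative_abundance":
            if (vals < 0).any():
                raise ValueError("relative abundances must be non-negative")
            sums = vals.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("relative-abundance columns must sum to 1")
        elif self.kind == "clr":
            sums = vals.sum(axis=0)
            if not np.allclose(sums, 0.0, atol=1e-6):
                raise ValueError("clr columns must sum to 0")

    # -- accessors ---------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        """Dense matrix, features x samples."""
        return self.data.to_numpy(dtype=float)

    def select_samples(self, sample_ids) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return FeatureTable(self.data[list(sample_ids)], self.kind, validate=False)

    def select_features(self, feature_ids) -> "FeatureTable":
        missing = [f for f in feature_ids if f not in self.data.index]
        if missing:
            raise KeyError(f"unknown feature ids: {missing[:5]}")
        return FeatureTable(self.data.loc[list(feature_ids)], self.kind, validate=False)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data, self.kind, validate=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        nf, ns = self.data.shape
        return f"FeatureTable(kind={self.kind!r}, {nf} features x {ns} samples)"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FeatureTable)
            and self.kind == other.kind
            and self.data.equals(other.data)
        )

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path: str | os.PathLike) -> None:
        """Write as TSV: first column feature id, header row of sample ids."""
        path = os.fspath(path)
        if not path:
            raise IOError("empty output path")
        self.data.rename_axis("feature_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, kind: str = "counts") -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        if kind == "counts":
            df = df.round().astype(np.int64)
        return cls(df, kind)


def read_feature_table(path, kind="counts") -> FeatureTable:
    """Read a feature table from TSV (features as rows)."""
    return FeatureTable.from_tsv(path, kind)


class SampleFrame:
    """Per-sample metadata: patient id, location, covariates, DNA concentration.

    Wraps a DataFrame indexed by sample id. Reserved columns: ``patient``,
    ``region``, ``dna_conc``, ``is_control``; all other columns are treated
    as covariates.
    """

    RESERVED = ("patient", "region", "dna_conc", "is_control")

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame indexed by sample id")
        self.data = data.copy()
        self.data.index = self.data.index.astype(str)
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        if "is_control" not in self.data.columns:
            self.data["is_control"] = False

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.RESERVED]

    def align(self, sample_ids) -> "SampleFrame":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples absent from metadata: {missing[:5]}")
        return SampleFrame(self.data.loc[list(sample_ids)])

    def real_samples(self) -> list[str]:
        """Sample ids that are not negative controls."""
        mask = ~self.data["is_control"].astype(bool)
        return self.data.index[mask].tolist()

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleFrame) and self.data.equals(other.data)

    def to_tsv(self, path) -> None:
        path = os.fspath(path)
        if not path:
            raise IOError("empty output path")
        self.data.rename_axis("sample_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "SampleFrame":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        if "is_control" in df.columns:
            df["is_control"] = df["is_control"].astype(bool)
        return cls(df)


@dataclass
class Ordination:
    """PCoA embedding: per-sample coordinates on positive-eigenvalue axes."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))
    proportion_explained: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.proportion_explained = np.asarray(self.proportion_explained, dtype=float)
        if self.coordinates.ndim != 2:
            raise ValueError("coordinates must be 2-D (samples x axes)")
        if len(self.sample_ids) != self.coordinates.shape[0]:
            raise ValueError("sample_ids length does not match coordinates")
        if self.eigenvalues.size and np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be non-increasing")

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.coordinates,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"PCo{i + 1}" for i in range(self.n_axes)],
        )
        df.to_csv(path, sep="\t")
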