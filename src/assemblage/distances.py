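"""Labelled square distance/similarity matrices with light validation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from ._utils import output_header

SYMMETRY_TOL = 1e-12


@dataclass
class DistanceMatrix:
    """Square symmetric matrix over labelled samples or taxa.

    ``kind`` is ``"dissimilarity"`` (zero diagonal, entries >= 0) or
    ``"similarity"`` (unit diagonal).  ``units`` documents the scale
    (e.g. ``"km"`` or ``""`` for dimensionless).
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "dissimilarity"
    units: str = ""

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if self.kind not in ("dissimilarity", "similarity"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if np.abs(self.values - self.values.T).max(initial=0.0) > SYMMETRY_TOL:
            raise ValueError("matrix is not symmetric")
        self.values = (self.values + self.values.T) / 2.0
        diag = np.diagonal(self.values)
        if self.kind == "dissimilarity":
            if np.abs(diag).max(initial=0.0) > SYMMETRY_TOL:
                raise ValueError("dissimilarity diagonal must be zero")
            if self.values.min(initial=0.0) < -SYMMETRY_TOL:
                raise ValueError("dissimilarity entries must be >= 0")
            np.fill_diagonal(self.values, 0.0)
        else:
            if np.abs(diag - 1.0).max(initial=0.0) > 1e-9:
                raise ValueError("similarity diagonal must be one")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries in scipy ``squareform`` order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)],
                              self.kind, self.units)

    def to_dissimilarity(self) -> "DistanceMatrix":
        if self.kind == "dissimilarity":
            return self
        return DistanceMatrix(list(self.labels), 1.0 - self.values,
                              "dissimilarity", self.units)

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.to_dissimilarity().values, ids=self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write(self, path, seed=None, params=None) -> None:
        with open(path, "w") as fh:
            fh.write(output_header(seed, dict(params or {}, kind=self.kind)) + "\n")
            self.to_dataframe().to_csv(fh, sep="\t", index_label="id")


def read_distance_matrix(path, kind: str = "dissimilarity", units: str = "") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return DistanceMatrix([str(c) for c in df.index], df.to_numpy(dtype=float),
                          kind, units)
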