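"""Distances between (N)RADs and distance-matrix assembly.

The working distance between two NRADs normalized to the same MaxRank R is
the Manhattan distance  d_R(a_i, a_j) = sum_r |a_ir - a_jr|.  It weights the
few large head differences and the many small tail differences of typical
NRAD pairs roughly equally.  The two-sample Kolmogorov-Smirnov statistic D on
non-normalized RADs is provided as the baseline comparator only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .normalize import NRAD
from .rad import RAD, relative_abundances

__all__ = ["DistanceMatrix", "manhattan_distance", "ks_distance", "distance_matrix"]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative matrix over a labelled set of samples."""

    labels: tuple
    values: np.ndarray
    metric: str = "manhattan"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape must match the number of labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, metric: str = "manhattan") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=tuple(df.index), values=df.to_numpy(dtype=float), metric=metric)


def manhattan_distance(a: NRAD, b: NRAD) -> float:
    """d_R between two NRADs sharing the same MaxRank R."""
    if a.R != b.R:
        raise ValueError(f"incompatible MaxRank: {a.R} != {b.R}")
    return float(np.abs(a.abundances - b.abundances).sum())


def ks_distance(rad_a: RAD, rad_b: RAD) -> float:
    """Two-sample KS statistic D between rank-indexed abundance CDFs.

    The shorter RAD's missing ranks count as zero abundance, so D is the
    Chebyshev distance between the two cumulative relative-abundance curves
    on the union of rank supports.  Baseline comparator only; the tails of
    RADs with very different richness are treated poorly by construction.
    """
    m = max(rad_a.richness, rad_b.richness)
    cdf_a = np.zeros(m)
    cdf_b = np.zeros(m)
    cdf_a[: rad_a.richness] = relative_abundances(rad_a)
    cdf_b[: rad_b.richness] = relative_abundances(rad_b)
    return float(np.abs(np.cumsum(cdf_a) - np.cumsum(cdf_b)).max())


def distance_matrix(items, metric: str = "manhattan") -> DistanceMatrix:
    """All pairwise distances of a collection of NRADs (or RADs for "ks")."""
    items = list(items)
    if not items:
        raise ValueError("empty collection")
    labels = [getattr(x, "label", "") or f"sample{i}" for i, x in enumerate(items)]
    if metric == "manhattan":
        Rs = {x.R for x in items}
        if len(Rs) > 1:
            raise ValueError(f"incompatible MaxRank values in collection: {sorted(Rs)}")
        X = np.vstack([x.abundances for x in items])
        vals = squareform(pdist(X, metric="cityblock")) if len(items) > 1 else np.zeros((1, 1))
    elif metric == "ks":
        n = len(items)
        vals = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                vals[i, j] = vals[j, i] = ks_distance(items[i], items[j])
    else:
        raise ValueError(f"unknown metric {metric!r} (use 'manhattan' or 'ks')")
    return DistanceMatrix(labels=tuple(labels), values=vals, metric=metric)
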