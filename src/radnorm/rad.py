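"""Rank abundance distributions (RADs).

A RAD is the abundance vector of a community sorted in decreasing order and
indexed by rank instead of by species identity.  It retains the full shape of
a species-abundance table while discarding taxonomy, which is what makes
communities of entirely different composition (microbiome OTUs, B-cell
receptor variants, ...) directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RAD", "build_rad", "relative_abundances", "EmptyCommunityError"]


class EmptyCommunityError(ValueError):
    """Raised when an abundance vector contains no positive entry."""


@dataclass(frozen=True)
class RAD:
    """Integer abundances per rank, strictly positive and non-increasing.

    Attributes
    ----------
    counts:
        Abundance of each rank (read counts / individuals), sorted descending.
    label:
        Sample identifier carried through downstream analyses.
    """

    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size == 0:
            raise EmptyCommunityError("empty community: RAD needs at least one rank")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise ValueError(
                    "RAD abundances must be integer counts; MaxRank normalization "
                    "draws individuals. Pre-scale relative abundances to counts first."
                )
            counts = counts.astype(np.int64)
        if np.any(counts <= 0):
            raise ValueError("RAD counts must be strictly positive (zeros are dropped by build_rad)")
        if np.any(np.diff(counts) > 0):
            raise ValueError("RAD counts must be sorted non-increasing")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def richness(self) -> int:
        """Number of observed ranks R_s."""
        return int(self.counts.size)

    @property
    def n_individuals(self) -> int:
        """Total number of individuals N_s."""
        return int(self.counts.sum())

    def __len__(self) -> int:
        return self.richness


def build_rad(abundances, label: str = "") -> RAD:
    """Build a RAD from a raw abundance vector.

    Zeros are removed (a species absent from this sample is not a rank) and
    the remaining counts are sorted in descending order.  Negative or
    fractional entries are rejected: the normalization resamples individual
    counts, so the input must be integer counts, not relative abundances.
    """
    arr = np.asarray(abundances, dtype=float)
    if arr.ndim != 1:
        raise ValueError("abundance input must be one-dimensional")
    if arr.size == 0 or not np.any(arr > 0):
        raise EmptyCommunityError(f"empty community: no positive abundance in sample {label!r}")
    if np.any(arr < 0):
        raise ValueError("negative abundances are not valid counts")
    if np.any(arr != np.floor(arr)):
        raise ValueError(
            "fractional abundances are not valid counts; if the table holds "
            "relative abundances, rescale to integer counts before building RADs"
        )
    counts = arr[arr > 0].astype(np.int64)
    counts = np.sort(counts)[::-1]
    return RAD(counts=counts, label=label)


def relative_abundances(rad: RAD) -> np.ndarray:
    """Counts divided by the sample total N_s; sums to 1, order preserved."""
    return rad.counts / rad.n_individuals
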