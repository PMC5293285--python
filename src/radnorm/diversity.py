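"""Shannon entropy and evenness of NRADs.

For NRADs the richness is the MaxRank R by construction, so Shannon evenness
J = H / log R is a rescaled entropy and the two can be used interchangeably
as diversity measures.  Entropies are in nats (natural logarithm).

The scaling relation H_R / log R ~ const (per sample) holds approximately as
long as R is not varied by more than about an order of magnitude, which is
what makes entropies computed at different MaxRanks comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy as _scipy_entropy

from .normalize import NRAD

__all__ = ["EntropyRecord", "shannon_entropy", "evenness", "entropy_table"]


@dataclass(frozen=True)
class EntropyRecord:
    label: str
    R: int
    H: float   # Shannon entropy, nats
    J: float   # evenness H / log R

    @property
    def c(self) -> float:
        """Scaling constant H_R / log R (identical to J for an NRAD)."""
        return self.J


def _abundances(nrad) -> np.ndarray:
    return nrad.abundances if isinstance(nrad, NRAD) else np.asarray(nrad, dtype=float)


def shannon_entropy(nrad) -> float:
    """H = -sum_r a_r log a_r of the mean abundance vector, in nats."""
    return float(_scipy_entropy(_abundances(nrad)))


def evenness(nrad) -> float:
    """Shannon evenness J = H / log R, in [0, 1]."""
    a = _abundances(nrad)
    if a.size < 2:
        raise ValueError("evenness needs R >= 2 (log R would vanish)")
    return shannon_entropy(a) / float(np.log(a.size))


def entropy_table(nrads) -> pd.DataFrame:
    """Tidy table (label, R, H, J) for a collection of NRADs."""
    rows = [
        {"label": n.label, "R": n.R, "H": shannon_entropy(n), "J": evenness(n)}
        for n in nrads
    ]
    return pd.DataFrame(rows, columns=["label", "R", "H", "J"])
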