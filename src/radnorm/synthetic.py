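"""Synthetic community and dataset generators.

Emulates the statistical regimes the analyses are designed for: communities
whose richness spans orders of magnitude, true abundance structure drawn from
geometric / log-normal / broken-stick / uniform laws, multinomial sampling at
a finite sequencing depth, saturating entropy-vs-age trajectories with
additive Gaussian noise, and two-class NRAD sets whose discriminative signal
is confined to a chosen rank band.

Everything is driven by explicit seeds; the same spec and seed reproduce the
same data bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .models import broken_stick_nrad, entropy_age_curve
from .normalize import NRAD, maxrank_normalize
from .rad import RAD, build_rad

__all__ = [
    "CommunitySpec",
    "true_abundances",
    "generate_community",
    "generate_communities",
    "generate_entropy_age_dataset",
    "middle_band_shapes",
    "generate_labeled_nrad_set",
]

FAMILIES = ("uniform", "geometric", "log-normal", "broken-stick")


@dataclass(frozen=True)
class CommunitySpec:
    """Distribution family + parameters + sequencing depth for one community."""

    family: str
    richness: int
    depth: int
    params: dict = field(default_factory=dict)
    seed: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.richness < 2:
            raise ValueError("richness must be >= 2")
        if self.depth < self.richness:
            raise ValueError("sequencing depth must be at least the richness")


def true_abundances(spec: CommunitySpec, rng=None) -> np.ndarray:
    """True (pre-sampling) relative abundances of the community, sorted."""
    S = spec.richness
    if spec.family == "uniform":
        p = np.full(S, 1.0 / S)
    elif spec.family == "geometric":
        q = spec.params.get("p", 0.01)
        if not 0 < q < 1:
            raise ValueError("geometric family needs 0 < p < 1")
        p = q * (1 - q) ** np.arange(S)
        p /= p.sum()
    elif spec.family == "log-normal":
        sigma = spec.params.get("sigma", 1.5)
        mu = spec.params.get("mu", 0.0)
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(
            spec.seed if rng is None else rng
        )
        x = rng.lognormal(mean=mu, sigma=sigma, size=S)
        p = np.sort(x)[::-1]
        p /= p.sum()
    elif spec.family == "broken-stick":
        p = broken_stick_nrad(S).abundances.copy()
    else:  # pragma: no cover - guarded by spec validation
        raise ValueError(spec.family)
    return p


def generate_community(spec: CommunitySpec, rng=None) -> RAD:
    """Multinomial sample of ``depth`` individuals from the true abundances.

    Species that receive zero reads are dropped, so the observed richness can
    fall below the spec richness at shallow depth -- exactly as in real
    sequencing data.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(
        spec.seed if rng is None else rng
    )
    p = true_abundances(spec, rng=rng)
    counts = rng.multinomial(spec.depth, p)
    return build_rad(counts, label=spec.label or f"{spec.family}-S{spec.richness}")


def generate_communities(specs, seed: int | None = None) -> list[RAD]:
    """Generate a set of communities, one independent stream per spec."""
    specs = list(specs)
    streams = np.random.SeedSequence(seed).spawn(len(specs))
    return [generate_community(s, rng=np.random.default_rng(ss)) for s, ss in zip(specs, streams)]


def generate_entropy_age_dataset(
    params=(3.41, 5.82, 0.69),
    n: int = 181,
    noise_sd: float = 0.5,
    age_range=(0.03, 80.0),
    rng=None,
):
    """(ages, entropies) drawn around the saturating entropy-growth curve.

    ``params`` is (H0, Hmax, lambda).  Ages are log-uniform over ``age_range``
    (years), mirroring the log-age design of developmental cohorts where most
    change happens early in life; entropies are the model curve plus additive
    Gaussian noise.  Defaults emulate a Malawi/Venezuela-sized gut-microbiome
    cohort: 181 samples, ages from a few weeks to 80 years.
    """
    H0, Hmax, lam = params
    if not (Hmax > H0 > 0 and lam > 0):
        raise ValueError("need Hmax > H0 > 0 and lambda > 0")
    if n < 4:
        raise ValueError("need at least 4 samples")
    lo, hi = age_range
    if not (0 < lo < hi):
        raise ValueError("invalid age range")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    ages = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    entropies = entropy_age_curve(ages, H0, lam, Hmax)
    if noise_sd > 0:
        entropies = entropies + rng.normal(0.0, noise_sd, size=n)
    return ages, entropies


def middle_band_shapes(
    richness: int = 300,
    band=(40, 160),
    strength: float = 0.9,
    decay: float = 0.03,
):
    """Two true-abundance laws that differ only inside a middle rank band.

    The base law is a slow geometric decay exp(-decay * r).  The second
    class multiplies the band by exp(eps * s(x)) where s is a sine bulge/sag
    (positive in the first half-band, negative in the second) windowed to
    have zero value and slope at the band edges, then rescales the band to
    keep its total mass.  The amplitude eps is ``strength`` times the
    largest value for which the perturbed vector stays non-increasing, so
    both laws are valid sorted abundance vectors with no re-sorting.
    Outside the band the two laws are exactly identical and any learnable
    class signal is strictly confined to the band.
    """
    lo, hi = band
    if not (0 <= lo < hi <= richness):
        raise ValueError("band must lie inside [0, richness)")
    if not 0 < strength <= 1:
        raise ValueError("strength must be in ]0, 1]")
    m = hi - lo
    base = np.exp(-decay * np.arange(richness))
    base /= base.sum()
    # windowed sine: zero value and slope at both band edges, so the
    # mass-conserving rescale cannot break the sorted order there
    x = np.arange(m)
    s = np.sin(2.0 * np.pi * x / m) * np.sin(np.pi * x / m)
    # monotonicity budget: per-rank increase of eps*s must stay below decay
    eps = strength * decay / np.abs(np.diff(s)).max()
    band_mass = base[lo:hi].sum()
    while True:
        other = base.copy()
        other[lo:hi] *= np.exp(eps * s)
        other[lo:hi] *= band_mass / other[lo:hi].sum()
        if not np.any(np.diff(other) > 0):
            return base, other
        eps *= 0.9  # safety net; the budget normally suffices


def generate_labeled_nrad_set(
    n_per_class: int,
    class_shapes,
    R: int,
    rng=None,
    depth: int = 300_000,
    n_reps: int = 5,
    rank_noise_sd: float = 0.08,
):
    """Two-class NRAD set for classification experiments.

    For each sample the class's true abundances are jittered rank-wise by
    log-normal noise (sd ``rank_noise_sd`` on the log scale), re-sorted and
    renormalized, then ``depth`` individuals are drawn multinomially and the
    observed RAD is MaxRank-normalized to R.  Returns (nrads, labels).
    """
    shape_a, shape_b = (np.asarray(s, dtype=float) for s in class_shapes)
    if n_per_class < 2:
        raise ValueError("need n_per_class >= 2 to cross-validate")
    if shape_a.shape == shape_b.shape and np.allclose(shape_a, shape_b):
        warnings.warn("identical class shapes: classification signal is absent (kappa ~ 0)")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    nrads, labels = [], []
    for cls, shape in (("A", shape_a), ("B", shape_b)):
        for i in range(n_per_class):
            p = shape * rng.lognormal(0.0, rank_noise_sd, size=shape.size)
            p = np.sort(p)[::-1]
            p /= p.sum()
            rad = build_rad(rng.multinomial(depth, p), label=f"{cls}{i}")
            nrads.append(maxrank_normalize(rad, R, n_reps=n_reps, seed=rng))
            labels.append(cls)
    return nrads, np.asarray(labels)
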