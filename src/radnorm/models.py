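"""Reference abundance models and the entropy-vs-age growth model.

* Broken stick (MacArthur): a unit resource split at R-1 uniform points; the
  expected sorted segment lengths a_r = (1/R) * sum_{k=r}^{R} 1/k form a
  parameter-free reference NRAD.
* Geometric distribution: maximum-entropy law for per-category counts with a
  fixed mean, fitted by maximum likelihood with a one-sample KS consistency
  test.  It is the discrete counterpart of the exponential law that generates
  the broken-stick RAD.
* Saturating entropy growth  H_R(t) = H_max - (H_max - H0) exp(-lambda t):
  diversity of a developing community (e.g. an infant gut microbiome) rising
  from a low post-birth entropy H0 towards an asymptote H_max at rate lambda
  per year, fitted by Levenberg-Marquardt least squares with Jacobian-based
  90% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .normalize import NRAD

__all__ = [
    "GeometricFit",
    "EntropyAgeModel",
    "FitError",
    "broken_stick_nrad",
    "simulate_broken_stick",
    "fit_geometric",
    "entropy_age_curve",
    "fit_entropy_age_model",
    "DEFAULT_ENTROPY_AGE_INIT",
]

# data-scale rough starting estimate for gut-microbiome style entropy data
DEFAULT_ENTROPY_AGE_INIT = (3.5, 0.19, 6.0)  # (H0, lambda, Hmax)


class FitError(RuntimeError):
    """A model fit failed to converge; carries the optimizer diagnostics."""


def broken_stick_nrad(R: int, label: str = "broken-stick") -> NRAD:
    """Expected broken-stick relative abundances a_r = (1/R) sum_{k=r}^R 1/k."""
    if R < 2:
        raise ValueError("broken stick needs R >= 2")
    inv = 1.0 / np.arange(1, R + 1)
    a = np.cumsum(inv[::-1])[::-1] / R
    a /= a.sum()  # telescoping sum is 1 analytically; tidy up roundoff
    return NRAD(a, a.copy(), a.copy(), n_reps=1, seed=None, label=label)


def simulate_broken_stick(R: int, n_sticks: int, rng) -> np.ndarray:
    """Monte-Carlo oracle: mean sorted segment lengths of n_sticks broken sticks."""
    if R < 2:
        raise ValueError("broken stick needs R >= 2")
    if n_sticks < 1:
        raise ValueError("n_sticks must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    cuts = np.sort(rng.random((n_sticks, R - 1)), axis=1)
    bounds = np.concatenate(
        [np.zeros((n_sticks, 1)), cuts, np.ones((n_sticks, 1))], axis=1
    )
    segments = np.sort(np.diff(bounds, axis=1), axis=1)[:, ::-1]
    return segments.mean(axis=0)


@dataclass(frozen=True)
class GeometricFit:
    """ML fit of a geometric law (support 1, 2, ...) to positive counts."""

    p_hat: float
    ks_p: float
    n: int


def fit_geometric(counts) -> GeometricFit:
    """Fit Geometric(p) on support {1, 2, ...} by maximum likelihood.

    The ML estimate is p_hat = 1 / mean(counts).  Consistency is assessed by
    a one-sample KS test against Geometric(p_hat): the statistic D is the
    supremum of |ecdf - cdf| evaluated on the integer support (the naive
    continuous-data formula overstates D badly when counts are tied), and the
    p-value uses the continuous-null KS distribution, which is conservative
    for discrete data and uses the plug-in estimate; borderline rejections
    should therefore not be over-interpreted.
    """
    x = np.asarray(counts)
    if x.size == 0:
        raise ValueError("empty count vector")
    if np.any(x < 1) or np.any(x != np.floor(x)):
        raise ValueError("geometric fit needs integer counts >= 1")
    n = int(x.size)
    p_hat = float(1.0 / x.mean())
    if p_hat >= 1.0:
        # all counts are 1: the fitted law is degenerate at 1 and fits exactly
        return GeometricFit(p_hat=1.0, ks_p=1.0, n=n)
    support = np.arange(1, x.max() + 1)
    ecdf = np.searchsorted(np.sort(x), support, side="right") / n
    cdf = stats.geom(p_hat).cdf(support)
    D = float(np.abs(ecdf - cdf).max())
    ks_p = float(stats.kstwo.sf(D, n))
    return GeometricFit(p_hat=p_hat, ks_p=ks_p, n=n)


def entropy_age_curve(t, H0: float, lam: float, Hmax: float):
    """H_R(t) = H_max - (H_max - H0) * exp(-lambda * t)."""
    return Hmax - (Hmax - H0) * np.exp(-lam * np.asarray(t, dtype=float))


@dataclass(frozen=True)
class EntropyAgeModel:
    """Fitted saturating-growth model of NRAD entropy versus age."""

    H0: float
    Hmax: float
    lam: float
    ci_half_widths: dict = field(default_factory=dict)  # 90% CI half-widths per parameter
    r2: float = float("nan")
    n: int = 0
    R: int | None = None

    def predict(self, t):
        return entropy_age_curve(t, self.H0, self.lam, self.Hmax)


def fit_entropy_age_model(
    entropies,
    ages,
    init=DEFAULT_ENTROPY_AGE_INIT,
    R: int | None = None,
) -> EntropyAgeModel:
    """Least-squares fit of the entropy growth model to (entropy, age) pairs.

    Uses the Levenberg-Marquardt algorithm; 90% confidence half-widths come
    from the parameter covariance estimated from the Jacobian at the optimum
    (Student t quantile with n - 3 degrees of freedom).  Raises FitError with
    diagnostics instead of returning a silently unconverged model.
    """
    H = np.asarray(entropies, dtype=float)
    t = np.asarray(ages, dtype=float)
    if H.shape != t.shape or H.ndim != 1:
        raise ValueError("entropies and ages must be 1-D vectors of equal length")
    if H.size < 4:
        raise ValueError("need at least 4 (entropy, age) pairs to fit 3 parameters")
    try:
        popt, pcov, infodict, mesg, ier = optimize.curve_fit(
            entropy_age_curve, t, H, p0=np.asarray(init, dtype=float),
            method="lm", maxfev=10000, full_output=True,
        )
    except RuntimeError as exc:
        raise FitError(f"entropy-age model fit failed: {exc}") from exc
    if ier not in (1, 2, 3, 4) or not np.all(np.isfinite(popt)):
        raise FitError(f"entropy-age model fit did not converge: {mesg}")
    if not np.all(np.isfinite(pcov)):
        raise FitError("entropy-age model fit has singular Jacobian; CIs undefined")
    H0, lam, Hmax = (float(v) for v in popt)
    se = np.sqrt(np.diag(pcov))
    tq = float(stats.t.ppf(0.95, df=max(H.size - 3, 1)))
    ci = {"H0": tq * float(se[0]), "lambda": tq * float(se[1]), "Hmax": tq * float(se[2])}
    resid = H - entropy_age_curve(t, *popt)
    ss_tot = float(((H - H.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    return EntropyAgeModel(H0=H0, Hmax=Hmax, lam=lam, ci_half_widths=ci,
                           r2=r2, n=int(H.size), R=R)
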