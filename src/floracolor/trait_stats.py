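"""Per-channel colour-distribution statistics and model adequacy.

Each segmented specimen yields three samples (L*, a*, b*).  A colour trait
is recorded as the two-parameter Gaussian summary (mean, SD) per channel,
with skewness and kurtosis to flag departures, and a one-sample
Kolmogorov–Smirnov test of whether the fitted model is an adequate
description of the observed pixel distribution.  Skew-normal (3-parameter)
and beta (4-parameter, on a declared finite support) alternatives are
available to check whether the extra parameters are warranted.

Conventions
-----------
* SD uses the n-1 denominator.
* Skewness is m3 / m2^(3/2) and kurtosis m4 / m2^2 with *population*
  central moments — i.e. **non-excess (Pearson) kurtosis, normal = 3**.
* KS p-values use the asymptotic Kolmogorov distribution.  Note the
  Lilliefors caveat: when the model's parameters are estimated from the
  same sample, these p-values are anti-conservative.  A parametric
  bootstrap p-value is available via ``n_bootstrap``.

Species-level traits are the unweighted mean of per-specimen channel means,
with the SD across specimen means (n-1) — the "mean ± SD" trait-table
shape.  A protocol warning is raised below five specimens (trait protocols
recommend at least five, preferably ten individuals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .colorspace import PixelCloudLab

__all__ = [
    "FittedDistribution",
    "ChannelTraits",
    "ColorTraitSummary",
    "DEFAULT_SUPPORTS",
    "moments_summary",
    "fit_distribution",
    "ks_adequacy",
    "summarize_specimen",
    "summarize_species",
    "pooled_pixel_summary",
]

#: Declared finite supports for beta fits.  a*/b* use [-128, 128]: true
#: sRGB-gamut extremes exceed +-100, so a nominal [-100, 100] support would
#: place valid samples outside the model.
DEFAULT_SUPPORTS = {"L": (0.0, 100.0), "a": (-128.0, 128.0), "b": (-128.0, 128.0)}

_BOUNDARY_EPS = 1e-9


@dataclass
class FittedDistribution:
    """A fitted per-channel colour model with a computable CDF."""

    family: str  # "gaussian" | "skew_normal" | "beta"
    params: dict
    support: tuple | None = None
    log_likelihood: float = float("nan")

    def _frozen(self):
        if self.family == "gaussian":
            return stats.norm(self.params["mu"], self.params["sigma"])
        if self.family == "skew_normal":
            return stats.skewnorm(self.params["alpha"], loc=self.params["xi"], scale=self.params["omega"])
        if self.family == "beta":
            lo, hi = self.support
            return stats.beta(self.params["alpha"], self.params["beta"], loc=lo, scale=hi - lo)
        raise ValueError(f"unknown family {self.family!r}")

    def cdf(self, x):
        return self._frozen().cdf(x)

    def rvs(self, size, rng):
        return self._frozen().rvs(size=size, random_state=rng)


def moments_summary(samples) -> tuple:
    """(mean, sd, skewness, kurtosis) of a channel sample.

    SD uses n-1; skewness and kurtosis use population central moments
    (kurtosis non-excess, normal -> 3).  Zero-variance samples yield NaN
    skewness/kurtosis with a warning.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D sample with n >= 2")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        warnings.warn("zero variance: skewness and kurtosis are undefined", stacklevel=2)
        return mean, sd, float("nan"), float("nan")
    skew = float(stats.skew(x, bias=True))
    kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    return mean, sd, skew, kurt


def _skewnorm_moment_start(x: np.ndarray) -> tuple:
    """Method-of-moments starting point for the skew-normal MLE."""
    g1 = stats.skew(x, bias=True)
    # |skewness| of a skew-normal is bounded by ~0.9953
    g1 = float(np.clip(g1, -0.99, 0.99))
    r = (2.0 * abs(g1) / (4.0 - np.pi)) ** (1.0 / 3.0)
    delta = np.sign(g1) * r / np.sqrt(1.0 + r**2) * np.sqrt(np.pi / 2.0)
    delta = float(np.clip(delta, -0.995, 0.995))
    alpha = delta / np.sqrt(1.0 - delta**2)
    sd = x.std(ddof=1)
    omega = sd / np.sqrt(max(1.0 - 2.0 * delta**2 / np.pi, 1e-6))
    xi = x.mean() - omega * delta * np.sqrt(2.0 / np.pi)
    return alpha, xi, omega


def fit_distribution(samples, family: str = "gaussian", support: tuple | None = None) -> FittedDistribution:
    """Fit a gaussian (moments), skew-normal (MLE) or beta (MLE) model.

    Beta fits rescale the sample onto (0, 1) over the declared *support*
    (required); samples exactly at the support boundary are nudged inward
    by 1e-9.  Skew-normal and beta require n >= 8.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D sample with n >= 2")
    if family == "gaussian":
        mu, sigma = float(x.mean()), float(x.std(ddof=1))
        if sigma <= 0:
            raise ValueError("cannot fit a gaussian to a zero-variance sample")
        fit = FittedDistribution("gaussian", {"mu": mu, "sigma": sigma})
    elif family == "skew_normal":
        if x.size < 8:
            raise ValueError("skew-normal fit needs n >= 8")
        a0, xi0, w0 = _skewnorm_moment_start(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, xi, w = stats.skewnorm.fit(x, a0, loc=xi0, scale=w0)
        if not np.isfinite([a, xi, w]).all() or w <= 0:
            raise RuntimeError(f"skew-normal fit did not converge (got alpha={a}, xi={xi}, omega={w})")
        fit = FittedDistribution("skew_normal", {"alpha": float(a), "xi": float(xi), "omega": float(w)})
    elif family == "beta":
        if x.size < 8:
            raise ValueError("beta fit needs n >= 8")
        if support is None:
            raise ValueError("beta fit requires a declared finite support")
        lo, hi = support
        if x.min() < lo or x.max() > hi:
            raise ValueError(f"samples outside declared support [{lo}, {hi}]")
        u = (x - lo) / (hi - lo)
        n_bound = int(((u <= 0) | (u >= 1)).sum())
        if n_bound:
            warnings.warn(f"{n_bound} sample(s) at the support boundary nudged inward by {_BOUNDARY_EPS}", stacklevel=2)
            u = np.clip(u, _BOUNDARY_EPS, 1.0 - _BOUNDARY_EPS)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, b, _, _ = stats.beta.fit(u, floc=0.0, fscale=1.0)
        if not np.isfinite([a, b]).all() or a <= 0 or b <= 0:
            raise RuntimeError(f"beta fit did not converge (got alpha={a}, beta={b})")
        fit = FittedDistribution("beta", {"alpha": float(a), "beta": float(b)}, support=(float(lo), float(hi)))
    else:
        raise ValueError(f"unknown family {family!r}")
    with np.errstate(divide="ignore"):
        fit.log_likelihood = float(np.sum(fit._frozen().logpdf(x)))
    return fit


def ks_adequacy(
    samples,
    fitted: FittedDistribution,
    alpha: float = 0.05,
    n_bootstrap: int = 0,
    seed=None,
) -> tuple:
    """One-sample Kolmogorov–Smirnov test of the fitted model.

    Returns ``(D, p, adequate)`` where ``adequate`` is True when the null
    (sample drawn from the fitted model) is *not* rejected at *alpha*.
    By default p comes from the asymptotic Kolmogorov distribution; with
    ``n_bootstrap > 0`` a parametric-bootstrap p-value is computed instead
    (refitting the same family on each synthetic sample).
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one sample")
    D = float(stats.kstest(x, fitted.cdf).statistic)
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_bootstrap):
            sim = fitted.rvs(x.size, rng)
            refit = fit_distribution(sim, fitted.family, support=fitted.support)
            if stats.kstest(sim, refit.cdf).statistic >= D:
                exceed += 1
        p = (exceed + 1) / (n_bootstrap + 1)
    else:
        p = float(stats.kstwobign.sf(np.sqrt(x.size) * D))
    return D, float(p), p >= alpha


@dataclass
class ChannelTraits:
    mean: float
    sd: float
    skewness: float
    kurtosis: float
    ks_D: float
    ks_p: float
    family: str = "gaussian"
    params: dict = field(default_factory=dict)


@dataclass
class ColorTraitSummary:
    """Trait-table row for one specimen (or one species, across specimens)."""

    species: str
    part: str
    n: int  # specimens for a species row, pixels for a specimen row
    channels: dict  # "L"/"a"/"b" -> ChannelTraits
    specimen_id: str = ""
    n_pixels: int = 0

    def as_row(self) -> dict:
        row = {"species": self.species, "part": self.part, "n": self.n}
        for ch, t in self.channels.items():
            row.update(
                {
                    f"{ch}_mean": t.mean,
                    f"{ch}_sd": t.sd,
                    f"{ch}_skewness": t.skewness,
                    f"{ch}_kurtosis": t.kurtosis,
                    f"{ch}_ks_D": t.ks_D,
                    f"{ch}_ks_p": t.ks_p,
                }
            )
        return row


def summarize_specimen(
    cloud: PixelCloudLab,
    family: str = "gaussian",
    alpha: float = 0.05,
    n_bootstrap: int = 0,
    seed=None,
) -> ColorTraitSummary:
    """Per-channel moments, model fit and KS adequacy for one pixel cloud."""
    channels = {}
    for i, ch in enumerate("Lab"):
        x = cloud.points[:, i]
        mean, sd, skew, kurt = moments_summary(x)
        if sd > 0:
            fit = fit_distribution(x, family, support=DEFAULT_SUPPORTS.get(ch))
            D, p, _ = ks_adequacy(x, fit, alpha=alpha, n_bootstrap=n_bootstrap, seed=seed)
            fam, params = fit.family, fit.params
        else:
            D, p, fam, params = float("nan"), float("nan"), family, {}
        channels[ch] = ChannelTraits(mean, sd, skew, kurt, D, p, fam, params)
    return ColorTraitSummary(
        species=cloud.species,
        part=cloud.part,
        n=cloud.n,
        channels=channels,
        specimen_id=cloud.specimen_id,
        n_pixels=cloud.n,
    )


def summarize_species(specimen_summaries) -> ColorTraitSummary:
    """Species mean ± SD across specimen channel means (n-1 SD)."""
    summaries = list(specimen_summaries)
    if not summaries:
        raise ValueError("need at least one specimen summary")
    if len(summaries) < 5:
        warnings.warn(
            f"only {len(summaries)} specimen(s); trait protocols recommend at least 5, preferably 10",
            stacklevel=2,
        )
    channels = {}
    for ch in "Lab":
        means = np.array([s.channels[ch].mean for s in summaries])
        sd = float(means.std(ddof=1)) if means.size > 1 else float("nan")
        channels[ch] = ChannelTraits(
            mean=float(means.mean()),
            sd=sd,
            skewness=float("nan"),
            kurtosis=float("nan"),
            ks_D=float(np.nanmean([s.channels[ch].ks_D for s in summaries])),
            ks_p=float("nan"),
        )
    return ColorTraitSummary(
        species=summaries[0].species,
        part=summaries[0].part,
        n=len(summaries),
        channels=channels,
        n_pixels=int(sum(s.n_pixels for s in summaries)),
    )


def pooled_pixel_summary(clouds) -> ColorTraitSummary:
    """Alternative species summary pooling all pixels across specimens."""
    clouds = list(clouds)
    if not clouds:
        raise ValueError("need at least one cloud")
    pooled = PixelCloudLab(
        points=np.vstack([c.points for c in clouds]),
        species=clouds[0].species,
        part=clouds[0].part,
        specimen_id="pooled",
    )
    return summarize_specimen(pooled)
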