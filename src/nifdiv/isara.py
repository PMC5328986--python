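"""Isotopic acetylene reduction assay (ISARA) and ARA rate fitting.

The ISARA partitions nitrogenase activity between canonical
Mo-nitrogenase and the alternative (Fe-only or V) isozymes using the
expressed carbon kinetic isotope effect of acetylene reduction,

    eps_AR = delta13C(acetylene) - delta13C(ethylene)   [per mil, V-PDB]

and a two-endmember linear mixing model

    f_alt = (eps_Mo - eps_AR) / (eps_Mo - eps_alt),

where the pure-isozyme endmembers are eps_Mo = 13.8 +/- 0.3,
eps_V = 7.9 +/- 0.2 and eps_Fe = 6.2 +/- 0.2 per mil (SE).  Because
eps_Fe < eps_V, the 100% Fe-only assumption yields the smallest f_alt
for any eps_AR between the endmembers and is therefore the conservative
lower bound on alternative-nitrogenase activity.

A single tracer cannot unmix three endmembers simultaneously, so the two
assumptions (Fe_only, V_only) are reported separately.  Uncertainty is
propagated by Monte Carlo with independent Gaussians at the stated SEs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

FE_ONLY = "Fe_only"
V_ONLY = "V_only"


class IsaraError(ValueError):
    pass


@dataclass(frozen=True)
class Endmembers:
    """Pure-isozyme 13C fractionation values (per mil) with SEs."""

    eps_Mo: float = 13.8
    eps_Mo_se: float = 0.3
    eps_V: float = 7.9
    eps_V_se: float = 0.2
    eps_Fe: float = 6.2
    eps_Fe_se: float = 0.2

    def __post_init__(self) -> None:
        if not (self.eps_Fe < self.eps_V < self.eps_Mo):
            raise IsaraError("expected eps_Fe < eps_V < eps_Mo")
        if min(self.eps_Mo_se, self.eps_V_se, self.eps_Fe_se) < 0:
            raise IsaraError("endmember SEs must be >= 0")

    def eps_alt(self, assumption: str) -> tuple[float, float]:
        if assumption == FE_ONLY:
            return self.eps_Fe, self.eps_Fe_se
        if assumption == V_ONLY:
            return self.eps_V, self.eps_V_se
        raise IsaraError(f"unknown assumption {assumption!r}")


@dataclass(frozen=True)
class IsotopeSample:
    sample_id: str
    delta13C_acetylene: float
    delta13C_ethylene: float
    replicate: int = 1


@dataclass(frozen=True)
class TimeCourse:
    sample_id: str
    times: list[float]  # hours, strictly increasing
    ethylene: list[float]  # ppmv

    def __post_init__(self) -> None:
        if len(self.times) != len(self.ethylene):
            raise IsaraError("times and ethylene must have equal length")
        if len(self.times) < 3:
            raise IsaraError("a time course needs at least 3 points")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise IsaraError("times must be strictly increasing")
        if any(e < 0 for e in self.ethylene):
            raise IsaraError("ethylene concentrations must be >= 0")


@dataclass(frozen=True)
class ARARate:
    slope: float  # ppmv per hour
    intercept: float  # ppmv
    r_squared: float
    n_points_used: int


@dataclass(frozen=True)
class MixingResult:
    eps_ar: float
    assumption: str
    f_alt: float
    ci95: tuple[float, float]
    n_mc: int
    seed: int


def fit_ara_rate(tc: TimeCourse, n_points: int = 3) -> ARARate:
    """OLS acetylene-reduction rate over the first ``n_points`` samples."""
    if len(tc.times) < n_points:
        raise IsaraError(f"time course has fewer than {n_points} points")
    t = np.asarray(tc.times[:n_points], dtype=float)
    y = np.asarray(tc.ethylene[:n_points], dtype=float)
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
    return ARARate(float(slope), float(intercept), float(r2), n_points)


def epsilon_ar(sample: IsotopeSample) -> float:
    """Expressed fractionation: delta13C(acetylene) - delta13C(ethylene)."""
    d_ace, d_eth = sample.delta13C_acetylene, sample.delta13C_ethylene
    if d_ace is None or d_eth is None or not np.isfinite([d_ace, d_eth]).all():
        raise IsaraError("both delta13C values must be finite")
    return float(d_ace - d_eth)


def mean_epsilon_ar(samples: list[IsotopeSample]) -> tuple[float, float]:
    """Per-replicate eps_AR averaged across an experiment; SE = SD/sqrt(n)."""
    vals = np.array([epsilon_ar(s) for s in samples])
    if len(vals) == 0:
        raise IsaraError("no samples")
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return float(vals.mean()), se


def fraction_alternative(
    eps_ar: float, em: Endmembers | None = None, assumption: str = FE_ONLY
) -> float:
    """Two-endmember mixing: f = (eps_Mo - eps_AR)/(eps_Mo - eps_alt),
    clamped to [0, 1] (a warning is issued for overshoots beyond
    [-0.05, 1.05], which signal inconsistent endmembers)."""
    em = em or Endmembers()
    eps_alt, _ = em.eps_alt(assumption)
    denom = em.eps_Mo - eps_alt
    if denom == 0:
        raise IsaraError("degenerate endmembers: eps_Mo equals eps_alt")
    f = (em.eps_Mo - eps_ar) / denom
    if f < -0.05 or f > 1.05:
        warnings.warn(
            f"unclamped mixing fraction {f:.3f} far outside [0, 1]; "
            "check eps_AR and endmember values",
            stacklevel=2,
        )
    return float(min(1.0, max(0.0, f)))


def mc_uncertainty(
    eps_ar_mean: float,
    eps_ar_se: float,
    em: Endmembers | None = None,
    assumption: str = FE_ONLY,
    n_mc: int = 10_000,
    seed: int = 0,
) -> MixingResult:
    """Monte-Carlo propagation of eps_AR and endmember SEs.

    Draws each quantity from an independent Gaussian, computes the clamped
    mixing fraction per draw, and reports the mean with the central 95%
    interval.  SE = 0 collapses a quantity to its point value.
    """
    em = em or Endmembers()
    if n_mc < 1000:
        raise IsaraError("n_mc must be >= 1000")
    if eps_ar_se < 0:
        raise IsaraError("eps_ar_se must be >= 0")
    eps_alt, eps_alt_se = em.eps_alt(assumption)
    rng = np.random.default_rng(seed)
    ar = rng.normal(eps_ar_mean, eps_ar_se, n_mc)
    mo = rng.normal(em.eps_Mo, em.eps_Mo_se, n_mc)
    alt = rng.normal(eps_alt, eps_alt_se, n_mc)
    denom = mo - alt
    denom[denom == 0] = np.nan
    f = np.clip((mo - ar) / denom, 0.0, 1.0)
    f = f[np.isfinite(f)]
    lo, hi = np.percentile(f, [2.5, 97.5])
    return MixingResult(
        eps_ar=float(eps_ar_mean),
        assumption=assumption,
        f_alt=float(f.mean()),
        ci95=(float(lo), float(hi)),
        n_mc=n_mc,
        seed=seed,
    )
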