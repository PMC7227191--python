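"""Mismatch-distribution demography.

The mismatch distribution is the frequency spectrum of pairwise nucleotide
differences over all sequence pairs. Under demographic equilibrium it follows
the geometric law F_j(theta) = theta^j / (theta+1)^(j+1); under a sudden
(stepwise) expansion from scaled size theta0 to theta1 at tau mutational time
units ago it follows the classic transient solution, which this module writes
with regularised incomplete gamma functions:

    F_j(tau, theta0, theta1) = F_j(theta1) * P(j+1, tau (1 + 1/theta1))
        + exp(-tau (1 + 1/theta1)) * sum_{i<=j} tau^(j-i)/(j-i)! F_i(theta0)

where P is the regularised lower incomplete gamma function. The limits are
the equilibrium spectra at theta0 (tau -> 0) and theta1 (tau -> infinity).

Fit quality is summarised by SSD (sum of squared deviations between observed
and fitted spectra) and Harpending's raggedness index
r = sum (x_i - x_{i-1})^2 (smooth, unimodal spectra — the expansion signature
— give small r). Significance of both comes from a parametric bootstrap:
coalescent samples simulated under the fitted model, each refitted with the
same optimiser settings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from . import coalescent
from .diversity import DistanceMatrix

__all__ = [
    "MismatchSpectrum",
    "ExpansionFit",
    "mismatch_spectrum",
    "equilibrium_mismatch",
    "sudden_expansion_mismatch",
    "fit_sudden_expansion",
    "raggedness",
    "mismatch_pvalues",
]


@dataclass
class MismatchSpectrum:
    """Relative frequencies of pairwise-difference classes 0..d."""

    x: np.ndarray  # frequencies, sums to 1
    pair_count: int

    @property
    def d_max(self) -> int:
        return len(self.x) - 1

    @property
    def mean(self) -> float:
        return float(np.dot(np.arange(len(self.x)), self.x))


@dataclass
class ExpansionFit:
    tau: float
    theta0: float
    theta1: float
    expected: np.ndarray  # model spectrum over the comparison support
    support: int  # classes 0..support compared
    ssd: float
    r: float
    theta1_cap: float
    converged: bool
    renormalized: bool = True


def mismatch_spectrum(dist: DistanceMatrix | np.ndarray) -> MismatchSpectrum:
    """Tabulate pairwise differences over all unordered pairs."""
    d = dist.d if isinstance(dist, DistanceMatrix) else np.asarray(dist)
    n = d.shape[0]
    if n < 2:
        raise ValueError("insufficient sequences: need n >= 2")
    iu = np.triu_indices(n, k=1)
    vals = d[iu].astype(int)
    counts = np.bincount(vals)
    return MismatchSpectrum(counts / counts.sum(), pair_count=len(vals))


def equilibrium_mismatch(theta: float, j_max: int) -> np.ndarray:
    """Stationary geometric mismatch law theta^j/(theta+1)^(j+1), truncated at
    j_max and renormalised so the returned vector sums to 1."""
    if theta < 0:
        raise ValueError("theta must be non-negative")
    if theta == 0:
        out = np.zeros(j_max + 1)
        out[0] = 1.0
        return out
    j = np.arange(j_max + 1)
    f = np.exp(j * math.log(theta) - (j + 1) * math.log(theta + 1.0))
    return f / f.sum()


def _raw_equilibrium(theta: float, j_max: int) -> np.ndarray:
    if theta == 0:
        out = np.zeros(j_max + 1)
        out[0] = 1.0
        return out
    j = np.arange(j_max + 1)
    return np.exp(j * math.log(theta) - (j + 1) * math.log(theta + 1.0))


def sudden_expansion_mismatch(
    tau: float, theta0: float, theta1: float, j_max: int
) -> np.ndarray:
    """Expected mismatch probabilities for classes 0..j_max under the stepwise
    expansion model (not renormalised; tail mass lies beyond j_max)."""
    if min(tau, theta0, theta1) < 0:
        raise ValueError("tau, theta0, theta1 must be non-negative")
    j = np.arange(j_max + 1)
    if theta1 == 0:
        recent = np.zeros(j_max + 1)
        recent[0] = 1.0 - math.exp(-tau)
        decay = math.exp(-tau)
    else:
        rate = 1.0 + 1.0 / theta1
        recent = _raw_equilibrium(theta1, j_max) * special.gammainc(j + 1, tau * rate)
        decay = math.exp(-tau * rate)
    # ancestral part: convolution of Poisson(tau) with the theta0 equilibrium
    f0 = _raw_equilibrium(theta0, j_max)
    log_pois = j * math.log(tau) - special.gammaln(j + 1) if tau > 0 else None
    if tau == 0:
        ancestral = f0
    else:
        pois = np.exp(log_pois)
        ancestral = np.convolve(pois, f0)[: j_max + 1]
    return recent + decay * ancestral


def raggedness(obs: MismatchSpectrum | np.ndarray) -> float:
    """Harpending's raggedness index r = sum_{i=1}^{d+1} (x_i - x_{i-1})^2
    with x_{d+1} = 0; depends only on relative frequencies."""
    x = obs.x if isinstance(obs, MismatchSpectrum) else np.asarray(obs, dtype=float)
    padded = np.concatenate([x, [0.0]])
    return float(np.sum(np.diff(padded) ** 2))


def _model_support(tau: float, theta0: float, theta1: float, d_obs: int) -> int:
    """Comparison support: max of observed range and the model 0.999 quantile."""
    j_max = max(d_obs, 10)
    for _ in range(20):
        f = sudden_expansion_mismatch(tau, theta0, theta1, j_max)
        if f.sum() >= 0.999:
            break
        j_max *= 2
    c = np.cumsum(f)
    q = int(np.searchsorted(c, 0.999)) if c[-1] >= 0.999 else j_max
    return max(d_obs, q)


def _ssd(obs_x: np.ndarray, tau: float, theta0: float, theta1: float) -> float:
    d_obs = len(obs_x) - 1
    support = _model_support(tau, theta0, theta1, d_obs)
    f = sudden_expansion_mismatch(tau, theta0, theta1, support)
    s = f.sum()
    if s > 0:
        f = f / s
    x = np.zeros(support + 1)
    x[: d_obs + 1] = obs_x
    return float(np.sum((x - f) ** 2))


def fit_sudden_expansion(obs: MismatchSpectrum, n: int | None = None) -> ExpansionFit:
    """Least-squares fit of (tau, theta0, theta1) to an observed spectrum.

    Coarse grid search followed by Nelder-Mead refinement; theta1 is capped at
    10x the largest observed difference class (the likelihood surface has a
    ridge towards theta1 -> infinity). theta0 <= theta1 is enforced.
    """
    x = np.asarray(obs.x, dtype=float)
    if len(x) < 2:
        # monomorphic sample: the zero-diversity model fits exactly
        return ExpansionFit(
            tau=0.0, theta0=0.0, theta1=0.0, expected=np.array([1.0]),
            support=0, ssd=0.0, r=raggedness(x), theta1_cap=10.0,
            converged=True,
        )
    d_obs = len(x) - 1
    mean = float(np.dot(np.arange(len(x)), x))
    cap = max(10.0 * d_obs, 10.0)

    taus = np.unique(
        np.concatenate(
            [
                np.linspace(0.0, 2.0 * mean + 1.0, 15),
                np.linspace(0.0, 2.0 * max(d_obs, 1), 9),
            ]
        )
    )
    theta0s = np.array([0.0, 0.1, 0.5, 1.0, max(mean, 0.5)])
    theta1s = np.unique(
        np.clip(np.array([1.0, 5.0, 20.0, 5 * mean + 1, cap / 2, cap]), 0.0, cap)
    )
    grid = []
    for t in taus:
        for t0 in theta0s:
            for t1 in theta1s:
                if t0 > t1:
                    continue
                grid.append((_ssd(x, t, t0, t1), t, t0, t1))
    grid.sort(key=lambda g: g[0])
    best = grid[0]

    def objective(params: np.ndarray) -> float:
        tau, th0, th1 = params
        if tau < 0 or th0 < 0 or th1 < th0 or th1 > cap:
            return 1e6 + abs(tau) + abs(th0) + abs(th1)
        return _ssd(x, tau, th0, th1)

    ssd_val, tau, th0, th1 = best
    converged = False
    for start in grid[:3]:  # polish the leading grid points
        res = optimize.minimize(
            objective,
            np.array(start[1:]),
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-12, "maxiter": 2000},
        )
        if res.fun < ssd_val:
            ssd_val = float(res.fun)
            tau, th0, th1 = res.x
            converged = bool(res.success)
    tau = max(tau, 0.0)
    th0 = min(max(th0, 0.0), th1)
    support = _model_support(tau, th0, th1, d_obs)
    f = sudden_expansion_mismatch(tau, th0, th1, support)
    f = f / f.sum()
    return ExpansionFit(
        tau=float(tau),
        theta0=float(th0),
        theta1=float(th1),
        expected=f,
        support=support,
        ssd=ssd_val,
        r=raggedness(obs),
        theta1_cap=cap,
        converged=converged,
    )


def _simulate_spectrum(
    n: int, tau: float, theta0: float, theta1: float, rng: np.random.Generator
) -> MismatchSpectrum:
    """One coalescent sample of size n under the fitted stepwise expansion,
    simulated directly in mutational units (pair coalescence rate 1/theta)."""
    eps = 1e-9
    profile = [(0.0, max(theta1, eps)), (tau, max(theta0, eps))]
    gen = coalescent.sim_tree(n, rng, size_profile=profile)
    branches = coalescent.place_poisson_mutations(gen, 1.0, rng)
    # theta absorbed into the size profile: mutation rate is 1/2 per lineage
    d = coalescent.pairwise_from_mutations(gen, branches)
    return mismatch_spectrum(d)


def mismatch_pvalues(
    obs: MismatchSpectrum,
    fit: ExpansionFit,
    n: int,
    reps: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Parametric bootstrap p-values (p_SSD, p_raggedness).

    Each replicate simulates n sequences under the fitted (tau, theta0,
    theta1), refits with the same optimiser settings, and contributes to
    p = Pr(simulated statistic >= observed).
    """
    if reps < 100:
        raise ValueError("insufficient replicates: need reps >= 100")
    rng = np.random.default_rng(seed)
    c_ssd = c_r = 0
    for _ in range(reps):
        spec = _simulate_spectrum(n, fit.tau, fit.theta0, fit.theta1, rng)
        refit = fit_sudden_expansion(spec)
        if refit.ssd >= fit.ssd - 1e-12:
            c_ssd += 1
        if raggedness(spec) >= fit.r - 1e-12:
            c_r += 1
    return c_ssd / reps, c_r / reps
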