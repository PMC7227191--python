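"""Neutrality tests: Tajima's D and Fu's Fs.

Tajima's D contrasts two estimators of the scaled mutation rate — the mean
pairwise difference K and S/a1 from the number of segregating sites — and is
negative when rare variants are in excess, the signature of recent population
expansion (or purifying selection).

Fu's Fs is built on the Ewens sampling formula: S' is the probability, given
theta estimated by K, of observing at least as many distinct haplotypes as
seen, and Fs = ln(S'/(1-S')). Large negative Fs means an excess of rare
haplotypes. Stirling numbers of the first kind are computed exactly as Python
integers and combined in log space, so no precision loss occurs even at n in
the hundreds.

Significance for both statistics comes from a fixed-S coalescent null:
constant-size genealogies with exactly S mutations dropped on branches,
mirroring the simulation approach of the standard population-genetics
packages whose conventions this module follows. For Tajima's D the default
p-value is the lower-tail proportion Pr(D_sim <= D_obs), the convention that
matches published tables; upper-tail and two-sided alternatives, and Tajima's
beta-distribution approximation, are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from . import coalescent

__all__ = [
    "TajimaConstants",
    "NeutralityResult",
    "tajima_constants",
    "tajimas_d",
    "tajimas_d_pvalue",
    "stirling1_row",
    "ewens_log_pmf",
    "fu_fs",
    "fu_fs_pvalue",
]


@dataclass(frozen=True)
class TajimaConstants:
    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """Closed-form normalising constants of Tajima's D for sample size n."""
    if n < 4:
        raise ValueError("sample too small for D: need n >= 4")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


def tajimas_d(n: int, S: int, K: float) -> float:
    """Tajima's D = (K - S/a1) / sqrt(e1 S + e2 S (S-1)).

    Returns NaN (the "no polymorphism" sentinel) when S == 0.
    """
    if S < 0:
        raise ValueError("S must be non-negative")
    if S == 0:
        return float("nan")
    c = tajima_constants(n)
    return (K - S / c.a1) / math.sqrt(c.e1 * S + c.e2 * S * (S - 1))


def _fixed_s_null(
    n: int, S: int, reps: int, rng: np.random.Generator, want_haplotypes: bool = False
):
    """Simulate (D, Fs) draws under the fixed-S constant-size coalescent."""
    c = tajima_constants(n)
    denom = math.sqrt(c.e1 * S + c.e2 * S * (S - 1))
    pair_norm = 2.0 / (n * (n - 1))
    d_out = np.empty(reps)
    fs_out = np.empty(reps) if want_haplotypes else None
    for r in range(reps):
        gen = coalescent.sim_tree(n, rng)
        branches = coalescent.place_fixed_mutations(gen, S, rng)
        carriers = coalescent.carrier_counts(gen, branches)
        K = float(np.sum(carriers * (n - carriers))) * pair_norm
        d_out[r] = (K - S / c.a1) / denom
        if want_haplotypes:
            part = coalescent.haplotype_partition(gen, branches)
            k_obs = int(part.max()) + 1
            if K <= 0:
                fs_out[r] = math.inf  # monomorphic draw: maximally conservative
            else:
                fs_out[r] = fu_fs(n, k_obs, K)[0]
    return (d_out, fs_out) if want_haplotypes else d_out


def tajimas_d_pvalue(
    n: int,
    S: int,
    D_obs: float,
    reps: int = 10000,
    seed: int | None = None,
    alternative: str = "lower",
    method: str = "simulation",
) -> float:
    """Empirical p-value of Tajima's D under the fixed-S coalescent null.

    ``alternative``: "lower" (Pr(D_sim <= D_obs), the table convention),
    "upper", or "two-sided" (doubled smaller tail, capped at 1).
    ``method="beta"`` uses Tajima's beta-distribution approximation instead of
    simulation (no randomness).
    """
    if method == "beta":
        return _beta_pvalue(n, D_obs, alternative)
    if reps < 100:
        raise ValueError("insufficient replicates: need reps >= 100")
    rng = np.random.default_rng(seed)
    null = _fixed_s_null(n, S, reps, rng)
    lower = float(np.mean(null <= D_obs))
    upper = float(np.mean(null >= D_obs))
    if alternative == "lower":
        return lower
    if alternative == "upper":
        return upper
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(lower, upper))
    raise ValueError(f"unknown alternative {alternative!r}")


def _beta_pvalue(n: int, D_obs: float, alternative: str) -> float:
    """Tajima's beta approximation: D rescaled to [Dmin, Dmax] with mean 0,
    variance 1, treated as a generalised beta variate."""
    c = tajima_constants(n)
    dmin = (2.0 / n - 1.0 / c.a1) / math.sqrt(c.e2)
    dmax = ((n + 1) / (2.0 * n) - 1.0 / c.a1) / math.sqrt(c.e2)
    span = dmax - dmin
    mean = -dmin / span
    var = 1.0 / span**2
    common = mean * (1 - mean) / var - 1.0
    alpha, beta = mean * common, (1 - mean) * common
    x = (D_obs - dmin) / span
    x = min(max(x, 0.0), 1.0)
    lower = stats.beta.cdf(x, alpha, beta)
    upper = stats.beta.sf(x, alpha, beta)
    if alternative == "lower":
        return float(lower)
    if alternative == "upper":
        return float(upper)
    return float(min(1.0, 2.0 * min(lower, upper)))


@lru_cache(maxsize=64)
def stirling1_row(n: int) -> tuple[int, ...]:
    """Unsigned Stirling numbers of the first kind |S_n^k| for k = 0..n.

    Exact integer recurrence |S_n^k| = |S_{n-1}^{k-1}| + (n-1) |S_{n-1}^k|.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    row = [1]
    for m in range(1, n + 1):
        prev = row
        row = [0] * (m + 1)
        for k in range(1, m + 1):
            row[k] = prev[k - 1] + (m - 1) * (prev[k] if k < m else 0)
    return tuple(row)


@lru_cache(maxsize=64)
def _log_stirling_row(n: int) -> np.ndarray:
    return np.array([math.log(v) for v in stirling1_row(n)[1:]])


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log Pr(k distinct alleles | n, theta) under the Ewens sampling formula,
    for k = 1..n: |S_n^k| theta^k / (theta (theta+1) ... (theta+n-1))."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    log_den = float(np.sum(np.log(theta + np.arange(n))))
    k = np.arange(1, n + 1)
    return _log_stirling_row(n) + k * math.log(theta) - log_den


def _logsumexp(terms: np.ndarray) -> float:
    if terms.size == 0:
        return -math.inf
    m = float(np.max(terms))
    return m + math.log(float(np.sum(np.exp(terms - m))))


def fu_fs(n: int, k_obs: int, theta: float) -> tuple[float, float]:
    """Fu's Fs and the tail probability S' = Pr(#alleles >= k_obs | theta).

    Fs = ln(S' / (1 - S')), computed as the difference of two log-sum-exp
    accumulations so that both tails keep full relative precision. Returns
    (+inf, 1.0) when k_obs == 1 (S' is exactly 1 and Fs is undefined); -inf
    cannot occur for k_obs <= n.
    """
    if not 1 <= k_obs <= n:
        raise ValueError("k_obs must be in 1..n")
    logp = ewens_log_pmf(n, theta)
    log_tail = _logsumexp(logp[k_obs - 1 :])  # k >= k_obs
    log_head = _logsumexp(logp[: k_obs - 1])  # k < k_obs
    s_prime = math.exp(log_tail)
    return log_tail - log_head, s_prime


def fu_fs_pvalue(
    n: int,
    S: int,
    Fs_obs: float,
    reps: int = 10000,
    seed: int | None = None,
) -> float:
    """Pr(Fs_sim <= Fs_obs) over fixed-S coalescent replicates, with theta and
    the haplotype count re-estimated within each replicate."""
    if reps < 100:
        raise ValueError("insufficient replicates: need reps >= 100")
    rng = np.random.default_rng(seed)
    _, fs_null = _fixed_s_null(n, S, reps, rng, want_haplotypes=True)
    return float(np.mean(fs_null <= Fs_obs))


@dataclass
class NeutralityResult:
    unit: str
    n: int
    S: int
    K: float
    D: float
    p_D: float
    Fs: float
    S_prime: float
    p_Fs: float
    theta_hat: float
    reps: int
    seed: int | None


def neutrality_tests(
    unit: str,
    n: int,
    S: int,
    K: float,
    k_obs: int,
    reps: int = 10000,
    seed: int | None = None,
) -> NeutralityResult:
    """Convenience wrapper running both tests for one analysis unit.

    theta for Fu's Fs is estimated by K, the mean pairwise difference.
    """
    D = tajimas_d(n, S, K)
    if math.isnan(D):
        return NeutralityResult(
            unit, n, S, K, D, float("nan"), float("nan"), float("nan"),
            float("nan"), K, reps, seed,
        )
    p_d = tajimas_d_pvalue(n, S, D, reps=reps, seed=seed)
    Fs, s_prime = fu_fs(n, k_obs, K)
    p_fs = fu_fs_pvalue(n, S, Fs, reps=reps, seed=None if seed is None else seed + 1)
    return NeutralityResult(unit, n, S, K, D, p_d, Fs, s_prime, p_fs, K, reps, seed)
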