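"""Random-orientation null model for branch parallelism.

For an image with n detected branches, the chance that a given branch falls
into alignment with another within the +/-10 deg window is modeled as a
Bernoulli success with p = 1/n, so the number of branches in a parallel
group of size k follows Binomial(n, 1/n).  Scaling the probability P(k) by
n gives the expected count of groups of each size in a randomly oriented
image of the same complexity; p = 1/n makes that baseline insensitive to
image density (denser images do not saturate the parallelism estimate).

Three evaluation modes:

``analytic``
    expected_groups_by_k[k] = n * P(k) as real numbers, with closed-form
    totals  groups = n(1 - P(0) - P(1))  and  lines = n(1 - P(1)).
``integerized``
    each n * P(k) rounded up to an integer, including sizes k >= 2 while
    n * P(k) >= include_cutoff (default 0.1).  This is the tabulated-counts
    convention used for per-image simulated group tables and the simulated
    parallelism percentage.
``montecarlo``
    empirical averages over seeded replicates of n Binomial(n, 1/n) draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

__all__ = [
    "NullModelConfig",
    "NullModelResult",
    "binomial_group_probability",
    "expected_counts",
    "simulate_bernoulli_mc",
    "simulate_random_angles",
]

DEFAULT_SEED = 20251031


@dataclass(frozen=True)
class NullModelConfig:
    mode: str = "integerized"
    seed: int = DEFAULT_SEED
    n_reps: int = 10_000
    include_cutoff: float = 0.1
    k_max: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("analytic", "integerized", "montecarlo"):
            raise ValueError(f"unknown null-model mode {self.mode!r}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.include_cutoff <= 0:
            raise ValueError("include_cutoff must be positive")


@dataclass(frozen=True)
class NullModelResult:
    """Expected (or simulated) parallel-group counts for one branch count n."""

    n: int
    mode: str
    expected_groups_by_k: dict[int, float]
    groups_total: float
    lines_total: float
    groups_se: float | None = None
    lines_se: float | None = None

    @property
    def p(self) -> float:
        return 1.0 / self.n


def binomial_group_probability(n: int, k: int) -> float:
    """P(k) = C(n,k) (1/n)^k (1-1/n)^(n-k), evaluated in log space."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0 or k > n:
        raise ValueError(f"k must lie in 0..n, got k={k}, n={n}")
    if n == 1:
        return 1.0 if k == 1 else 0.0
    return float(_stats.binom.pmf(k, n, 1.0 / n))


def _integerized_counts(n: int, cutoff: float, k_max: int) -> dict[int, float]:
    counts: dict[int, float] = {}
    for k in range(2, k_max + 1):
        expected = n * binomial_group_probability(n, k)
        if expected < cutoff:
            break
        counts[k] = float(math.ceil(expected))
    return counts


def expected_counts(n: int, cfg: NullModelConfig | None = None) -> NullModelResult:
    """Expected parallel-group counts per size k >= 2 under the null model."""
    cfg = cfg or NullModelConfig()
    if n < 2:
        raise ValueError("the null model needs n >= 2 (no pair is possible otherwise)")
    if cfg.mode == "montecarlo":
        return simulate_bernoulli_mc(n, cfg)
    k_max = min(cfg.k_max or n, n)
    p0 = binomial_group_probability(n, 0)
    p1 = binomial_group_probability(n, 1)
    if cfg.mode == "integerized":
        counts = _integerized_counts(n, cfg.include_cutoff, k_max)
        return NullModelResult(
            n=n,
            mode="integerized",
            expected_groups_by_k=counts,
            groups_total=float(sum(counts.values())),
            lines_total=float(sum(k * v for k, v in counts.items())),
        )
    counts = {}
    for k in range(2, k_max + 1):
        expected = n * binomial_group_probability(n, k)
        if expected < 1e-12 and k > 2:
            break
        counts[k] = float(expected)
    return NullModelResult(
        n=n,
        mode="analytic",
        expected_groups_by_k=counts,
        groups_total=float(n * (1.0 - p0 - p1)),
        lines_total=float(n * (1.0 - p1)),
    )


def simulate_bernoulli_mc(n: int, cfg: NullModelConfig | None = None) -> NullModelResult:
    """Monte Carlo version of :func:`expected_counts`.

    Each replicate draws, for every one of the n branches, a Binomial(n, 1/n)
    alignment count; the per-size histogram of those counts is averaged over
    replicates and converges to the analytic n * P(k).
    """
    cfg = cfg or NullModelConfig(mode="montecarlo")
    if n < 2:
        raise ValueError("the null model needs n >= 2")
    rng = np.random.default_rng(cfg.seed)
    reps = cfg.n_reps
    sum_counts = np.zeros(n + 1)
    sumsq_groups = 0.0
    sumsq_lines = 0.0
    sum_groups = 0.0
    sum_lines = 0.0
    chunk = max(1, min(reps, 20_000_000 // max(n, 1)))
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        draws = rng.binomial(n, 1.0 / n, size=(m, n))
        # per-replicate histogram of alignment counts, via offset bincount
        offsets = (n + 1) * np.arange(m)[:, None]
        hist = np.bincount((draws + offsets).ravel(), minlength=m * (n + 1)).reshape(m, n + 1)
        sum_counts += hist.sum(axis=0)
        k = np.arange(n + 1)
        groups = hist[:, 2:].sum(axis=1)
        lines = (hist * k).astype(float)[:, 2:].sum(axis=1)
        sum_groups += groups.sum()
        sum_lines += lines.sum()
        sumsq_groups += float((groups.astype(float) ** 2).sum())
        sumsq_lines += float((lines**2).sum())
        done += m
    mean_counts = sum_counts / reps
    mean_groups = sum_groups / reps
    mean_lines = sum_lines / reps
    var_g = max(sumsq_groups / reps - mean_groups**2, 0.0)
    var_l = max(sumsq_lines / reps - mean_lines**2, 0.0)
    counts = {k: float(mean_counts[k]) for k in range(2, n + 1) if mean_counts[k] > 0}
    return NullModelResult(
        n=n,
        mode="montecarlo",
        expected_groups_by_k=counts,
        groups_total=float(mean_groups),
        lines_total=float(mean_lines),
        groups_se=float(np.sqrt(var_g / reps)),
        lines_se=float(np.sqrt(var_l / reps)),
    )


def simulate_random_angles(n: int, seed: int = DEFAULT_SEED) -> np.ndarray:
    """n orientations drawn uniformly on [0, 180), reproducible under seed.

    Exploratory mode: feeding these to the geometric orientation clustering
    gives an alternative, density-dependent baseline; the binomial model
    above is the default because it does not saturate for large n.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 180.0, size=n)
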