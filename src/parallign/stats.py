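"""Parallelism statistics per image and aggregation across images.

Per image, with n detected branches and a group-size frequency table
freq[k] (k = group size, k >= 2):

* PM (measured parallelism)  = sum_k k*freq[k] / n — the fraction of
  branches that belong to some parallel group.
* PS (simulated parallelism) = the same quantity under the binomial null
  model's expected counts.
* PMS = PM / PS; values above 1 mean the image is more parallel than a
  randomly oriented image of the same complexity.
* Group-weighted parallelism = sum_k k^2 * freq[k], up-weighting large
  groups; the measured/simulated ratio of these sums (M/S) emphasizes
  whether large parallel groups occur more often than chance predicts.

Across images, the study-level signal is the slope of the least-squares
regression of parallel-line counts (and of weighted sums) on n: a steeper
measured slope than the null slope indicates systematic excess parallelism.
Fractions are stored as fractions throughout; rendering as percentages
happens only at the reporting boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _scistats

from .grouping import GroupSizeDistribution
from .nullmodel import NullModelResult

__all__ = [
    "ImageRecord",
    "RegressionFit",
    "StudySummary",
    "measured_parallelism",
    "simulated_parallelism",
    "pms_ratio",
    "weighted_parallelism_sum",
    "ms_weight_ratio",
    "fit_regression",
    "aggregate",
    "rank_sum_compare",
    "build_record",
]


@dataclass(frozen=True)
class ImageRecord:
    """Per-image parallelism summary (the one row the batch table stores)."""

    image_id: str
    n_branches: int
    measured: GroupSizeDistribution
    simulated: NullModelResult | None
    pm: float
    ps: float
    pms: float
    weighted_measured: float
    weighted_simulated: float
    ms_ratio: float


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r: float
    degenerate: bool = False


@dataclass(frozen=True)
class StudySummary:
    """Cross-image aggregates: per-metric mean/SD and the four regressions."""

    n_images: int
    metric_means: dict[str, float]
    metric_sds: dict[str, float]
    measured_fit: RegressionFit
    simulated_fit: RegressionFit
    weighted_measured_fit: RegressionFit
    weighted_simulated_fit: RegressionFit


def measured_parallelism(dist: GroupSizeDistribution) -> float:
    """PM: fraction of detected branches belonging to a parallel group."""
    if dist.n_branches < 1:
        raise ValueError("PM is undefined for an image with no branches")
    return dist.parallel_lines / dist.n_branches


def simulated_parallelism(result: NullModelResult) -> float:
    """PS: null-model parallel-line total divided by n."""
    if result.n < 2:
        raise ValueError("PS is undefined for n < 2")
    return result.lines_total / result.n


def pms_ratio(pm: float, ps: float) -> float:
    """PM / PS; > 1 means measured parallelism exceeds the random baseline."""
    if ps <= 0:
        raise ValueError("PMS is undefined when PS is zero")
    return pm / ps


def weighted_parallelism_sum(dist) -> float:
    """Group-weighted parallelism: sum over sizes of k^2 * count[k].

    Accepts a :class:`GroupSizeDistribution`, a :class:`NullModelResult`,
    or a plain {size: count} mapping.
    """
    if isinstance(dist, GroupSizeDistribution):
        freq = dist.freq
    elif isinstance(dist, NullModelResult):
        freq = dist.expected_groups_by_k
    else:
        freq = dict(dist)
    return float(sum(k * k * v for k, v in freq.items()))


def ms_weight_ratio(measured_sum: float, simulated_sum: float) -> float:
    """Measured/simulated ratio of group-weighted parallelism sums."""
    if simulated_sum <= 0:
        raise ValueError("M/S ratio is undefined when the simulated sum is zero")
    return measured_sum / simulated_sum


def fit_regression(x, y) -> RegressionFit:
    """Ordinary least squares y ~ x with Pearson r.

    Constant y is reported as slope 0, r 0 with the ``degenerate`` flag set;
    constant x is a fit error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("regression needs >= 2 paired points")
    if np.ptp(x) == 0:
        raise ValueError("regression is undefined for constant x")
    if np.ptp(y) == 0:
        return RegressionFit(slope=0.0, intercept=float(y[0]), r=0.0, degenerate=True)
    res = _scistats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope), intercept=float(res.intercept), r=float(res.rvalue)
    )


def build_record(
    image_id: str,
    measured: GroupSizeDistribution,
    simulated: NullModelResult | None,
) -> ImageRecord:
    """Assemble an :class:`ImageRecord`, tolerating degenerate blank images."""
    n = measured.n_branches
    pm = measured_parallelism(measured) if n >= 1 else float("nan")
    if simulated is not None and simulated.n >= 2:
        ps = simulated_parallelism(simulated)
        ws = weighted_parallelism_sum(simulated)
    else:
        ps = float("nan")
        ws = float("nan")
    wm = weighted_parallelism_sum(measured)
    pms = pm / ps if ps and ps > 0 else float("nan")
    msr = wm / ws if ws and ws > 0 else float("nan")
    return ImageRecord(
        image_id=image_id,
        n_branches=n,
        measured=measured,
        simulated=simulated,
        pm=pm,
        ps=ps,
        pms=pms,
        weighted_measured=wm,
        weighted_simulated=ws,
        ms_ratio=msr,
    )


def records_frame(records: list[ImageRecord]) -> pd.DataFrame:
    """Tabulate records into the S1-style per-image summary table."""
    rows = []
    for r in records:
        sim = r.simulated
        rows.append(
            {
                "image_id": r.image_id,
                "detected_branches": r.n_branches,
                "measured_groups": r.measured.n_groups,
                "measured_lines": r.measured.parallel_lines,
                "simulated_groups": sim.groups_total if sim else float("nan"),
                "simulated_lines": sim.lines_total if sim else float("nan"),
                "PM_pct": 100.0 * r.pm,
                "PS_pct": 100.0 * r.ps,
                "PMS": r.pms,
                "weighted_measured": r.weighted_measured,
                "weighted_simulated": r.weighted_simulated,
                "MS_ratio": r.ms_ratio,
            }
        )
    return pd.DataFrame(rows)


def aggregate(records: list[ImageRecord]) -> StudySummary:
    """Cross-image means/SDs (sample SD, n-1) and the four n-regressions."""
    if len(records) < 2:
        raise ValueError("aggregation needs >= 2 image records")
    df = records_frame(records)
    metrics = [
        "detected_branches",
        "measured_groups",
        "measured_lines",
        "simulated_groups",
        "simulated_lines",
        "PM_pct",
        "PS_pct",
        "PMS",
        "weighted_measured",
        "weighted_simulated",
        "MS_ratio",
    ]
    means = {m: float(df[m].mean()) for m in metrics}
    sds = {m: float(df[m].std(ddof=1)) for m in metrics}
    n = df["detected_branches"].to_numpy(dtype=float)

    def safe_fit(y):
        # identical branch counts across images make the slope undefined
        if np.ptp(n) == 0:
            return RegressionFit(slope=float("nan"), intercept=float("nan"), r=0.0, degenerate=True)
        return fit_regression(n, y)

    return StudySummary(
        n_images=len(records),
        metric_means=means,
        metric_sds=sds,
        measured_fit=safe_fit(df["measured_lines"]),
        simulated_fit=safe_fit(df["simulated_lines"]),
        weighted_measured_fit=safe_fit(df["weighted_measured"]),
        weighted_simulated_fit=safe_fit(df["weighted_simulated"]),
    )


def rank_sum_compare(a, b):
    """Two-sided Mann-Whitney U (normal approximation with tie correction).

    Returns ``(U, p)`` where U is the statistic for the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = _scistats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(min(res.pvalue, 1.0))
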