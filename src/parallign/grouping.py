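"""Cluster branch segments into parallel groups by orientation.

Orientations are axial quantities with period 180 deg, so all angular
arithmetic here is circular on the doubled angle.  Grouping is a
deterministic angle-sorted greedy pass: branches are sorted by orientation
(ties broken by branch id), each unassigned branch seeds a candidate group,
and every later unassigned branch joins if its circular distance to the
group's running circular mean stays within the tolerance (default +/-10 deg).
Greedy growth against the running mean bounds the within-group spread, which
transitive chaining would not.  Singletons are not groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .branches import BranchSegment, min_distance

__all__ = [
    "GroupingParams",
    "ParallelGroup",
    "GroupSizeDistribution",
    "circular_angle_distance",
    "circular_mean_deg",
    "cluster_by_orientation",
    "size_distribution",
]


@dataclass(frozen=True)
class GroupingParams:
    """Angular tolerance (deg) and optional spatial cap (px) for grouping."""

    tolerance_deg: float = 10.0
    max_pair_distance_px: float = float("inf")

    def __post_init__(self) -> None:
        if not (0 < self.tolerance_deg <= 45):
            raise ValueError("tolerance_deg must be in (0, 45]")
        if self.max_pair_distance_px <= 0:
            raise ValueError("max_pair_distance_px must be positive")


@dataclass
class ParallelGroup:
    """A set of >= 2 co-oriented branches."""

    group_id: int
    member_ids: list[int]
    mean_angle_deg: float

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class GroupSizeDistribution:
    """Frequency table of parallel-group sizes for one image.

    ``freq[k]`` counts groups of exactly k branches; ``n_branches`` is the
    total number of detected branches n in the image.
    """

    freq: dict[int, int]
    n_branches: int

    def __post_init__(self) -> None:
        if any(k < 2 or v < 0 for k, v in self.freq.items()):
            raise ValueError("group sizes must be >= 2 with non-negative counts")
        if self.parallel_lines > self.n_branches:
            raise ValueError("parallel lines cannot exceed total branches")

    @property
    def n_groups(self) -> int:
        return int(sum(self.freq.values()))

    @property
    def parallel_lines(self) -> int:
        """Total branches participating in any parallel group: sum k*freq[k]."""
        return int(sum(k * v for k, v in self.freq.items()))


def circular_angle_distance(a: float, b: float) -> float:
    """Distance between two axial orientations (deg), in [0, 90]."""
    d = abs(float(a) - float(b)) % 180.0
    return min(d, 180.0 - d)


def circular_mean_deg(angles) -> float:
    """Circular mean of axial orientations (period 180), in [0, 180)."""
    ang = np.asarray(angles, dtype=float)
    if ang.size == 0:
        raise ValueError("cannot average an empty set of angles")
    doubled = np.deg2rad(2.0 * ang)
    mean = 0.5 * np.degrees(np.arctan2(np.sin(doubled).mean(), np.cos(doubled).mean()))
    mean = float(np.mod(mean, 180.0))
    return 0.0 if mean >= 180.0 - 1e-9 else mean


def cluster_by_orientation(
    branches: list[BranchSegment],
    params: GroupingParams | None = None,
    angles: list[float] | None = None,
) -> list[ParallelGroup]:
    """Greedy orientation clustering into parallel groups.

    ``angles`` may be supplied to cluster precomputed orientations (e.g. a
    random-angle draw); otherwise each branch's principal-axis orientation
    is used.  When ``max_pair_distance_px`` is finite, a branch joins a group
    only if it also lies within that distance of some current member.
    """
    params = params or GroupingParams()
    if angles is None:
        angles = [b.angle_deg for b in branches]
    if len(angles) != len(branches):
        raise ValueError("angles and branches must align")
    order = sorted(range(len(branches)), key=lambda i: (angles[i], branches[i].branch_id))
    assigned = [False] * len(branches)
    use_distance = np.isfinite(params.max_pair_distance_px)
    groups: list[ParallelGroup] = []
    for si, seed in enumerate(order):
        if assigned[seed]:
            continue
        assigned[seed] = True
        members = [seed]
        member_angles = [angles[seed]]
        mean = angles[seed]
        for cand in order[si + 1 :]:
            if assigned[cand]:
                continue
            if circular_angle_distance(angles[cand], mean) > params.tolerance_deg:
                continue
            if use_distance and not any(
                min_distance(branches[cand], branches[m]) <= params.max_pair_distance_px
                for m in members
            ):
                continue
            assigned[cand] = True
            members.append(cand)
            member_angles.append(angles[cand])
            mean = circular_mean_deg(member_angles)
        if len(members) >= 2:
            groups.append(
                ParallelGroup(
                    group_id=len(groups),
                    member_ids=sorted(branches[i].branch_id for i in members),
                    mean_angle_deg=mean,
                )
            )
    return groups


def size_distribution(groups: list[ParallelGroup], n_branches: int) -> GroupSizeDistribution:
    """Tabulate group sizes into a :class:`GroupSizeDistribution`."""
    all_ids: list[int] = []
    freq: dict[int, int] = {}
    for g in groups:
        all_ids.extend(g.member_ids)
        freq[g.size] = freq.get(g.size, 0) + 1
    if len(all_ids) != len(set(all_ids)):
        raise ValueError("groups share members; they must be disjoint")
    return GroupSizeDistribution(freq=dict(sorted(freq.items())), n_branches=int(n_branches))
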