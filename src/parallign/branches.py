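"""Decompose a skeleton into individual branch segments and measure them.

Branch points are found by 8-neighbor counting on the thin skeleton
(1 neighbor = endpoint, 2 = internal, >= 3 = junction).  Removing junction
pixels partitions the remaining skeleton into maximal paths; each path
becomes one :class:`BranchSegment` carrying its arc length in pixels and its
orientation in degrees relative to the horizontal axis, folded into
[0, 180).  Angles follow the mathematical convention (counter-clockwise
positive) with the image y-axis pointing down, so a horizontal run is 0 deg
and a vertical run is 90 deg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as _ndi
from scipy.spatial.distance import cdist

__all__ = [
    "BranchSegment",
    "JunctionMap",
    "find_junctions",
    "split_into_branches",
    "map_length_slider",
    "filter_by_length",
    "branch_orientation",
    "branch_length",
    "min_distance",
    "extract_branches",
]

_NEIGHBOR_KERNEL = np.ones((3, 3), dtype=int)
_EIGHT = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class BranchSegment:
    """One skeleton path between endpoints/junctions.

    ``path`` is the ordered list of (row, col) pixels; consecutive pixels are
    8-neighbors.  Degenerate single-pixel fragments (isolated between
    junctions) are kept so the skeleton partition is exact; they carry length
    0 and no orientation and are removed by any positive length filter.
    """

    branch_id: int
    path: list[tuple[int, int]]
    image_id: str = ""
    group_id: int = -1

    def __post_init__(self) -> None:
        if not self.path:
            raise ValueError("branch path must contain at least one pixel")

    @property
    def endpoints(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return self.path[0], self.path[-1]

    @property
    def length_px(self) -> float:
        return branch_length(self)

    @property
    def angle_deg(self) -> float:
        return branch_orientation(self)

    @property
    def centroid(self) -> tuple[float, float]:
        """(x, y) centroid of the path pixels."""
        arr = np.asarray(self.path, dtype=float)
        return float(arr[:, 1].mean()), float(arr[:, 0].mean())


@dataclass(frozen=True)
class JunctionMap:
    """Skeleton pixels classified by 8-neighbor count."""

    junction_pixels: frozenset
    endpoint_pixels: frozenset

    def __post_init__(self) -> None:
        if self.junction_pixels & self.endpoint_pixels:
            raise ValueError("junction and endpoint sets must be disjoint")


def find_junctions(skeleton: np.ndarray) -> JunctionMap:
    """Classify skeleton pixels: 1 neighbor = endpoint, >= 3 = junction."""
    sk = np.asarray(skeleton, dtype=bool)
    counts = _ndi.convolve(sk.astype(int), _NEIGHBOR_KERNEL, mode="constant") - sk
    junctions = frozenset(zip(*np.nonzero(sk & (counts >= 3))))
    endpoints = frozenset(zip(*np.nonzero(sk & (counts == 1))))
    return JunctionMap(junction_pixels=junctions, endpoint_pixels=endpoints)


def _order_component(pixels: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Order the pixels of a path-like component by walking from a tip."""
    if len(pixels) <= 2:
        return sorted(pixels)
    pixset = set(pixels)
    nbrs = {
        p: [q for dr, dc in _EIGHT if (q := (p[0] + dr, p[1] + dc)) in pixset]
        for p in pixels
    }
    tips = sorted(p for p, ns in nbrs.items() if len(ns) <= 1)
    start = tips[0] if tips else sorted(pixels)[0]  # cycles: arbitrary start
    order = [start]
    seen = {start}
    current = start
    while True:
        nxt = [q for q in nbrs[current] if q not in seen]
        if not nxt:
            break
        # prefer axial moves so diagonal shortcuts do not skip pixels
        nxt.sort(key=lambda q: (abs(q[0] - current[0]) + abs(q[1] - current[1]), q))
        current = nxt[0]
        order.append(current)
        seen.add(current)
    if len(order) != len(pixels):  # rare: component is not a simple path
        order.extend(sorted(pixset - seen))
    return order


def split_into_branches(
    skeleton: np.ndarray, junctions: JunctionMap | None = None, image_id: str = ""
) -> list[BranchSegment]:
    """Partition the skeleton into maximal paths between endpoints/junctions.

    Junction pixels belong to no branch; every other skeleton pixel belongs
    to exactly one returned segment, so pixel counts obey the conservation
    law  sum(segment sizes) + #junctions = #skeleton pixels.
    """
    sk = np.asarray(skeleton, dtype=bool)
    junctions = junctions if junctions is not None else find_junctions(sk)
    body = sk.copy()
    for r, c in junctions.junction_pixels:
        body[r, c] = False
    labels, n_comp = _ndi.label(body, structure=_NEIGHBOR_KERNEL)
    segments: list[BranchSegment] = []
    for idx, comp in enumerate(_ndi.find_objects(labels), start=1):
        rows, cols = np.nonzero(labels[comp] == idx)
        pixels = [(int(r + comp[0].start), int(c + comp[1].start)) for r, c in zip(rows, cols)]
        segments.append(
            BranchSegment(branch_id=len(segments), path=_order_component(pixels), image_id=image_id)
        )
    return segments


def map_length_slider(s: int | None) -> float:
    """Map the 1-10 length slider linearly onto 5-200 px; absent means 50 px."""
    if s is None:
        return 50.0
    if int(s) != s or not (1 <= int(s) <= 10):
        raise ValueError(f"length slider must be an integer in 1..10 or None, got {s!r}")
    return float(int(np.floor(5 + (int(s) - 1) * 195.0 / 9 + 0.5)))


def filter_by_length(branches: list[BranchSegment], min_len: float) -> list[BranchSegment]:
    """Keep segments with arc length >= ``min_len`` (inclusive), order preserved."""
    return [b for b in branches if branch_length(b) >= min_len]


def branch_length(branch: BranchSegment) -> float:
    """Polyline arc length: 1 per axial step, sqrt(2) per diagonal step."""
    arr = np.asarray(branch.path, dtype=float)
    if len(arr) < 2:
        return 0.0
    steps = np.diff(arr, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def branch_orientation(branch: BranchSegment) -> float:
    """Principal-axis orientation of the path pixels, in degrees in [0, 180).

    A total-least-squares fit through the pixel cloud (the leading axis of
    its second moments), robust to jagged rasterization.  Horizontal = 0,
    vertical = 90.
    """
    arr = np.asarray(branch.path, dtype=float)
    if len(arr) < 2:
        raise ValueError("orientation is undefined for a single-pixel path")
    x = arr[:, 1] - arr[:, 1].mean()
    y = -(arr[:, 0] - arr[:, 0].mean())  # flip so y points up
    cxx = float(np.dot(x, x))
    cyy = float(np.dot(y, y))
    cxy = float(np.dot(x, y))
    angle = float(np.mod(0.5 * np.degrees(np.arctan2(2.0 * cxy, cxx - cyy)), 180.0))
    return 0.0 if angle >= 180.0 - 1e-9 else angle


def chord_orientation(branch: BranchSegment) -> float:
    """Endpoint-chord orientation in [0, 180); alternative estimator."""
    (r0, c0), (r1, c1) = branch.endpoints
    if (r0, c0) == (r1, c1):
        raise ValueError("orientation is undefined for a degenerate chord")
    return float(np.mod(np.degrees(np.arctan2(-(r1 - r0), c1 - c0)), 180.0))


def min_distance(a: BranchSegment, b: BranchSegment) -> float:
    """Minimum Euclidean distance between the pixels of two segments."""
    if a.branch_id == b.branch_id and a.image_id == b.image_id and a.path == b.path:
        raise ValueError("min_distance requires two distinct segments")
    pa = np.asarray(a.path, dtype=float)
    pb = np.asarray(b.path, dtype=float)
    return float(cdist(pa, pb).min())


def extract_branches(
    skeleton: np.ndarray,
    min_length_px: float | None = None,
    length_slider: int | None = None,
    image_id: str = "",
) -> list[BranchSegment]:
    """Skeleton -> measured, length-filtered branch segments.

    ``min_length_px`` wins over the slider when both are given.
    """
    if min_length_px is None:
        min_length_px = map_length_slider(length_slider)
    segments = split_into_branches(skeleton, image_id=image_id)
    kept = filter_by_length(segments, min_length_px)
    for new_id, seg in enumerate(kept):
        seg.branch_id = new_id
    return kept
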