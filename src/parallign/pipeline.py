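"""Batch execution, tabular export, and annotated overlays.

`run_single` drives one image through segmentation -> branch extraction ->
orientation grouping -> null model -> parallelism statistics and returns the
per-image record plus its branch table; `run_batch` maps that over a
directory in lexicographic order and aggregates a study summary.  Exports
are plain UTF-8 comma-separated CSV with a header row and '.' decimals;
overlays are PNGs with branches colored by parallel group.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .branches import BranchSegment, extract_branches
from .grouping import GroupingParams, cluster_by_orientation, size_distribution
from .nullmodel import NullModelConfig, expected_counts
from .segmentation import RawImage, SegmentationParams, load_image, segment_image
from .stats import ImageRecord, StudySummary, aggregate, build_record, records_frame

logger = logging.getLogger("parallign")

__all__ = [
    "PipelineResult",
    "run_single",
    "run_batch",
    "export_branch_csv",
    "export_summary_csv",
    "read_summary_csv",
    "annotate_image",
]

IMAGE_EXTENSIONS = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp")

# fixed qualitative palette for group overlays (RGB, 0-255)
_PALETTE = np.array(
    [
        (31, 119, 180), (255, 127, 14), (44, 160, 44), (214, 39, 40),
        (148, 103, 189), (140, 86, 75), (227, 119, 194), (188, 189, 34),
        (23, 190, 207), (255, 187, 120), (152, 223, 138), (255, 152, 150),
    ],
    dtype=np.uint8,
)
_UNGROUPED_COLOR = np.array((200, 200, 200), dtype=np.uint8)


@dataclass
class PipelineResult:
    """Everything `run_single` computes for one image."""

    record: ImageRecord
    branches: list[BranchSegment]
    branch_table: pd.DataFrame
    skeleton: np.ndarray
    mask: np.ndarray
    image: RawImage


def _branch_table(branches: list[BranchSegment], image_id: str) -> pd.DataFrame:
    rows = []
    for b in branches:
        cx, cy = b.centroid
        rows.append(
            {
                "image_id": image_id,
                "branch_id": b.branch_id,
                "centroid_x": round(cx, 2),
                "centroid_y": round(cy, 2),
                "angle_deg": round(b.angle_deg, 3),
                "length_px": round(b.length_px, 3),
                "group_id": b.group_id,
            }
        )
    cols = ["image_id", "branch_id", "centroid_x", "centroid_y", "angle_deg", "length_px", "group_id"]
    return pd.DataFrame(rows, columns=cols)


def run_single(
    image: str | RawImage,
    seg_params: SegmentationParams | None = None,
    grouping_params: GroupingParams | None = None,
    null_config: NullModelConfig | None = None,
) -> PipelineResult:
    """Run the full pipeline on one image (path or in-memory grayscale)."""
    seg_params = seg_params or SegmentationParams()
    grouping_params = grouping_params or GroupingParams()
    null_config = null_config or NullModelConfig()

    img = load_image(image) if isinstance(image, str) else image
    image_id = os.path.basename(img.source_path)
    try:
        _, mask, skeleton = segment_image(img, seg_params)
        branches = extract_branches(
            skeleton,
            min_length_px=seg_params.min_length_px,
            length_slider=seg_params.length_slider,
            image_id=image_id,
        )
        groups = cluster_by_orientation(branches, grouping_params)
        for g in groups:
            for bid in g.member_ids:
                branches[bid].group_id = g.group_id
        dist = size_distribution(groups, len(branches))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed on {image_id!r}: {exc}") from exc

    n = len(branches)
    if n >= 2:
        simulated = expected_counts(n, null_config)
    else:
        simulated = None
        logger.warning("image %s: only %d branch(es) detected; null metrics undefined", image_id, n)
    record = build_record(image_id, dist, simulated)
    return PipelineResult(
        record=record,
        branches=branches,
        branch_table=_branch_table(branches, image_id),
        skeleton=skeleton,
        mask=mask,
        image=img,
    )


def run_batch(
    directory: str,
    seg_params: SegmentationParams | None = None,
    grouping_params: GroupingParams | None = None,
    null_config: NullModelConfig | None = None,
) -> tuple[list[PipelineResult], StudySummary | None]:
    """Process every readable image in ``directory`` (lexicographic order).

    Unreadable entries are skipped with a warning; if nothing is readable a
    batch error is raised.  The summary is None when fewer than two images
    succeed.
    """
    entries = sorted(
        f for f in os.listdir(directory) if f.lower().endswith(IMAGE_EXTENSIONS)
    )
    if not entries:
        raise ValueError(f"no image files found in {directory!r}")
    results: list[PipelineResult] = []
    for name in entries:
        path = os.path.join(directory, name)
        try:
            results.append(run_single(path, seg_params, grouping_params, null_config))
        except Exception as exc:
            logger.warning("skipping %s: %s", name, exc)
    if not results:
        raise RuntimeError(f"no image in {directory!r} could be processed")
    summary = aggregate([r.record for r in results]) if len(results) >= 2 else None
    return results, summary


def export_branch_csv(results: list[PipelineResult] | PipelineResult, path: str) -> None:
    """Write the per-branch measurement table (one row per branch)."""
    if isinstance(results, PipelineResult):
        results = [results]
    table = pd.concat([r.branch_table for r in results], ignore_index=True)
    table.to_csv(path, index=False)


def export_summary_csv(records: list[ImageRecord], path: str) -> None:
    """Write the per-image summary table (one row per image)."""
    records_frame(records).to_csv(path, index=False)


def read_summary_csv(path: str) -> pd.DataFrame:
    """Re-read a summary CSV written by :func:`export_summary_csv`."""
    return pd.read_csv(path)


def annotate_image(result: PipelineResult, path: str | None = None) -> np.ndarray:
    """Overlay the skeleton branches on the micrograph, colored by group.

    Ungrouped branches are light gray; each parallel group gets a fixed
    palette color.  Returns the RGB array; writes a PNG when ``path`` given.
    """
    base = result.image.pixels.astype(np.uint8)
    rgb = np.stack([base] * 3, axis=-1)
    for b in result.branches:
        if b.group_id >= 0:
            color = _PALETTE[b.group_id % len(_PALETTE)]
        else:
            color = _UNGROUPED_COLOR
        rows, cols = zip(*b.path)
        rgb[rows, cols] = color
    if path is not None:
        import imageio.v3 as iio

        iio.imwrite(path, rgb)
    return rgb
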