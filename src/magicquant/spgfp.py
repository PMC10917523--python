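"""Split-GFP mitochondrial import scoring.

The central readout of the mitochondrial-import (split-GFP) assay: for each
segmented cell, the marker (mCherry) projection is thresholded at a fraction
(default 5%) of that cell's maximal marker value to define the mitochondrial
mask, and the median reporter (GFP) intensity within that mask is the per-cell
spGFP intensity. Group statistics operate on biological-replicate means via
:func:`magicquant.stats.summarize_groups`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image_io import ImageStack, Projection2D, sum_project
from .segmentation import (
    QC_NO_MITO,
    CellLabelMap,
    SegmentationParams,
    segment_projections,
)
from .stats import summarize_groups  # noqa: F401  (re-exported group statistics)

DEFAULT_THRESHOLD_FRAC = 0.05


@dataclass
class SpGFPMeasurement:
    """Per-cell mitochondrial-mask statistics."""

    cell_id: int
    mito_area_px: int
    mito_threshold_value: float
    spgfp_median: float  # NaN when excluded
    excluded: bool = False
    reason: str = ""


def mito_mask(
    cell_id: int,
    labels: CellLabelMap,
    marker_proj: Projection2D,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    per_image_max: bool = False,
) -> np.ndarray:
    """Mitochondrial mask of one cell: marker >= threshold_frac x max marker.

    The maximum is the *per-cell* maximum of the marker projection by default
    (``per_image_max=True`` switches to the image-wide maximum). Returns a
    boolean mask restricted to the cell's pixels; the mask is empty when the
    cell has no positive marker signal.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must be in (0, 1)")
    cell = labels.cell_mask(cell_id)
    marker = marker_proj.pixels
    ref = marker.max() if per_image_max else marker[cell].max()
    if ref <= 0:
        return np.zeros_like(cell)
    return cell & (marker >= threshold_frac * ref)


def spgfp_per_cell(
    cell_id: int,
    labels: CellLabelMap,
    gfp_proj: Projection2D,
    mito: np.ndarray,
    threshold_value: float = float("nan"),
) -> SpGFPMeasurement:
    """Median GFP intensity within one cell's mitochondrial mask.

    An empty mask yields an excluded measurement (reason: no mitochondrial
    signal), never a silent zero. Even-sized medians are the mean of the two
    central order statistics (``numpy.median``).
    """
    cell = labels.cell_mask(cell_id)
    mito = np.asarray(mito, dtype=bool)
    if mito.any() and not (mito <= cell).all():
        raise ValueError(f"mito mask of cell {cell_id} extends outside the cell")
    area = int(mito.sum())
    if area == 0:
        return SpGFPMeasurement(
            cell_id=cell_id,
            mito_area_px=0,
            mito_threshold_value=threshold_value,
            spgfp_median=float("nan"),
            excluded=True,
            reason=QC_NO_MITO,
        )
    return SpGFPMeasurement(
        cell_id=cell_id,
        mito_area_px=area,
        mito_threshold_value=threshold_value,
        spgfp_median=float(np.median(gfp_proj.pixels[mito])),
        excluded=False,
    )


def quantify_image(
    gfp_stack: ImageStack,
    marker_stack: ImageStack,
    seg_params: SegmentationParams | None = None,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    per_image_max: bool = False,
    labels: CellLabelMap | None = None,
) -> tuple[pd.DataFrame, CellLabelMap]:
    """Run the full spGFP pipeline on one field of view.

    Z-sums both channels, segments cells (unless a precomputed ``labels`` map
    is supplied), and scores every segmented cell. Returns the per-cell table
    (columns ``cell_id, mito_area_px, mito_threshold_value, spgfp_median,
    excluded, reason``) and the label map. Cells excluded by segmentation QC
    (border-touching) or with empty mitochondrial masks are reported with
    reasons rather than dropped.
    """
    gfp_proj = sum_project(gfp_stack)
    marker_proj = sum_project(marker_stack)
    if labels is None:
        labels = segment_projections(marker_proj, gfp_proj, seg_params)

    qc = labels.qc.set_index("cell_id")
    rows = []
    for cid in labels.cell_ids:
        if not bool(qc.loc[cid, "included"]):
            rows.append(
                SpGFPMeasurement(
                    cell_id=cid,
                    mito_area_px=0,
                    mito_threshold_value=float("nan"),
                    spgfp_median=float("nan"),
                    excluded=True,
                    reason=str(qc.loc[cid, "reason"]),
                )
            )
            continue
        cell = labels.cell_mask(cid)
        ref = marker_proj.pixels.max() if per_image_max else marker_proj.pixels[cell].max()
        mask = mito_mask(cid, labels, marker_proj, threshold_frac, per_image_max)
        rows.append(
            spgfp_per_cell(cid, labels, gfp_proj, mask, threshold_value=threshold_frac * ref)
        )
    table = pd.DataFrame(
        [
            {
                "cell_id": m.cell_id,
                "mito_area_px": m.mito_area_px,
                "mito_threshold_value": m.mito_threshold_value,
                "spgfp_median": m.spgfp_median,
                "excluded": m.excluded,
                "reason": m.reason,
            }
            for m in rows
        ]
    )
    return table, labels
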