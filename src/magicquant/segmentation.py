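"""Cell segmentation of z-sum projections.

Two stages, mirroring the quantification pipeline for the split-GFP import
assay: background/foreground separation by random-walker segmentation with
automatic intensity-quantile seeds, then watershed separation of adjoining
cells on the negative Euclidean distance transform.

All outputs are deterministic: watershed markers and final labels are ordered
in raster order, which removes ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import random_walker, watershed

from .image_io import Projection2D

logger = logging.getLogger(__name__)

QC_BORDER = "touches_border"
QC_NO_MITO = "no mitochondrial signal"


class DegenerateImageError(ValueError):
    """Raised when an image has no intensity structure to segment (constant)."""


@dataclass
class SegmentationParams:
    """Tunable parameters of the two-stage segmentation.

    ``bg_seed_quantile`` / ``fg_seed_quantile`` pick the random-walker seeds:
    pixels at or below the background quantile of (smoothed) intensity seed
    background, pixels at or above the foreground quantile seed cells, and the
    solver assigns everything between. Quantile seeding makes the stage
    invariant to multiplying the projection by any positive constant.

    ``min_marker_separation_px`` suppresses distance-transform maxima closer
    together than about two thirds of a cell radius, so each cell contributes
    one watershed marker while small cells adjoining large ones keep theirs.
    """

    bg_seed_quantile: float = 0.20
    fg_seed_quantile: float = 0.90
    rw_beta: float = 130.0
    min_cell_area_px: int = 80
    smoothing_sigma_px: float = 1.0
    min_marker_separation_px: int = 8
    rw_tol: float = 1e-5

    def __post_init__(self) -> None:
        if not (0.0 < self.bg_seed_quantile < self.fg_seed_quantile < 1.0):
            raise ValueError("require 0 < bg_seed_quantile < fg_seed_quantile < 1")
        if self.rw_beta <= 0:
            raise ValueError("rw_beta must be > 0")
        if self.smoothing_sigma_px < 0:
            raise ValueError("smoothing_sigma_px must be >= 0")


@dataclass
class CellLabelMap:
    """Per-pixel cell identities on the 2D projection.

    ``labels`` uses 0 for background and 1..n for cells. ``qc`` has one row
    per cell id with columns ``cell_id, area_px, touches_border, included,
    reason``; border-touching cells keep their pixels but are excluded from
    downstream statistics.
    """

    labels: np.ndarray
    cell_ids: list[int]
    qc: pd.DataFrame

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def included_ids(self) -> list[int]:
        return [int(c) for c in self.qc.loc[self.qc["included"], "cell_id"]]

    def cell_mask(self, cell_id: int) -> np.ndarray:
        if cell_id not in self.cell_ids:
            raise KeyError(f"cell id {cell_id} not in label map")
        return self.labels == cell_id


def combined_projection(marker_proj: Projection2D, gfp_proj: Projection2D) -> Projection2D:
    """Sum of the min-max-normalized marker and reporter projections.

    A mitochondrial marker is sparse inside the cell; adding the reporter
    projection (which fills the cytosol) gives a segmentation image that
    covers whole cell bodies in either channel arrangement.
    """

    def norm(p: np.ndarray) -> np.ndarray:
        # robust upper reference: rare bright structures (puncta, hot pixels)
        # must not squash the cytosol toward zero
        lo = float(p.min())
        hi = float(np.quantile(p, 0.995))
        if hi <= lo:
            hi = float(p.max())  # sparse channel: the quantile sits on background
        if hi <= lo:
            return np.zeros_like(p)
        return np.clip((p - lo) / (hi - lo), 0.0, 1.0)

    return Projection2D(
        pixels=norm(marker_proj.pixels) + norm(gfp_proj.pixels),
        provenance=f"combine({marker_proj.provenance},{gfp_proj.provenance})",
    )


def segment_foreground(proj: Projection2D, params: SegmentationParams | None = None) -> np.ndarray:
    """Separate cells from background with seeded random-walker segmentation.

    Returns a boolean foreground mask covering every pixel of the projection.

    Raises
    ------
    DegenerateImageError
        If the projection is constant, so the seed quantiles collapse.
    """
    params = params or SegmentationParams()
    img = proj.pixels.astype(np.float64)
    if img.max() <= img.min():
        raise DegenerateImageError("projection is constant; nothing to segment")
    # normalize first: quantile seeds and edge weights become scale-free
    img = (img - img.min()) / (img.max() - img.min())
    # seeds come from the raw normalized image, so flat background stays
    # seeded even when smoothing spreads intensity across cell borders
    lo = np.quantile(img, params.bg_seed_quantile)
    hi = np.quantile(img, params.fg_seed_quantile)
    if hi <= lo:
        # sparse scenes: the foreground quantile fell on the background
        # plateau; seed foreground halfway between background and maximum
        hi = lo + 0.5 * (img.max() - lo)
    seeds = np.zeros(img.shape, dtype=np.int32)
    seeds[img <= lo] = 1
    seeds[img >= hi] = 2
    if params.smoothing_sigma_px > 0:
        img = ndi.gaussian_filter(img, params.smoothing_sigma_px)
        rng_ = img.max() - img.min()
        if rng_ <= 0:
            raise DegenerateImageError("projection is constant after smoothing")
        img = (img - img.min()) / rng_
    if not (seeds == 2).any() or hi <= lo:
        logger.warning("no foreground seeds; returning empty mask (no cells detected)")
        return np.zeros(img.shape, dtype=bool)
    if (seeds == 0).all() or not (seeds == 1).any():
        raise DegenerateImageError("seed quantiles collapsed; cannot seed both phases")

    labels = random_walker(img, seeds, beta=params.rw_beta, mode="cg_j", tol=params.rw_tol)
    return labels == 2


def split_cells(foreground: np.ndarray, params: SegmentationParams | None = None) -> CellLabelMap:
    """Split a foreground mask into individual cells by marker-based watershed.

    Markers are local maxima of the (lightly smoothed) Euclidean distance
    transform, suppressed within ``min_marker_separation_px``; watershed runs
    on the negative distance transform confined to the mask. Components under
    ``min_cell_area_px`` are removed; cells touching the image border are
    flagged and excluded from downstream statistics. Labels are dense 1..n in
    raster order of centroid.
    """
    params = params or SegmentationParams()
    mask = np.asarray(foreground, dtype=bool)
    if not mask.any():
        logger.info("empty foreground mask: zero cells")
        return CellLabelMap(
            labels=np.zeros(mask.shape, dtype=np.int32),
            cell_ids=[],
            qc=pd.DataFrame(
                columns=["cell_id", "area_px", "touches_border", "included", "reason"]
            ),
        )

    dist = ndi.distance_transform_edt(mask)
    dist_s = ndi.gaussian_filter(dist, 1.0)  # merge plateau maxima
    coords = peak_local_max(
        dist_s,
        min_distance=params.min_marker_separation_px,
        labels=mask,
        exclude_border=False,
    )
    if coords.size == 0:
        coords = np.array([np.unravel_index(np.argmax(dist_s), dist_s.shape)])
    # deterministic marker ids: raster order of peak coordinates
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, idx in enumerate(order, start=1):
        y, x = coords[idx]
        markers[y, x] = i
    ws = watershed(-dist_s, markers, mask=mask)

    # drop undersized components, flag border-touching cells
    ny, nx = mask.shape
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True

    kept = []
    for lab in np.unique(ws):
        if lab == 0:
            continue
        m = ws == lab
        area = int(m.sum())
        if area < params.min_cell_area_px:
            ws[m] = 0
            continue
        ys, xs = np.nonzero(m)
        kept.append(
            {
                "old": int(lab),
                "area": area,
                "cy": ys.mean(),
                "cx": xs.mean(),
                "touches_border": bool((m & border).any()),
            }
        )

    kept.sort(key=lambda r: (r["cy"], r["cx"]))
    labels = np.zeros(mask.shape, dtype=np.int32)
    rows = []
    for new_id, rec in enumerate(kept, start=1):
        labels[ws == rec["old"]] = new_id
        rows.append(
            {
                "cell_id": new_id,
                "area_px": rec["area"],
                "touches_border": rec["touches_border"],
                "included": not rec["touches_border"],
                "reason": QC_BORDER if rec["touches_border"] else "",
            }
        )
    qc = pd.DataFrame(rows, columns=["cell_id", "area_px", "touches_border", "included", "reason"])
    return CellLabelMap(labels=labels, cell_ids=[r["cell_id"] for r in rows], qc=qc)


def segment_projections(
    marker_proj: Projection2D,
    gfp_proj: Projection2D,
    params: SegmentationParams | None = None,
) -> CellLabelMap:
    """Full segmentation of one field of view from its two channel projections."""
    params = params or SegmentationParams()
    fg = segment_foreground(combined_projection(marker_proj, gfp_proj), params)
    return split_cells(fg, params)


def write_label_map(label_map: CellLabelMap, tiff_path, qc_csv_path=None) -> None:
    """Write a label map as 16-bit TIFF, optionally with its QC table as CSV."""
    import tifffile

    if label_map.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 cells; cannot store as 16-bit TIFF")
    tifffile.imwrite(str(tiff_path), label_map.labels.astype(np.uint16))
    if qc_csv_path is not None:
        label_map.qc.to_csv(qc_csv_path, index=False)


def match_labels(pred: np.ndarray, truth: np.ndarray) -> pd.DataFrame:
    """Match predicted to true cells by maximal overlap; report IoU per true cell.

    Returns a DataFrame with columns ``true_id, pred_id, iou`` (``pred_id`` 0
    and IoU 0 for undetected true cells). Used to evaluate segmentation
    against generator ground truth.
    """
    rows = []
    for tid in np.unique(truth):
        if tid == 0:
            continue
        tm = truth == tid
        overlap_ids, counts = np.unique(pred[tm], return_counts=True)
        nz = overlap_ids != 0
        if not nz.any():
            rows.append({"true_id": int(tid), "pred_id": 0, "iou": 0.0})
            continue
        best = overlap_ids[nz][np.argmax(counts[nz])]
        pm = pred == best
        inter = float(np.logical_and(tm, pm).sum())
        union = float(np.logical_or(tm, pm).sum())
        rows.append({"true_id": int(tid), "pred_id": int(best), "iou": inter / union})
    return pd.DataFrame(rows, columns=["true_id", "pred_id", "iou"])
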