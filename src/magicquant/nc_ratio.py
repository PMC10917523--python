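"""Nucleocytoplasmic ratio scoring of a GFP reporter with an RFP nuclear marker.

For each segmented cell the nuclear marker (e.g. Pus1-RFP) defines a
nucleoplasmic mask (per-cell Otsu threshold, largest connected component);
cytoplasm is the annulus obtained by dilating the nuclear mask and clipping it
to the cell, minus the nucleus itself. The per-cell readout is the mean
nuclear reporter intensity divided by the mean cytoplasmic reporter intensity;
population statistics operate on replicate means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .image_io import ImageStack, Projection2D, sum_project
from .segmentation import CellLabelMap, SegmentationParams, segment_projections


class CellExclusion(ValueError):
    """A cell could not be scored; ``reason`` says why."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class NCParams:
    """Nuclear/cytoplasmic masking parameters.

    ``dilation_radius_px`` sets the width of the cytoplasmic annulus (the
    dilation of the nuclear mask); ``min_contrast`` is the minimum ratio of
    mean marker intensity above vs below the per-cell Otsu threshold for the
    nucleus to count as distinct; ``whole_cell_cytoplasm`` replaces the
    annulus by all non-nuclear cell pixels.
    """

    dilation_radius_px: int = 3
    min_nuclear_area_px: int = 10
    min_contrast: float = 1.2
    whole_cell_cytoplasm: bool = False


@dataclass
class NCRatioMeasurement:
    cell_id: int
    nuclear_mean: float
    cytoplasmic_mean: float
    ratio: float
    nuclear_area_px: int
    dilation_radius_px: int
    excluded: bool = False
    reason: str = ""


def nuclear_mask(
    cell_id: int,
    labels: CellLabelMap,
    rfp_proj: Projection2D,
    params: NCParams | None = None,
) -> np.ndarray:
    """Nucleoplasmic mask of one cell from the nuclear marker projection.

    Thresholds the marker at the per-cell Otsu value and keeps the largest
    connected component.

    Raises
    ------
    CellExclusion
        When the marker is uniform, the above/below contrast is too low
        (no distinct nucleus), or the largest component is under
        ``min_nuclear_area_px``.
    """
    params = params or NCParams()
    cell = labels.cell_mask(cell_id)
    vals = rfp_proj.pixels[cell]
    if np.ptp(vals) == 0:
        raise CellExclusion("no distinct nucleus (uniform marker)")
    th = threshold_otsu(vals)
    above = cell & (rfp_proj.pixels > th)
    below = cell & ~above
    if not above.any() or not below.any():
        raise CellExclusion("no distinct nucleus (degenerate threshold)")
    lo = float(rfp_proj.pixels[below].mean())
    hi = float(rfp_proj.pixels[above].mean())
    if lo > 0 and hi / lo < params.min_contrast:
        raise CellExclusion("no distinct nucleus (low marker contrast)")
    comp, n = ndi.label(above)
    if n == 0:
        raise CellExclusion("no distinct nucleus")
    sizes = ndi.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    nuc = comp == largest
    if nuc.sum() < params.min_nuclear_area_px:
        raise CellExclusion("nucleus under minimum area")
    return nuc


def cytoplasm_mask(
    nuclear: np.ndarray,
    cell_mask: np.ndarray,
    dilation_radius_px: int,
    whole_cell: bool = False,
) -> np.ndarray:
    """Cytoplasmic mask: dilated nucleus clipped to the cell, minus the nucleus.

    With ``whole_cell=True`` the annulus is replaced by every non-nuclear
    pixel of the cell.

    Raises
    ------
    CellExclusion
        When the resulting mask is empty (zero dilation radius, or the
        nucleus fills the cell).
    """
    nuclear = np.asarray(nuclear, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not nuclear.any():
        raise CellExclusion("empty nuclear mask")
    if whole_cell:
        cyto = cell_mask & ~nuclear
    else:
        if dilation_radius_px < 1:
            raise CellExclusion("empty cytoplasmic annulus (zero dilation radius)")
        grown = ndi.binary_dilation(nuclear, structure=disk(dilation_radius_px))
        cyto = grown & cell_mask & ~nuclear
    if not cyto.any():
        raise CellExclusion("empty cytoplasmic annulus (nucleus fills cell)")
    return cyto


def nc_ratio_cell(
    cell_id: int,
    gfp_proj: Projection2D,
    nuclear: np.ndarray,
    cytoplasm: np.ndarray,
    dilation_radius_px: int = 0,
) -> NCRatioMeasurement:
    """Mean nuclear / mean cytoplasmic reporter intensity for one cell."""
    nuclear = np.asarray(nuclear, dtype=bool)
    cytoplasm = np.asarray(cytoplasm, dtype=bool)
    if (nuclear & cytoplasm).any():
        raise ValueError("nuclear and cytoplasmic masks overlap")
    if not nuclear.any() or not cytoplasm.any():
        raise CellExclusion("empty mask")
    nuc_mean = float(gfp_proj.pixels[nuclear].mean())
    cyt_mean = float(gfp_proj.pixels[cytoplasm].mean())
    if cyt_mean <= 0:
        raise CellExclusion("non-positive cytoplasmic mean")
    return NCRatioMeasurement(
        cell_id=cell_id,
        nuclear_mean=nuc_mean,
        cytoplasmic_mean=cyt_mean,
        ratio=nuc_mean / cyt_mean,
        nuclear_area_px=int(nuclear.sum()),
        dilation_radius_px=dilation_radius_px,
    )


def quantify_image(
    gfp_stack: ImageStack,
    rfp_stack: ImageStack,
    seg_params: SegmentationParams | None = None,
    nc_params: NCParams | None = None,
    labels: CellLabelMap | None = None,
) -> tuple[pd.DataFrame, CellLabelMap]:
    """Full N/C pipeline on one field of view.

    Returns the per-cell table (``cell_id, nuclear_mean, cytoplasmic_mean,
    ratio, nuclear_area_px, dilation_radius_px, excluded, reason``) and the
    label map; excluded cells carry the exclusion reason.
    """
    nc_params = nc_params or NCParams()
    gfp_proj = sum_project(gfp_stack)
    rfp_proj = sum_project(rfp_stack)
    if labels is None:
        labels = segment_projections(rfp_proj, gfp_proj, seg_params)

    qc = labels.qc.set_index("cell_id")
    rows = []
    for cid in labels.cell_ids:
        if not bool(qc.loc[cid, "included"]):
            rows.append(_excluded_row(cid, nc_params, str(qc.loc[cid, "reason"])))
            continue
        try:
            nuc = nuclear_mask(cid, labels, rfp_proj, nc_params)
            cyto = cytoplasm_mask(
                nuc,
                labels.cell_mask(cid),
                nc_params.dilation_radius_px,
                whole_cell=nc_params.whole_cell_cytoplasm,
            )
            m = nc_ratio_cell(cid, gfp_proj, nuc, cyto, nc_params.dilation_radius_px)
        except CellExclusion as exc:
            rows.append(_excluded_row(cid, nc_params, exc.reason))
            continue
        rows.append(
            {
                "cell_id": m.cell_id,
                "nuclear_mean": m.nuclear_mean,
                "cytoplasmic_mean": m.cytoplasmic_mean,
                "ratio": m.ratio,
                "nuclear_area_px": m.nuclear_area_px,
                "dilation_radius_px": m.dilation_radius_px,
                "excluded": False,
                "reason": "",
            }
        )
    return pd.DataFrame(rows), labels


def _excluded_row(cid: int, params: NCParams, reason: str) -> dict:
    return {
        "cell_id": cid,
        "nuclear_mean": float("nan"),
        "cytoplasmic_mean": float("nan"),
        "ratio": float("nan"),
        "nuclear_area_px": 0,
        "dilation_radius_px": params.dilation_radius_px,
        "excluded": True,
        "reason": reason,
    }
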