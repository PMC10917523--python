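"""Synthetic microscopy scenes and chase time courses with known ground truth.

The generator emulates the imaging regime of the assays this package
quantifies: budding-yeast-sized elliptical cells on a dark background, tubular
mitochondria (or a round nucleus) rendered bright in a marker channel, and a
reporter channel whose intensity carries a controllable mitochondrial
enrichment, nuclear/cytoplasmic ratio, or per-cell puncta. Images are built as
a designed 2D intensity pattern distributed over z-slices with a Gaussian
axial profile; only the z-sum of a stack is contractually meaningful, matching
the pipeline's first processing step. Camera noise follows the standard
fluorescence model: Poisson shot noise on expected counts followed by additive
Gaussian read noise.

Every scene carries its exact ground truth (cell label map, compartment masks
labeled by owning cell, per-cell designed intensities), so each downstream
stage of the pipeline has a recoverable answer.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import disk

from .image_io import ImageStack, write_stack
from .segmentation import CellLabelMap

MARKER_KINDS = ("mito", "nucleus")


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without exceeding the retry budget."""


@dataclass(frozen=True)
class SceneSpec:
    """Full parameterization of one synthetic two-channel scene.

    Intensity fields are in arbitrary camera units on the z-sum scale: the
    designed 2D pattern equals the expected value of the z-summed stack.

    Attributes
    ----------
    image_shape:
        ``(n_z, n_y, n_x)`` voxel counts. The default 12 half-micron slices
        span 6 um axially, a full yeast cell.
    n_cells:
        Number of cells to place (>= 1).
    cell_radius_px, cell_radius_sd_px:
        Mean and spread of the per-cell equivalent radius. At 0.16 um/px a
        12 px radius corresponds to a ~3.8 um yeast cell.
    mito_fraction:
        Fraction of each cell's area occupied by mitochondrial tubules.
    nuclear_radius_px:
        Nucleus radius for ``marker="nucleus"`` scenes.
    marker:
        Which structure the marker (mCherry/RFP) channel labels:
        ``"mito"`` or ``"nucleus"``.
    reporter_mito_enrichment:
        Ratio of true mean reporter intensity inside mitochondria to the
        cytosolic mean (1 = no enrichment).
    nc_ratio_true:
        True nuclear/cytoplasmic reporter intensity ratio (nucleus scenes).
    aggregate_fraction_true:
        Fraction of cells carrying >= 1 bright punctum; the number of positive
        cells is the rounded count, chosen at random without replacement.
    punctum_radius_px, punctum_gain:
        Punctum size and its brightness relative to that cell's cytosol.
    cytosol_level:
        Mean designed cytosolic reporter intensity (z-sum units).
    cell_brightness_cv:
        Lognormal coefficient of variation of per-cell expression level.
    background_level:
        Reporter-channel background added everywhere (z-sum units).
    marker_level, marker_background:
        Marker-channel intensity inside the labeled structure and elsewhere.
    poisson_scale:
        Gain of the shot-noise model: a voxel with expected intensity ``I``
        is drawn as ``g * Poisson(I / g)`` with ``g = poisson_scale``
        (variance ``g * I``). 0 disables shot noise.
    read_noise_sd:
        Standard deviation of per-voxel additive Gaussian read noise
        (0 disables). Negative values are clipped at zero, as a camera
        offset would.
    n_touching_pairs:
        Number of designed cell pairs that share a boundary (touch without
        overlap) to exercise watershed splitting.
    z_profile_sigma:
        Sigma, in slices, of the Gaussian axial intensity profile.
    margin_px:
        Minimum distance from any cell pixel to the image border, so that
        ground-truth cells are never border-truncated.
    max_placement_tries:
        Retry budget per cell before :class:`PlacementError` is raised.
    seed:
        RNG seed; identical spec + seed gives bit-identical output.
    """

    image_shape: tuple[int, int, int] = (12, 256, 256)
    n_cells: int = 20
    cell_radius_px: float = 12.0
    cell_radius_sd_px: float = 1.5
    mito_fraction: float = 0.15
    nuclear_radius_px: float = 5.0
    marker: str = "mito"
    reporter_mito_enrichment: float = 1.0
    nc_ratio_true: float = 1.0
    aggregate_fraction_true: float = 0.0
    punctum_radius_px: float = 2.0
    punctum_gain: float = 5.0
    cytosol_level: float = 100.0
    cell_brightness_cv: float = 0.1
    background_level: float = 5.0
    marker_level: float = 300.0
    marker_background: float = 2.0
    poisson_scale: float = 1.0
    read_noise_sd: float = 1.0
    n_touching_pairs: int = 1
    z_profile_sigma: float = 2.0
    margin_px: int = 4
    max_placement_tries: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.image_shape) != 3 or any(s <= 0 for s in self.image_shape):
            raise ValueError("image_shape must be three positive ints (n_z, n_y, n_x)")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("mito_fraction", "aggregate_fraction_true"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]; got {v}")
        for name in (
            "reporter_mito_enrichment",
            "nc_ratio_true",
            "poisson_scale",
            "read_noise_sd",
            "background_level",
            "cell_brightness_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.marker not in MARKER_KINDS:
            raise ValueError(f"marker must be one of {MARKER_KINDS}")
        if 2 * self.n_touching_pairs > self.n_cells:
            raise ValueError("n_touching_pairs cells exceed n_cells")


@dataclass
class SyntheticScene:
    """A rendered scene paired with its exact ground truth.

    ``mito_truth``, ``nuclear_truth`` and ``puncta_truth`` are integer maps
    whose nonzero value is the owning cell id (0 = no structure).
    ``true_values`` holds one row per cell with the designed compartment
    means on the z-sum scale.
    """

    spec: SceneSpec
    gfp_stack: ImageStack
    marker_stack: ImageStack
    cell_truth: CellLabelMap
    mito_truth: np.ndarray
    nuclear_truth: np.ndarray
    puncta_truth: np.ndarray
    true_values: pd.DataFrame


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size) -> np.ndarray:
    """Lognormal variates with the given arithmetic mean and CV."""
    if cv <= 0:
        return np.full(size, float(mean))
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def _sample_ellipse(rng: np.random.Generator, spec: SceneSpec):
    r = rng.normal(spec.cell_radius_px, spec.cell_radius_sd_px)
    r = float(np.clip(r, 0.6 * spec.cell_radius_px, 1.5 * spec.cell_radius_px))
    aspect = rng.uniform(0.78, 1.0)
    a = r / np.sqrt(aspect)  # major semi-axis
    b = r * np.sqrt(aspect)
    theta = rng.uniform(0.0, np.pi)
    return a, b, theta


def _ellipse_pixels(cy, cx, a, b, theta, shape):
    rr, cc = draw_ellipse(cy, cx, a, b, shape=shape, rotation=theta)
    return rr, cc


def _free(rr, cc, occupied, gap: int = 1) -> bool:
    """True if the candidate pixels and a 1-px guard ring are unoccupied."""
    if occupied[rr, cc].any():
        return False
    if gap:
        # check the guard ring on a local crop only
        y0, y1 = rr.min() - gap, rr.max() + gap + 1
        x0, x1 = cc.min() - gap, cc.max() + gap + 1
        crop = np.zeros((y1 - y0, x1 - x0), dtype=bool)
        crop[rr - y0, cc - x0] = True
        grown = ndi.binary_dilation(crop, structure=disk(gap))
        if occupied[y0:y1, x0:x1][grown].any():
            return False
    return True


def _place_cells(rng: np.random.Generator, spec: SceneSpec) -> np.ndarray:
    """Place non-overlapping elliptical cells; returns the 2D truth label map.

    The first ``2 * n_touching_pairs`` labels are the designed touching pairs:
    adjacent (sharing a boundary within 1 px) but never overlapping.
    """
    _, ny, nx = spec.image_shape
    labels = np.zeros((ny, nx), dtype=np.int32)
    occupied = np.zeros((ny, nx), dtype=bool)
    margin = spec.margin_px
    next_id = 1

    def commit(rr, cc):
        nonlocal next_id
        labels[rr, cc] = next_id
        occupied[rr, cc] = True
        next_id += 1

    amax = 1.5 * spec.cell_radius_px / np.sqrt(0.78)

    def random_center(rng, a):
        lo = a + margin + 1
        if ny - lo <= lo or nx - lo <= lo:
            raise PlacementError("image too small for the requested cell size")
        return rng.uniform(lo, ny - 1 - lo), rng.uniform(lo, nx - 1 - lo)

    def in_bounds(rr, cc):
        return (
            rr.min() >= margin
            and cc.min() >= margin
            and rr.max() < ny - margin
            and cc.max() < nx - margin
        )

    # Designed touching pairs first.
    for _ in range(spec.n_touching_pairs):
        placed = False
        for _try in range(spec.max_placement_tries):
            a1, b1, t1 = _sample_ellipse(rng, spec)
            a2, b2, t2 = _sample_ellipse(rng, spec)
            cy1, cx1 = random_center(rng, amax + 2 * amax)  # room for the partner
            rr1, cc1 = _ellipse_pixels(cy1, cx1, a1, b1, t1, labels.shape)
            if rr1.size == 0 or not _free(rr1, cc1, occupied):
                continue
            phi = rng.uniform(0.0, 2 * np.pi)
            dy, dx = np.sin(phi), np.cos(phi)
            # march the partner inwards until its mask would overlap; keep the
            # last non-overlapping offset -> adjacency without overlap
            mask1 = np.zeros(labels.shape, dtype=bool)
            mask1[rr1, cc1] = True
            best = None
            for d in np.arange(a1 + a2 + 3.0, 0.0, -0.5):
                cy2, cx2 = cy1 + d * dy, cx1 + d * dx
                rr2, cc2 = _ellipse_pixels(cy2, cx2, a2, b2, t2, labels.shape)
                if rr2.size == 0 or not in_bounds(rr2, cc2):
                    best = None
                    break
                if mask1[rr2, cc2].any() or occupied[rr2, cc2].any():
                    break
                best = (rr2, cc2)
            if best is None:
                continue
            rr2, cc2 = best
            commit(rr1, cc1)
            commit(rr2, cc2)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place touching pair within {spec.max_placement_tries} tries"
            )

    # Remaining solitary cells: forbid both overlap and accidental touching.
    for _ in range(spec.n_cells - 2 * spec.n_touching_pairs):
        placed = False
        for _try in range(spec.max_placement_tries):
            a, b, t = _sample_ellipse(rng, spec)
            cy, cx = random_center(rng, a)
            rr, cc = _ellipse_pixels(cy, cx, a, b, t, labels.shape)
            if rr.size == 0 or not in_bounds(rr, cc):
                continue
            if not _free(rr, cc, occupied, gap=2):
                continue
            commit(rr, cc)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {next_id} within {spec.max_placement_tries} "
                "tries; reduce n_cells or cell_radius_px"
            )
    return labels


def _mito_walk(rng: np.random.Generator, cell_mask: np.ndarray, target_px: int) -> np.ndarray:
    """Tubular mitochondria: persistent random-walk curves dilated to ~3 px width."""
    ys, xs = np.nonzero(cell_mask)
    if ys.size == 0:
        return np.zeros_like(cell_mask)
    cy, cx = ys.mean(), xs.mean()
    skeleton = np.zeros_like(cell_mask)
    budget = 40
    while skeleton.sum() < max(target_px // 3, 2) and budget > 0:
        budget -= 1
        i = rng.integers(0, ys.size)
        y, x = float(ys[i]), float(xs[i])
        theta = rng.uniform(0, 2 * np.pi)
        for _ in range(int(4 * np.sqrt(cell_mask.sum()))):
            theta += rng.normal(0.0, 0.35)
            y2, x2 = y + np.sin(theta), x + np.cos(theta)
            iy, ix = int(round(y2)), int(round(x2))
            if (
                iy < 0
                or ix < 0
                or iy >= cell_mask.shape[0]
                or ix >= cell_mask.shape[1]
                or not cell_mask[iy, ix]
            ):
                # steer back toward the cell center instead of leaving
                theta = np.arctan2(cy - y, cx - x) + rng.normal(0.0, 0.3)
                continue
            y, x = y2, x2
            skeleton[iy, ix] = True
        tubules = ndi.binary_dilation(skeleton, structure=disk(1)) & cell_mask
        if tubules.sum() >= target_px:
            break
    return ndi.binary_dilation(skeleton, structure=disk(1)) & cell_mask


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Render a two-channel scene from ``spec`` with exact ground truth.

    Raises
    ------
    PlacementError
        If cells cannot be placed within the retry budget.
    """
    rng = np.random.default_rng(spec.seed)
    n_z, ny, nx = spec.image_shape
    labels = _place_cells(rng, spec)
    n = spec.n_cells
    objects = ndi.find_objects(labels)

    mito_truth = np.zeros((ny, nx), dtype=np.int32)
    nuclear_truth = np.zeros((ny, nx), dtype=np.int32)
    puncta_truth = np.zeros((ny, nx), dtype=np.int32)

    brightness = spec.cytosol_level * _lognormal(rng, 1.0, spec.cell_brightness_cv, n)

    n_positive = int(round(spec.aggregate_fraction_true * n))
    positive_ids = set((rng.permutation(n) + 1)[:n_positive].tolist())

    gfp2d = np.full((ny, nx), spec.background_level, dtype=np.float64)
    marker2d = np.full((ny, nx), spec.marker_background, dtype=np.float64)

    rows = []
    for cid in range(1, n + 1):
        sl = objects[cid - 1]
        cell = labels[sl] == cid
        area = int(cell.sum())
        c_i = brightness[cid - 1]
        gfp_local = np.where(cell, spec.background_level + c_i, gfp2d[sl])
        marker_local = marker2d[sl].copy()

        mito_mean_true = np.nan
        nuclear_mean_true = np.nan
        spgfp_true = np.nan
        nc_true = np.nan

        if spec.marker == "mito":
            target = max(int(spec.mito_fraction * area), 4)
            tub = _mito_walk(rng, cell, target)
            mito_truth[sl][tub] = cid
            gfp_local[tub] = spec.background_level + c_i * spec.reporter_mito_enrichment
            marker_local[tub] = spec.marker_level
            mito_mean_true = spec.background_level + c_i * spec.reporter_mito_enrichment
            spgfp_true = mito_mean_true
        else:
            ys, xs = np.nonzero(cell)
            cy, cx = ys.mean(), xs.mean()
            rr, cc = draw_disk((cy, cx), spec.nuclear_radius_px, shape=cell.shape)
            nuc = np.zeros_like(cell)
            nuc[rr, cc] = True
            nuc &= cell
            nuclear_truth[sl][nuc] = cid
            gfp_local[nuc] = spec.background_level + c_i * spec.nc_ratio_true
            marker_local[nuc] = spec.marker_level
            nuclear_mean_true = spec.background_level + c_i * spec.nc_ratio_true
            nc_true = nuclear_mean_true / (spec.background_level + c_i)

        n_puncta = 0
        if cid in positive_ids:
            pr = int(np.ceil(spec.punctum_radius_px))
            interior = ndi.binary_erosion(cell, disk(pr + 1))
            pys, pxs = np.nonzero(interior)
            if pys.size == 0:
                pys, pxs = np.nonzero(cell)
            j = rng.integers(0, pys.size)
            rr, cc = draw_disk((pys[j], pxs[j]), spec.punctum_radius_px, shape=cell.shape)
            pm = np.zeros_like(cell)
            pm[rr, cc] = True
            pm &= cell
            puncta_truth[sl][pm] = cid
            gfp_local[pm] = spec.background_level + c_i * spec.punctum_gain
            n_puncta = 1

        gfp2d[sl] = np.where(cell, gfp_local, gfp2d[sl])
        marker2d[sl] = np.where(cell, marker_local, marker2d[sl])
        rows.append(
            {
                "cell_id": cid,
                "area_px": area,
                "cytosol_mean_true": spec.background_level + c_i,
                "mito_mean_true": mito_mean_true,
                "spgfp_true": spgfp_true,
                "nuclear_mean_true": nuclear_mean_true,
                "nc_ratio_true": nc_true,
                "n_puncta_true": n_puncta,
                "has_aggregate_true": cid in positive_ids,
                "in_touching_pair": cid <= 2 * spec.n_touching_pairs,
            }
        )

    true_values = pd.DataFrame(rows)

    # axial Gaussian profile; the z-sum of the expectation equals the design
    z = np.arange(n_z, dtype=np.float64)
    w = np.exp(-0.5 * ((z - (n_z - 1) / 2.0) / spec.z_profile_sigma) ** 2)
    w /= w.sum()

    def render(design: np.ndarray) -> np.ndarray:
        expected = w[:, None, None] * design[None, :, :]
        if spec.poisson_scale > 0:
            g = spec.poisson_scale
            out = g * rng.poisson(expected / g).astype(np.float64)
        else:
            out = expected.copy()
        if spec.read_noise_sd > 0:
            out += rng.normal(0.0, spec.read_noise_sd, size=out.shape)
        return np.clip(out, 0.0, None)

    gfp_stack = ImageStack(render(gfp2d), channel_name="GFP")
    marker_stack = ImageStack(render(marker2d), channel_name="mCherry")

    qc = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "area_px": true_values["area_px"].to_numpy(),
            "touches_border": False,
            "included": True,
            "reason": "",
        }
    )
    cell_truth = CellLabelMap(labels=labels, cell_ids=list(range(1, n + 1)), qc=qc)
    return SyntheticScene(
        spec=spec,
        gfp_stack=gfp_stack,
        marker_stack=marker_stack,
        cell_truth=cell_truth,
        mito_truth=mito_truth,
        nuclear_truth=nuclear_truth,
        puncta_truth=puncta_truth,
        true_values=true_values,
    )


def write_scene(scene: SyntheticScene, out_dir) -> None:
    """Write a scene as two TIFF stacks, a ground-truth CSV and a spec JSON sidecar."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_stack(out / "gfp.tif", scene.gfp_stack)
    write_stack(out / "marker.tif", scene.marker_stack)
    scene.true_values.to_csv(out / "truth.csv", index=False)
    spec_dict = dataclasses.asdict(scene.spec)
    spec_dict["image_shape"] = list(spec_dict["image_shape"])
    (out / "scene_spec.json").write_text(json.dumps(spec_dict, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# chase time courses


@dataclass(frozen=True)
class ChaseSpec:
    """Parameters of a synthetic single-cell degradation chase.

    Each cell's expected intensity is ``background_mean + initial_i *
    exp(-decay_rate_per_min * t)``; per-cell initial intensities are lognormal
    with mean ``initial_mean`` and CV ``cell_cv``. One pre-induction row per
    cell carries background only (``is_background``), emulating the
    autofluorescence measurement taken before reporter induction.
    """

    n_cells: int = 1000
    timepoints_min: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0)
    decay_rate_per_min: float = 0.03
    initial_mean: float = 1000.0
    background_mean: float = 50.0
    cell_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        t = np.asarray(self.timepoints_min, dtype=float)
        if t.size < 1 or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints_min must be strictly increasing")
        if self.decay_rate_per_min < 0:
            raise ValueError("decay_rate_per_min must be >= 0")
        if self.cell_cv < 0:
            raise ValueError("cell_cv must be >= 0")


def generate_chase(spec: ChaseSpec) -> pd.DataFrame:
    """Generate a long-format per-cell chase table.

    Returns a DataFrame with columns ``cell_id, time_min, intensity,
    is_background``; the background rows carry ``time_min`` of the
    pre-induction measurement (set to -30 by convention).
    """
    rng = np.random.default_rng(spec.seed)
    init = _lognormal(rng, spec.initial_mean, spec.cell_cv, spec.n_cells)
    t = np.asarray(spec.timepoints_min, dtype=float)
    k = spec.decay_rate_per_min
    inten = spec.background_mean + init[:, None] * np.exp(-k * t[None, :])

    cells = np.arange(1, spec.n_cells + 1)
    frames = [
        pd.DataFrame(
            {
                "cell_id": cells,
                "time_min": -30.0,
                "intensity": np.full(spec.n_cells, spec.background_mean),
                "is_background": True,
            }
        )
    ]
    for j, tj in enumerate(t):
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": cells,
                    "time_min": tj,
                    "intensity": inten[:, j],
                    "is_background": False,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
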