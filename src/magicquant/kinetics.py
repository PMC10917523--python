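"""Chase-assay degradation kinetics.

Implements the standard cycloheximide-chase quantification: per-timepoint mean
intensities are background-subtracted (background measured before reporter
induction) and normalized to the first chase time point, giving a relative
decay curve with ``relative[t0] = 1`` by construction. An optional
origin-constrained log-linear fit estimates the first-order decay rate and
half-life. Group comparisons are per-timepoint two-tailed t-tests on
replicate-level relative intensities, with no multiplicity correction
(per-timepoint reporting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import _ttest

logger = logging.getLogger(__name__)


class NormalizationError(ValueError):
    """Signal at the first time point is indistinguishable from background."""


class AlignmentError(ValueError):
    """Replicate curves do not share a common timepoint grid."""


@dataclass
class ChaseCurve:
    """One background-subtracted, t0-normalized chase curve."""

    timepoints_min: np.ndarray
    raw_means: np.ndarray
    background: float
    relative: np.ndarray
    replicate: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.timepoints_min = np.asarray(self.timepoints_min, dtype=float)
        self.raw_means = np.asarray(self.raw_means, dtype=float)
        self.relative = np.asarray(self.relative, dtype=float)


@dataclass
class DecayFit:
    rate_per_min: float
    half_life_min: float  # inf when rate == 0
    rss: float
    n_points: int


def build_curve(
    timepoints_min,
    raw_means,
    background: float,
    replicate: str = "",
    group: str = "",
) -> ChaseCurve:
    """Background-subtract and normalize a raw mean-intensity time course.

    ``relative = (raw - background) / (raw[t0] - background)``; negative
    post-subtraction values are clipped to 0 with a warning.

    Raises
    ------
    NormalizationError
        When ``raw[t0] <= background``.
    """
    t = np.asarray(timepoints_min, dtype=float)
    raw = np.asarray(raw_means, dtype=float)
    if t.ndim != 1 or t.shape != raw.shape or t.size < 1:
        raise ValueError("timepoints and raw means must be 1D arrays of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    denom = raw[0] - background
    if denom <= 0:
        raise NormalizationError(
            f"raw intensity at t0 ({raw[0]:g}) does not exceed background ({background:g})"
        )
    sub = raw - background
    if np.any(sub < 0):
        logger.warning("negative background-subtracted intensities clipped to 0")
        sub = np.clip(sub, 0.0, None)
    return ChaseCurve(
        timepoints_min=t,
        raw_means=raw,
        background=float(background),
        relative=sub / denom,
        replicate=replicate,
        group=group,
    )


def curves_from_table(df: pd.DataFrame) -> list[ChaseCurve]:
    """Build one curve per (group, replicate) from a long-format chase table.

    Expects columns ``group, replicate, time_min, intensity, is_background``
    (``group``/``replicate`` optional; a single curve is built when absent).
    Background is the mean intensity of the ``is_background`` rows; raw means
    are per-timepoint means of the remaining rows (averaging cells when a
    ``cell_id`` column makes rows single-cell measurements).
    """
    df = df.copy()
    for col in ("group", "replicate"):
        if col not in df.columns:
            df[col] = ""
    if "is_background" not in df.columns:
        df["is_background"] = False
    curves = []
    for (grp, rep), sub in df.groupby(["group", "replicate"], sort=True):
        bg_rows = sub[sub["is_background"].astype(bool)]
        background = float(bg_rows["intensity"].mean()) if len(bg_rows) else 0.0
        chase = sub[~sub["is_background"].astype(bool)]
        means = chase.groupby("time_min", sort=True)["intensity"].mean()
        curves.append(
            build_curve(
                means.index.to_numpy(dtype=float),
                means.to_numpy(dtype=float),
                background,
                replicate=str(rep),
                group=str(grp),
            )
        )
    return curves


def fit_decay(curve: ChaseCurve) -> DecayFit:
    """Origin-constrained log-linear decay fit: ``log R = -k t``.

    Least squares over the timepoints with positive relative intensity;
    ``k`` is clipped at 0. Requires at least 3 usable points.
    """
    usable = curve.relative > 0
    if int(usable.sum()) < 3:
        raise ValueError("fewer than 3 timepoints with positive relative intensity")
    t = curve.timepoints_min[usable]
    logr = np.log(curve.relative[usable])
    denom = float(np.sum(t * t))
    k = -float(np.sum(t * logr)) / denom if denom > 0 else 0.0
    k = max(k, 0.0)
    model = np.exp(-k * curve.timepoints_min)
    rss = float(np.sum((curve.relative - model) ** 2))
    return DecayFit(
        rate_per_min=k,
        half_life_min=float(np.log(2) / k) if k > 0 else float("inf"),
        rss=rss,
        n_points=int(usable.sum()),
    )


def compare_timepoints(curves: list[ChaseCurve], test: str = "welch") -> pd.DataFrame:
    """Per-timepoint two-tailed unpaired t-tests between two groups of curves.

    Operates on replicate-level relative intensities: at each timepoint the
    two groups' replicate values are compared; no multiplicity correction is
    applied. Returns a DataFrame with columns ``time_min, group_a, group_b,
    statistic, pvalue, n_a, n_b``.

    Raises
    ------
    AlignmentError
        When curves do not share an identical timepoint grid.
    ValueError
        When there are not exactly two groups or fewer than 2 replicates in
        either group.
    """
    if not curves:
        raise ValueError("no curves supplied")
    grid = curves[0].timepoints_min
    for c in curves[1:]:
        if c.timepoints_min.shape != grid.shape or not np.allclose(c.timepoints_min, grid):
            raise AlignmentError("curves have mismatched timepoint grids")
    groups = sorted({c.group for c in curves})
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    ga, gb = groups
    a = np.array([c.relative for c in curves if c.group == ga])
    b = np.array([c.relative for c in curves if c.group == gb])
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 replicate curves per group")
    rows = []
    for j, tj in enumerate(grid):
        stat, p = _ttest(a[:, j], b[:, j], test)
        rows.append(
            {
                "time_min": float(tj),
                "group_a": ga,
                "group_b": gb,
                "statistic": stat,
                "pvalue": p,
                "n_a": a.shape[0],
                "n_b": b.shape[0],
            }
        )
    return pd.DataFrame(rows)


def curves_to_frame(curves: list[ChaseCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for t, raw, rel in zip(c.timepoints_min, c.raw_means, c.relative):
            rows.append(
                {
                    "group": c.group,
                    "replicate": c.replicate,
                    "time_min": t,
                    "raw_mean": raw,
                    "background": c.background,
                    "relative": rel,
                }
            )
    return pd.DataFrame(rows)
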