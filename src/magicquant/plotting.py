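"""Small plotting helpers for chase curves and hydropathy profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .hydropathy import HydropathyProfile  # noqa: E402
from .kinetics import ChaseCurve  # noqa: E402


def plot_chase(curves: list[ChaseCurve], path) -> None:
    """Relative-intensity chase curves, one line per replicate, colored by group."""
    fig, ax = plt.subplots(figsize=(5, 4))
    groups = sorted({c.group for c in curves})
    colors = plt.get_cmap("tab10")
    for c in curves:
        gi = groups.index(c.group)
        ax.plot(
            c.timepoints_min,
            c.relative,
            marker="o",
            color=colors(gi),
            alpha=0.7,
            label=c.group if c.replicate in ("", "1") else None,
        )
    ax.set_xlabel("time (min)")
    ax.set_ylabel("relative intensity")
    ax.set_ylim(bottom=0)
    if any(g for g in groups):
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_hydropathy(profile: HydropathyProfile, path) -> None:
    """Windowed hydropathy score vs center-residue position."""
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(profile.positions, profile.scores, color="tab:blue")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("residue position (window center)")
    ax.set_ylabel(f"{profile.scale_name} score (window {profile.window})")
    if profile.sequence_id:
        ax.set_title(profile.sequence_id)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
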