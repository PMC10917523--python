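"""Kyte-Doolittle hydropathy profiling.

Sliding-window hydropathy in the ProtScale parameterization: an odd window
(default 5 residues), a relative edge weight with linear variation toward the
window center, and no normalization of the output. At the default edge weight
of 100% all window weights are equal and the score is the plain mean of the
scale values; the weighting machinery is implemented generally and collapses
to uniform in that case.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

# Kyte & Doolittle (1982) hydropathy scale, standard one-letter codes.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5,
    "V": 4.2,
    "L": 3.8,
    "F": 2.8,
    "C": 2.5,
    "M": 1.9,
    "A": 1.8,
    "G": -0.4,
    "T": -0.7,
    "S": -0.8,
    "W": -0.9,
    "Y": -1.3,
    "P": -1.6,
    "H": -3.2,
    "E": -3.5,
    "Q": -3.5,
    "D": -3.5,
    "N": -3.5,
    "K": -3.9,
    "R": -4.5,
}


class SequenceError(ValueError):
    """Raised for non-standard residues or sequences shorter than the window."""


@dataclass
class HydropathyProfile:
    """Windowed hydropathy scores indexed by the window's center residue.

    ``positions`` are 1-based center-residue indices (ProtScale display
    convention); ``scores`` has length ``L - window + 1``.
    """

    sequence_id: str
    window: int
    positions: np.ndarray
    scores: np.ndarray
    scale_name: str = "Kyte-Doolittle"


def window_weights(window: int, edge_weight: float = 1.0) -> np.ndarray:
    """Normalized window weights: linear variation from ``edge_weight`` at the
    edges to 1 at the center. ``edge_weight=1`` gives uniform weights."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if not 0.0 < edge_weight <= 1.0:
        raise ValueError("edge_weight must be in (0, 1]")
    if window == 1:
        return np.ones(1)
    c = (window - 1) / 2.0
    j = np.arange(window, dtype=float)
    w = edge_weight + (1.0 - edge_weight) * (1.0 - np.abs(j - c) / c)
    return w / w.sum()


def kd_profile(
    sequence: str,
    window: int = 5,
    edge_weight: float = 1.0,
    sequence_id: str = "",
    scale: dict[str, float] | None = None,
    scale_name: str = "Kyte-Doolittle",
) -> HydropathyProfile:
    """Hydropathy profile of an amino-acid sequence.

    Raises
    ------
    SequenceError
        For residues outside the 20 standard one-letter codes (the message
        lists the offending 1-based positions) or a sequence shorter than the
        window.
    """
    scale = scale if scale is not None else KYTE_DOOLITTLE
    seq = sequence.strip().upper()
    bad = [i + 1 for i, aa in enumerate(seq) if aa not in scale]
    if bad:
        raise SequenceError(f"non-standard residues at positions {bad}")
    if len(seq) < window:
        raise SequenceError(f"sequence length {len(seq)} is shorter than window {window}")
    values = np.array([scale[aa] for aa in seq], dtype=float)
    w = window_weights(window, edge_weight)
    scores = np.convolve(values, w[::-1], mode="valid")
    half = (window - 1) // 2
    positions = np.arange(half + 1, len(seq) - half + 1)
    return HydropathyProfile(
        sequence_id=sequence_id,
        window=window,
        positions=positions,
        scores=scores,
        scale_name=scale_name,
    )


def load_scale_csv(path) -> dict[str, float]:
    """Load an alternate residue scale from a two-column CSV (residue, value)."""
    out: dict[str, float] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#"):
                continue
            out[row[0].strip().upper()] = float(row[1])
    if not out:
        raise ValueError(f"no scale entries found in {path!r}")
    return out


def profiles_from_fasta(path, window: int = 5, edge_weight: float = 1.0):
    """Profile every record of a FASTA file."""
    from Bio import SeqIO

    return [
        kd_profile(str(rec.seq), window=window, edge_weight=edge_weight, sequence_id=rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
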