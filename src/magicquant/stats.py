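"""Replicate-level summaries and two-tailed t-tests.

All group statistics in this package operate on biological-replicate means,
not on pooled single cells: the per-cell tables are first collapsed to one
mean per (group, replicate), and grand means, SEMs and t-tests are computed
over those replicate means (n = number of replicates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class PairingError(ValueError):
    """Raised when a paired test is requested but replicate ids do not match."""


@dataclass
class GroupSummary:
    group: str
    replicate_means: np.ndarray
    grand_mean: float
    sem: float  # NaN when fewer than 2 replicates
    n_replicates: int
    relative_to: str | None = None
    relative_value: float = float("nan")


@dataclass
class TTestResult:
    group_a: str
    group_b: str
    test: str  # "welch", "student" or "paired"
    statistic: float
    pvalue: float


def replicate_means(df: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Collapse a per-cell table to one mean per (group, replicate)."""
    for col in ("group", "replicate", value_col):
        if col not in df.columns:
            raise KeyError(f"missing column {col!r}")
    out = (
        df.groupby(["group", "replicate"], sort=True)[value_col]
        .mean()
        .reset_index()
        .rename(columns={value_col: "mean"})
    )
    return out


def _ttest(a: np.ndarray, b: np.ndarray, test: str) -> tuple[float, float]:
    with warnings.catch_warnings():
        # near-identical replicate means trip scipy's precision-loss note;
        # the degenerate all-equal cases are short-circuited above it
        warnings.filterwarnings(
            "ignore", message="Precision loss occurred", category=RuntimeWarning
        )
        if test == "paired":
            d = a - b
            if np.allclose(d, 0.0):
                return 0.0, 1.0
            res = sps.ttest_rel(a, b)
        elif test in ("welch", "student"):
            if np.allclose(a, b) and np.ptp(a) == 0 and np.ptp(b) == 0:
                return 0.0, 1.0
            res = sps.ttest_ind(a, b, equal_var=(test == "student"))
        else:
            raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def summarize_groups(
    df: pd.DataFrame,
    value_col: str = "value",
    test: str = "welch",
    reference: str | None = None,
) -> tuple[list[GroupSummary], list[TTestResult]]:
    """Replicate-mean summaries per group plus two-tailed t-tests.

    Parameters
    ----------
    df:
        Per-cell table with columns ``group``, ``replicate`` and
        ``value_col``.
    test:
        ``"welch"`` (default; unequal-variance unpaired), ``"student"``
        (pooled-variance unpaired) or ``"paired"`` (on matching replicate
        ids).
    reference:
        Group whose grand mean defines relative values; defaults to the first
        group in sorted order. With more than two groups, each non-reference
        group is tested against the reference; with exactly two, a single test
        is performed.

    Raises
    ------
    PairingError
        For a paired test when the two groups' replicate id sets differ.
    """
    rm = replicate_means(df, value_col)
    groups = sorted(rm["group"].unique().tolist())
    if not groups:
        raise ValueError("no groups present")
    if reference is None:
        reference = groups[0]
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not present")

    by_group = {g: rm[rm["group"] == g].sort_values("replicate") for g in groups}
    ref_mean = float(by_group[reference]["mean"].mean())

    summaries = []
    for g in groups:
        means = by_group[g]["mean"].to_numpy(dtype=float)
        n = means.size
        summaries.append(
            GroupSummary(
                group=g,
                replicate_means=means,
                grand_mean=float(means.mean()),
                sem=float(means.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan"),
                n_replicates=n,
                relative_to=reference,
                relative_value=float(means.mean() / ref_mean) if ref_mean != 0 else float("nan"),
            )
        )

    if len(groups) == 2:
        pairs = [(groups[0], groups[1])]
    else:
        pairs = [(reference, g) for g in groups if g != reference]

    tests = []
    for ga, gb in pairs:
        a_df, b_df = by_group[ga], by_group[gb]
        if test == "paired":
            a_ids = set(a_df["replicate"])
            b_ids = set(b_df["replicate"])
            if a_ids != b_ids:
                raise PairingError(
                    f"paired test needs matching replicate ids; {ga}: {sorted(a_ids)}, "
                    f"{gb}: {sorted(b_ids)}"
                )
            # align by replicate id
            a = a_df.set_index("replicate")["mean"].sort_index().to_numpy(dtype=float)
            b = b_df.set_index("replicate")["mean"].sort_index().to_numpy(dtype=float)
        else:
            a = a_df["mean"].to_numpy(dtype=float)
            b = b_df["mean"].to_numpy(dtype=float)
        stat, p = _ttest(a, b, test)
        tests.append(TTestResult(group_a=ga, group_b=gb, test=test, statistic=stat, pvalue=p))
    return summaries, tests


def summaries_to_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": s.group,
                "grand_mean": s.grand_mean,
                "sem": s.sem,
                "n_replicates": s.n_replicates,
                "relative_to": s.relative_to,
                "relative_value": s.relative_value,
            }
            for s in summaries
        ]
    )


def tests_to_frame(tests: list[TTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_a": t.group_a,
                "group_b": t.group_b,
                "test": t.test,
                "statistic": t.statistic,
                "pvalue": t.pvalue,
            }
            for t in tests
        ]
    )
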