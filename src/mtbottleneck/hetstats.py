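"""Grouped single-cell heteroplasmy/copy-number summaries and resampling tests.

Per-cell measurements (heteroplasmy fraction h, mtDNA copies N) from sorted
cells are summarised per line x protocol x day x gate group, and segregation
is tested as a one-sided bootstrap question: is the heteroplasmy variance at
a later day greater than at the D4 reference?  Multiplicity across later
days is handled with Benjamini-Hochberg control at FDR q.  A two-sided
Mann-Whitney U test probes median shifts (selection), and fold changes
summarise the copy-number bottleneck depth.

Heteroplasmy is always handled on the fraction scale: the reported group
variances (0.015-0.041) are only consistent with fractions, not percent.
Variances are sample variances (n - 1 denominator) unless stated otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestConfig",
    "BootstrapResult",
    "group_summaries",
    "bootstrap_variance_increase_test",
    "bh_adjust",
    "fold_change",
    "median_shift_test",
    "variance_increase_suite",
]

GROUP_KEYS = ("line", "protocol", "day", "gate")


@dataclass(frozen=True)
class TestConfig:
    """Bootstrap test configuration: B resamples, one-sided greater, FDR q."""

    iterations: int = 50_000
    q: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must lie strictly in (0, 1)")


@dataclass(frozen=True)
class BootstrapResult:
    p_value: float
    observed_delta: float
    iterations: int
    n_ref: int
    n_alt: int


def _clean(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    n_missing = int(np.sum(~np.isfinite(x)))
    if n_missing:
        warnings.warn(f"dropping {n_missing} missing values", stacklevel=3)
    return x[np.isfinite(x)]


def group_summaries(
    records: pd.DataFrame,
    keys: Sequence[str] = GROUP_KEYS,
    value: str = "heteroplasmy",
    ddof: int = 1,
) -> pd.DataFrame:
    """Per-group n, mean, SD, median and sample variance of one measurement.

    Missing values are dropped per group; groups left empty are omitted with
    a warning.  ``ddof=1`` gives the unbiased sample variance (default).
    """
    keys = list(keys)
    if value not in records.columns:
        raise KeyError(f"column {value!r} not in records")
    rows = []
    for group, sub in records.groupby(keys, sort=True, observed=True):
        x = sub[value].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        if len(x) == 0:
            warnings.warn(f"group {group} has no non-missing {value}; omitted")
            continue
        group = group if isinstance(group, tuple) else (group,)
        rows.append(
            dict(zip(keys, group))
            | {
                "n_cells": len(x),
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=ddof)) if len(x) > ddof else 0.0,
                "median": float(np.median(x)),
                "variance": float(np.var(x, ddof=ddof)) if len(x) > ddof else 0.0,
            }
        )
    return pd.DataFrame(rows)


def bootstrap_variance_increase_test(
    ref,
    alt,
    config: TestConfig = TestConfig(),
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """One-sided bootstrap test for Var(alt) > Var(ref).

    Each group is resampled with replacement to its own size, B times; the
    statistic is the variance difference Delta* = Var*(alt) - Var*(ref) and
    the p-value is the bootstrap probability that Delta* <= 0 (the one-sided
    percentile-CI criterion).  The add-one convention
    p = (1 + #{Delta* <= 0}) / (B + 1) keeps p away from exactly 0, and the
    result is invariant to the ordering of the input values.
    """
    ref = _clean(ref)
    alt = _clean(alt)
    if len(ref) < 3 or len(alt) < 3:
        raise ValueError("each group needs at least 3 non-missing values")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    B = config.iterations
    idx_ref = rng.integers(0, len(ref), size=(B, len(ref)))
    idx_alt = rng.integers(0, len(alt), size=(B, len(alt)))
    var_ref = np.var(ref[idx_ref], axis=1, ddof=1)
    var_alt = np.var(alt[idx_alt], axis=1, ddof=1)
    delta = var_alt - var_ref
    p = (1 + int(np.sum(delta <= 0.0))) / (B + 1)
    observed = float(np.var(alt, ddof=1) - np.var(ref, ddof=1))
    return BootstrapResult(p, observed, B, len(ref), len(alt))


def bh_adjust(pvalues, q: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values) at FDR q."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


@dataclass(frozen=True)
class FoldChange:
    ratio: float
    fold: int


def fold_change(mean_a: float, mean_b: float) -> FoldChange:
    """Ratio mean_a / mean_b and its nearest-integer fold."""
    if mean_b <= 0:
        raise ValueError("denominator mean must be positive")
    ratio = mean_a / mean_b
    return FoldChange(float(ratio), int(round(ratio)))


def median_shift_test(a, b, alternative: str = "two-sided") -> float:
    """Mann-Whitney U p-value for a location shift between two groups.

    Exact null distribution for small tie-free samples, normal approximation
    with tie correction otherwise (scipy's automatic policy).  Degenerate
    all-tied input returns p = 1 with a warning.
    """
    a = _clean(a)
    b = _clean(b)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied; median-shift test is uninformative")
        return 1.0
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="auto")
    return float(res.pvalue)


def variance_increase_suite(
    records: pd.DataFrame,
    ref_day: str = "D4",
    config: TestConfig = TestConfig(),
    keys: Sequence[str] = ("line", "protocol", "gate"),
    value: str = "heteroplasmy",
) -> pd.DataFrame:
    """Run the bootstrap variance test for every later day against ref_day.

    Cells are pooled across replicates within each day (one variance per day).
    Within each line x protocol x gate stratum, every day later than
    ``ref_day`` is tested against it and the per-stratum p-values are
    BH-adjusted at the configured FDR.
    """
    rows = []
    rng = np.random.default_rng(config.seed)
    for stratum, sub in records.groupby(list(keys), sort=True, observed=True):
        stratum = stratum if isinstance(stratum, tuple) else (stratum,)
        days = sorted(sub["day"].unique())
        if ref_day not in days:
            continue
        ref = sub.loc[sub["day"] == ref_day, value]
        stratum_rows = []
        for day in days:
            if day <= ref_day:
                continue
            alt = sub.loc[sub["day"] == day, value]
            res = bootstrap_variance_increase_test(ref, alt, config, rng=rng)
            stratum_rows.append(
                dict(zip(keys, stratum))
                | {
                    "ref_day": ref_day,
                    "day": day,
                    "n_ref": res.n_ref,
                    "n_alt": res.n_alt,
                    "delta_variance": res.observed_delta,
                    "p_value": res.p_value,
                }
            )
        if stratum_rows:
            reject, p_adj = bh_adjust(
                [r["p_value"] for r in stratum_rows], q=config.q
            )
            for r, rej, pa in zip(stratum_rows, reject, p_adj):
                r["p_adjusted"] = float(pa)
                r["reject"] = bool(rej)
            rows.extend(stratum_rows)
    return pd.DataFrame(rows)
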