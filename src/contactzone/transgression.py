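"""Bootstrap test of transgressive segregation along shape axes.

Transgressive segregation is phenotypic novelty in hybrids: hybrid values
falling outside the pooled parental range along an axis.  The statistic is
the percentage range extension

    100 * [max(0, max(H) - max(P)) + max(0, min(P) - min(H))] / (max(P) - min(P))

i.e. novelty beyond the parental maximum and minimum, summed, relative to
the parental range.

The reported magnitude is the median extension over bootstrap resamples of
the hybrid group (with replacement, default 50 individuals, 500
replicates) against the fixed pooled parental sample; resampling to a
fixed size makes groups of unequal sample size comparable, since a raw
range grows with sample size.

Significance (default) comes from a group-label permutation test on the
same statistic: hybrid and parental labels are shuffled over the pooled
values, preserving group sizes, and the p-value is the add-one-smoothed
proportion of relabellings whose extension reaches the observed one.
``support`` is 1 - p, the proportion of replicates showing less
transgression than observed, so stars at support >= 0.95/0.99/0.999
correspond to p < 0.05/0.01/0.001.  A label permutation is the natural
null here because a resample of the parents alone can never extend the
parental range, so counting extending hybrid resamples directly (the
``significance="bootstrap_support"`` option) has no null reference and is
anticonservative; it is retained for comparison only.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STAR_LEVELS = ((0.999, "***"), (0.99, "**"), (0.95, "*"))


def significance_stars(support: float) -> str:
    """Star annotation at support >= 0.95 (*), 0.99 (**), 0.999 (***)."""
    for level, stars in STAR_LEVELS:
        if support >= level:
            return stars
    return ""


@dataclass
class TransgressionResult:
    """One cell of a transgression table: an (axis, hybrid group) pair."""

    axis: str
    hybrid_group: str
    median_pct: float
    support: float
    p_value: float
    n_boot: int
    n_resample: int
    seed: int

    @property
    def stars(self) -> str:
        return significance_stars(self.support)


def range_extension(hybrid_values: np.ndarray, parent_values: np.ndarray) -> float:
    """Percentage by which the hybrid range extends beyond the parental range.

    Zero when all hybrid values lie within the parental range; extensions
    beyond the parental maximum and below the parental minimum both count.
    """
    h = np.asarray(hybrid_values, dtype=float)
    p = np.asarray(parent_values, dtype=float)
    if h.size < 1:
        raise ValueError("at least one hybrid value required")
    if p.size < 2:
        raise ValueError("at least two parental values required")
    p_min, p_max = p.min(), p.max()
    span = p_max - p_min
    if span <= 0.0:
        raise ValueError("parental range is zero; extension undefined")
    upper = max(0.0, float(h.max()) - p_max)
    lower = max(0.0, p_min - float(h.min()))
    return 100.0 * (upper + lower) / span


def _bootstrap_extensions(
    values: np.ndarray, p_min: float, p_max: float, B: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    idx = rng.integers(0, values.size, size=(B, n))
    samples = values[idx]
    upper = np.maximum(0.0, samples.max(axis=1) - p_max)
    lower = np.maximum(0.0, p_min - samples.min(axis=1))
    return 100.0 * (upper + lower) / (p_max - p_min)


def _permutation_null(
    h: np.ndarray, p: np.ndarray, B: int, rng: np.random.Generator
) -> np.ndarray:
    """Extensions under random relabelling of the pooled values (sizes preserved)."""
    pooled = np.concatenate([p, h])
    m, n_p = pooled.size, p.size
    order = np.argsort(rng.random((B, m)), axis=1)
    perm = pooled[order]
    pseudo_p, pseudo_h = perm[:, :n_p], perm[:, n_p:]
    pmin = pseudo_p.min(axis=1)
    pmax = pseudo_p.max(axis=1)
    span = pmax - pmin
    upper = np.maximum(0.0, pseudo_h.max(axis=1) - pmax)
    lower = np.maximum(0.0, pmin - pseudo_h.min(axis=1))
    ext = np.full(B, np.inf)  # degenerate pseudo-parental range counts conservatively
    ok = span > 0.0
    ext[ok] = 100.0 * (upper[ok] + lower[ok]) / span[ok]
    return ext


def bootstrap_transgression(
    hybrid_values: np.ndarray,
    parent_values: np.ndarray,
    B: int = 500,
    n: int = 50,
    seed: int | np.random.SeedSequence = 0,
    axis: str = "",
    hybrid_group: str = "",
    resample: str = "hybrid",
    significance: str = "permutation",
) -> TransgressionResult:
    """Bootstrap range-extension test of one hybrid group against pooled parents.

    The magnitude is the median extension of ``B`` resamples of ``n`` hybrid
    values (with replacement) against the fixed pooled parental sample.
    Significance, by default, is a ``B``-replicate group-label permutation
    test on the full-sample extension (``p = (1 + #{null >= observed}) /
    (B + 1)``; ``support = 1 - p``).  ``significance="bootstrap_support"``
    instead takes support as the raw proportion of hybrid resamples showing
    any extension (anticonservative; comparison only).  ``resample="parent"``
    resamples the parental side for the magnitude (an alternative reading of
    the design; not the default).  Fully reproducible for a given seed.
    """
    if B < 1 or n < 1:
        raise ValueError("B and n must be positive")
    if resample not in ("hybrid", "parent"):
        raise ValueError(f"resample must be 'hybrid' or 'parent', got {resample!r}")
    if significance not in ("permutation", "bootstrap_support"):
        raise ValueError(f"unknown significance method {significance!r}")
    h = np.asarray(hybrid_values, dtype=float)
    p = np.asarray(parent_values, dtype=float)
    if h.size < 1:
        raise ValueError("hybrid group is empty")
    if p.size < 2 or np.ptp(p) <= 0.0:
        raise ValueError("parental sample must span a nonzero range")

    rng = np.random.default_rng(seed)
    p_min, p_max = float(p.min()), float(p.max())
    if resample == "hybrid":
        ext = _bootstrap_extensions(h, p_min, p_max, B, n, rng)
    else:
        # resample parents; extension of fixed hybrids over each parental replicate
        idx = rng.integers(0, p.size, size=(B, n))
        samples = p[idx]
        pmin_b = samples.min(axis=1)
        pmax_b = samples.max(axis=1)
        span = pmax_b - pmin_b
        span[span <= 0.0] = np.nan
        upper = np.maximum(0.0, h.max() - pmax_b)
        lower = np.maximum(0.0, pmin_b - h.min())
        ext = 100.0 * (upper + lower) / span
        ext = ext[np.isfinite(ext)]

    if significance == "permutation":
        e_obs = range_extension(h, p)
        null_ext = _permutation_null(h, p, B, rng)
        p_value = float((1 + (null_ext >= e_obs).sum()) / (B + 1))
        support = 1.0 - p_value
    else:
        support = float((ext > 0.0).mean())
        p_value = 1.0 - support

    seed_int = seed if isinstance(seed, (int, np.integer)) else -1
    return TransgressionResult(
        axis=axis,
        hybrid_group=hybrid_group,
        median_pct=float(np.median(ext)),
        support=support,
        p_value=p_value,
        n_boot=B,
        n_resample=n,
        seed=int(seed_int),
    )


def _cell_seed(seed: int, axis_index: int, group: str) -> np.random.SeedSequence:
    """Deterministic per-cell substream from (seed, axis, group)."""
    return np.random.SeedSequence([int(seed), int(axis_index), zlib.crc32(group.encode())])


def transgression_table(
    scores: np.ndarray | pd.DataFrame,
    groups: Sequence[str],
    hybrid_groups: Iterable[str],
    parent_groups: Iterable[str],
    axes: Sequence[str] | None = None,
    B: int = 500,
    n: int = 50,
    seed: int = 0,
    resample: str = "hybrid",
    significance: str = "permutation",
) -> list[TransgressionResult]:
    """Full transgression table: one result per (axis, hybrid group).

    ``scores`` is a specimens x axes matrix (size-corrected residuals in the
    standard workflow); parents are pooled across ``parent_groups``.  Each
    cell draws from its own deterministic substream of ``seed``, so the
    table is reproducible and independent of evaluation order.
    """
    if isinstance(scores, pd.DataFrame):
        axis_names = list(scores.columns)
        mat = scores.to_numpy(dtype=float)
    else:
        mat = np.asarray(scores, dtype=float)
        axis_names = [f"RW{i + 1}" for i in range(mat.shape[1])]
    if axes is None:
        axes = axis_names
    groups = np.asarray(list(groups))
    if groups.shape[0] != mat.shape[0]:
        raise ValueError("one group label required per specimen")
    hybrid_groups = list(hybrid_groups)
    parent_groups = list(parent_groups)

    present = set(groups)
    missing = [g for g in hybrid_groups + parent_groups if g not in present]
    if missing:
        raise ValueError(f"group labels absent from data: {missing}")
    bad_axes = [a for a in axes if a not in axis_names]
    if bad_axes:
        raise ValueError(f"axes absent from scores: {bad_axes}")

    parent_mask = np.isin(groups, parent_groups)
    results = []
    for a in axes:
        j = axis_names.index(a)
        parent_vals = mat[parent_mask, j]
        for g in hybrid_groups:
            hyb_vals = mat[groups == g, j]
            res = bootstrap_transgression(
                hyb_vals,
                parent_vals,
                B=B,
                n=n,
                seed=_cell_seed(seed, j, g),
                axis=a,
                hybrid_group=g,
                resample=resample,
                significance=significance,
            )
            res.seed = seed
            results.append(res)
    return results


def results_to_long(results: Iterable[TransgressionResult]) -> pd.DataFrame:
    """Machine-readable long-format table of transgression results."""
    rows = [
        {
            "axis": r.axis,
            "hybrid_group": r.hybrid_group,
            "median_pct": r.median_pct,
            "support": r.support,
            "p_value": r.p_value,
            "stars": r.stars,
            "n_boot": r.n_boot,
            "n_resample": r.n_resample,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def results_to_wide(results: Iterable[TransgressionResult]) -> pd.DataFrame:
    """Wide table (rows = axes, columns = hybrid crosses, cells = median % + stars)."""
    long = results_to_long(results)
    long["cell"] = long.apply(lambda r: f"{r.median_pct:.1f}{r.stars}", axis=1)
    wide = long.pivot(index="axis", columns="hybrid_group", values="cell")
    order = list(dict.fromkeys(long["axis"]))
    cols = list(dict.fromkeys(long["hybrid_group"]))
    return wide.loc[order, cols]
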