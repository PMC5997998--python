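"""Replicate-coherence and early-warning statistics.

Three complementary views of resilience loss in replicated cultures:
pairwise Spearman rank correlation of transcriptomes (after dropping
transcripts below 5 FPKM), Euclidean dispersion of replicate positions
in the physiological state space, and the coefficient of variation of
photosynthetic efficiency (Fv/Fm) across replicates over the growth
cycle.  Distribution shifts between stages are assessed with a
two-sided Mann-Whitney U test (dispersion) and a two-sided Wilcoxon
signed-rank test on time-paired CVs (Fv/Fm), exact p-values whenever
sample sizes permit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix, SampleMetadata


@dataclass
class SimilarityMatrix:
    """Pairwise Spearman rank correlations between samples."""

    frame: pd.DataFrame  # symmetric, unit diagonal
    n_genes_used: int

    def __post_init__(self) -> None:
        vals = self.frame.to_numpy()
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")


@dataclass(frozen=True)
class StatTestResult:
    test: str
    statistic: float
    pvalue: float
    n_a: int
    n_b: int
    method: str = "auto"

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "method": self.method,
        }


def pairwise_spearman(
    expr: ExpressionMatrix,
    min_fpkm: float = 5.0,
    filter_mode: str = "all",
) -> SimilarityMatrix:
    """Spearman correlation matrix over well-expressed transcripts.

    ``filter_mode="all"`` keeps genes with FPKM >= min_fpkm in *every*
    sample, so the same gene compendium enters each comparison;
    ``"pairwise"`` re-filters per sample pair (both samples must pass).
    Average ranks are used for ties.
    """
    frame = expr.frame
    if frame.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    if filter_mode == "all":
        keep = (frame >= min_fpkm).all(axis=1)
        filtered = frame.loc[keep]
        n_used = int(keep.sum())
        if n_used < 3:
            raise ValueError(
                f"only {n_used} genes pass the {min_fpkm}-FPKM filter; "
                "need >= 3"
            )
        rho = sps.spearmanr(filtered.to_numpy(), axis=0).statistic
        if np.ndim(rho) == 0:  # scipy collapses the 2-sample case to a scalar
            r = float(rho)
            rho = np.array([[1.0, r], [r, 1.0]])
    elif filter_mode == "pairwise":
        ids = expr.sample_ids
        n = len(ids)
        rho = np.eye(n)
        n_used = frame.shape[0]
        for i, j in combinations(range(n), 2):
            pair = frame.iloc[:, [i, j]]
            keep = (pair >= min_fpkm).all(axis=1)
            if int(keep.sum()) < 3:
                raise ValueError(
                    f"samples {ids[i]!r}/{ids[j]!r}: fewer than 3 genes "
                    f"pass the {min_fpkm}-FPKM filter"
                )
            n_used = min(n_used, int(keep.sum()))
            r = sps.spearmanr(pair.loc[keep].to_numpy(), axis=0).statistic
            rho[i, j] = rho[j, i] = r
    else:
        raise ValueError("filter_mode must be 'all' or 'pairwise'")
    out = pd.DataFrame(rho, index=expr.sample_ids, columns=expr.sample_ids)
    np.fill_diagonal(out.values, 1.0)
    return SimilarityMatrix(frame=out, n_genes_used=n_used)


def replicate_distance_per_timepoint(
    positions: pd.DataFrame,
    meta: Sequence[SampleMetadata],
) -> pd.DataFrame:
    """Pairwise Euclidean distances between replicate state positions.

    A "time-point" is one (condition, stage, diurnal_phase,
    growth_phase) sampling group; all unordered replicate pairs within
    it contribute one distance.  Samples without a mapped position are
    an error.
    """
    groups: dict[tuple, list[SampleMetadata]] = {}
    for r in meta:
        key = (r.condition, r.stage, r.diurnal_phase, r.growth_phase)
        groups.setdefault(key, []).append(r)
    missing = [
        r.sample_id
        for rs in groups.values()
        for r in rs
        if r.sample_id not in positions.index
    ]
    if missing:
        raise KeyError(f"samples without state positions: {missing[:10]}")
    rows = []
    for (condition, stage, diurnal, growth), rs in sorted(
        groups.items(), key=lambda kv: kv[0]
    ):
        if len(rs) < 2:
            raise ValueError(
                f"group {(condition, stage, diurnal, growth)}: need >= 2 "
                f"replicates, got {len(rs)}"
            )
        for ra, rb in combinations(sorted(rs, key=lambda r: r.replicate), 2):
            pa = positions.loc[ra.sample_id]
            pb = positions.loc[rb.sample_id]
            dist = float(np.hypot(pa["s_x"] - pb["s_x"], pa["s_y"] - pb["s_y"]))
            rows.append(
                {
                    "condition": condition,
                    "stage": stage,
                    "diurnal_phase": diurnal,
                    "growth_phase": growth,
                    "replicate_a": ra.replicate,
                    "replicate_b": rb.replicate,
                    "distance": dist,
                }
            )
    return pd.DataFrame(rows)


def test_distance_shift(group_a, group_b) -> StatTestResult:
    """Two-sided Mann-Whitney U comparing two distance distributions.

    Exact p-value for small samples without ties, normal approximation
    with tie correction otherwise (scipy's ``method="auto"``).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return StatTestResult(
        test="mann-whitney-u",
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_a=a.size,
        n_b=b.size,
    )


def cv_over_replicates(
    fvfm: pd.DataFrame,
    group_keys: Sequence[str] = ("stage", "time"),
) -> pd.DataFrame:
    """Coefficient of variation of replicate values per time-point.

    ``fvfm`` is a tidy frame with a ``value`` column and grouping
    columns (default stage and time).  CV = sample SD (n-1) / mean;
    a non-positive mean is an error, as the CV is then undefined.
    """
    if "value" not in fvfm.columns:
        raise ValueError("expected a 'value' column")
    rows = []
    for key, grp in fvfm.groupby(list(group_keys), sort=True):
        vals = grp["value"].to_numpy(float)
        if vals.size < 2:
            raise ValueError(
                f"group {key}: need >= 2 replicates, got {vals.size}"
            )
        mean = vals.mean()
        if mean <= 0:
            raise ValueError(f"group {key}: mean <= 0, CV undefined")
        row = dict(zip(group_keys, key if isinstance(key, tuple) else (key,)))
        row["cv"] = float(vals.std(ddof=1) / mean)
        row["n"] = int(vals.size)
        rows.append(row)
    return pd.DataFrame(rows)


def test_cv_shift(
    stage_a_cvs,
    stage_b_cvs,
    pairing: str = "by_time_index",
    fallback: str | None = None,
) -> StatTestResult:
    """Two-sided Wilcoxon signed-rank on time-paired CV series.

    Pairs are formed by within-stage time index, truncating to the
    shorter series; zero differences are dropped (standard practice).
    Exact p-values are used for n <= 25 without ties.  Fewer than 5
    usable pairs is an error unless ``fallback="mannwhitney"`` requests
    the unpaired comparison instead.
    """
    if pairing != "by_time_index":
        raise ValueError("only pairing='by_time_index' is supported")
    a = np.asarray(stage_a_cvs, float)
    b = np.asarray(stage_b_cvs, float)
    n = min(a.size, b.size)
    a, b = a[:n], b[:n]
    diffs = b - a
    nonzero = diffs[diffs != 0]
    if nonzero.size < 5:
        if fallback == "mannwhitney":
            res = test_distance_shift(a, b)
            return StatTestResult(
                test="mann-whitney-u-fallback",
                statistic=res.statistic,
                pvalue=res.pvalue,
                n_a=a.size,
                n_b=b.size,
            )
        raise ValueError(
            f"only {nonzero.size} non-zero paired differences (< 5); "
            "consider the Mann-Whitney fallback (fallback='mannwhitney')"
        )
    method = "exact" if (
        nonzero.size <= 25 and np.unique(np.abs(nonzero)).size == nonzero.size
    ) else "approx"
    res = sps.wilcoxon(nonzero, alternative="two-sided", method=method)
    ranks = sps.rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    return StatTestResult(
        test="wilcoxon-signed-rank",
        statistic=w_plus,
        pvalue=float(res.pvalue),
        n_a=n,
        n_b=int(nonzero.size),
        method=method,
    )
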