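"""State-descriptor selection and generic two-condition gene-set comparison.

A transcript qualifies as a state descriptor for an axis (diurnal:
light vs dark; growth_phase: early vs late) when, over the reference
samples (by default all stage-1 samples pooled across CO2 conditions),

1. a two-sided Mann-Whitney U test on log10(FPKM + pseudocount)
   rejects at ``alpha`` after the configured multiple-testing
   adjustment (Benjamini-Hochberg by default),
2. the absolute difference of the two per-state medians is at least
   log10(fold_change_min), and
3. that median separation is at least ``separation_sd_multiple`` times
   the mean of the two per-state sample standard deviations.

Genes meeting the criteria for both axes are assigned to the axis with
the larger separation/SD ratio so the two descriptor sets never
overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SampleMetadata
from .statespace import AXIS_STATES, DescriptorProfile, DescriptorSet


@dataclass(frozen=True)
class DescriptorCriteria:
    """Thresholds of the three selection criteria.

    fold_change_min is on the linear FPKM scale (2.0 = twofold);
    separation_sd_multiple scales the mean per-state SD in log10 space;
    pseudocount is added to FPKM before the log10 transform.
    """

    fold_change_min: float = 2.0
    separation_sd_multiple: float = 1.0
    alpha: float = 0.05
    multiple_testing: str = "bh"  # or "none"
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not self.fold_change_min > 1:
            raise ValueError("fold_change_min must exceed 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.multiple_testing not in ("bh", "none"):
            raise ValueError("multiple_testing must be 'bh' or 'none'")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


def log_transform(expr: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log10(FPKM + pseudocount).

    With pseudocount 0 every value must be strictly positive.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    values = expr.frame
    if pseudocount == 0 and (values.to_numpy() == 0).any():
        raise ValueError("zero FPKM with pseudocount 0: log10 undefined")
    return np.log10(values + pseudocount)


def _axis_groups(
    meta: Sequence[SampleMetadata],
    axis: str,
    reference_stage: int | None,
) -> tuple[list[str], list[str]]:
    """Sample ids of the alpha and beta states among reference samples."""
    if axis not in AXIS_STATES:
        raise ValueError(f"unknown axis {axis!r}; expected one of {list(AXIS_STATES)}")
    alpha_label, beta_label = AXIS_STATES[axis]
    attr = "diurnal_phase" if axis == "diurnal" else "growth_phase"
    alpha_ids, beta_ids = [], []
    for r in meta:
        if reference_stage is not None and r.stage != reference_stage:
            continue
        label = getattr(r, attr)
        (alpha_ids if label == alpha_label else beta_ids).append(r.sample_id)
    return alpha_ids, beta_ids


def selection_statistics(
    expr: ExpressionMatrix,
    meta: Sequence[SampleMetadata],
    axis: str,
    criteria: DescriptorCriteria = DescriptorCriteria(),
    reference_stage: int | None = 1,
) -> pd.DataFrame:
    """Per-gene selection statistics for one axis.

    Columns: q2_alpha, q2_beta, median_diff, sd_alpha, sd_beta,
    mean_sd, sep_ratio, pvalue, padj, selected.
    """
    alpha_ids, beta_ids = _axis_groups(meta, axis, reference_stage)
    if len(alpha_ids) < 2 or len(beta_ids) < 2:
        raise ValueError(
            f"axis {axis!r}: need >= 2 reference samples per state "
            f"(got {len(alpha_ids)} vs {len(beta_ids)})"
        )
    log = log_transform(expr, criteria.pseudocount)
    a = log[alpha_ids].to_numpy()
    b = log[beta_ids].to_numpy()
    res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
    pvalues = np.asarray(res.pvalue, float)
    if criteria.multiple_testing == "bh":
        padj = multipletests(pvalues, method="fdr_bh")[1]
    else:
        padj = pvalues
    q2a = np.median(a, axis=1)
    q2b = np.median(b, axis=1)
    sda = a.std(axis=1, ddof=1)
    sdb = b.std(axis=1, ddof=1)
    median_diff = q2a - q2b
    mean_sd = 0.5 * (sda + sdb)
    with np.errstate(divide="ignore", invalid="ignore"):
        sep_ratio = np.abs(median_diff) / mean_sd
    selected = (
        (padj < criteria.alpha)
        & (np.abs(median_diff) >= np.log10(criteria.fold_change_min))
        & (np.abs(median_diff) >= criteria.separation_sd_multiple * mean_sd)
        & (q2a != q2b)
    )
    return pd.DataFrame(
        {
            "q2_alpha": q2a,
            "q2_beta": q2b,
            "median_diff": median_diff,
            "sd_alpha": sda,
            "sd_beta": sdb,
            "mean_sd": mean_sd,
            "sep_ratio": sep_ratio,
            "pvalue": pvalues,
            "padj": padj,
            "selected": selected,
        },
        index=expr.gene_ids,
    )


def _build_set(
    expr: ExpressionMatrix,
    meta: Sequence[SampleMetadata],
    axis: str,
    criteria: DescriptorCriteria,
    reference_stage: int | None,
    gene_ids: Sequence[str],
) -> DescriptorSet:
    alpha_ids, beta_ids = _axis_groups(meta, axis, reference_stage)
    log = log_transform(expr, criteria.pseudocount)
    entries = [
        DescriptorProfile.from_samples(
            g, axis, log.loc[g, alpha_ids], log.loc[g, beta_ids]
        )
        for g in gene_ids
    ]
    return DescriptorSet(axis=axis, entries=entries, pseudocount=criteria.pseudocount)


def select_state_descriptors(
    expr: ExpressionMatrix,
    meta: Sequence[SampleMetadata],
    axis: str,
    criteria: DescriptorCriteria = DescriptorCriteria(),
    reference_stage: int | None = 1,
    exclude: Sequence[str] = (),
) -> DescriptorSet:
    """Select the descriptor set of one axis from the reference samples.

    ``exclude`` removes genes already claimed by the other axis.  An
    empty result is returned (with a warning) rather than raised, since
    downstream mapping is then simply impossible.
    """
    table = selection_statistics(expr, meta, axis, criteria, reference_stage)
    chosen = [g for g in table.index[table["selected"]] if g not in set(exclude)]
    if not chosen:
        import warnings

        warnings.warn(
            f"axis {axis!r}: no state descriptors met the criteria",
            stacklevel=2,
        )
    return _build_set(expr, meta, axis, criteria, reference_stage, chosen)


def select_descriptor_sets(
    expr: ExpressionMatrix,
    meta: Sequence[SampleMetadata],
    criteria: DescriptorCriteria = DescriptorCriteria(),
    reference_stage: int | None = 1,
) -> tuple[DescriptorSet, DescriptorSet]:
    """Select both axes and enforce non-overlapping descriptor sets.

    A gene passing the criteria for both axes is assigned to the axis
    where its separation/SD ratio is larger (ties go to the diurnal
    axis, checked first).
    """
    tables = {
        axis: selection_statistics(expr, meta, axis, criteria, reference_stage)
        for axis in AXIS_STATES
    }
    sel = {axis: set(t.index[t["selected"]]) for axis, t in tables.items()}
    overlap = sel["diurnal"] & sel["growth_phase"]
    for gene in overlap:
        rx = tables["diurnal"].loc[gene, "sep_ratio"]
        ry = tables["growth_phase"].loc[gene, "sep_ratio"]
        loser = "growth_phase" if rx >= ry else "diurnal"
        sel[loser].discard(gene)
    sets = []
    for axis, table in tables.items():
        chosen = [g for g in table.index if g in sel[axis]]
        sets.append(_build_set(expr, meta, axis, criteria, reference_stage, chosen))
    return sets[0], sets[1]


def summarize_descriptor_profiles(dset: DescriptorSet) -> pd.DataFrame:
    """One row per descriptor with its full reference geometry."""
    if not dset.entries:
        raise ValueError("cannot summarize an empty descriptor set")
    rows = []
    for entry, weight in zip(dset.entries, dset.weights):
        d = entry.to_dict()
        d["weight"] = float(weight)
        if d["theta"] <= 0:
            d["theta"] = np.nan
            d["theta_c"] = np.nan
        rows.append(d)
    cols = [
        "gene_id", "axis", "q2_alpha", "q2_beta", "min_alpha", "max_alpha",
        "min_beta", "max_beta", "epsilon", "theta", "theta_c", "weight",
    ]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class GeneSetComparison:
    """Result of a targeted two-condition comparison of a gene set."""

    table: pd.DataFrame
    counts: dict[str, int]


def compare_gene_set_between_conditions(
    expr: ExpressionMatrix,
    meta: Sequence[SampleMetadata],
    gene_ids: Sequence[str],
    condition_a: str,
    condition_b: str,
    alpha: float = 0.001,
    pseudocount: float = 1.0,
) -> GeneSetComparison:
    """Per-gene differential test of condition b vs condition a.

    Reports the log2 fold change of median FPKM (b over a, with
    pseudocount), a two-sided Mann-Whitney U p-value, its BH-adjusted
    value, and an up/down/ns call at ``alpha``.
    """
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ValueError("gene set is empty")
    unknown = [g for g in gene_ids if g not in expr.frame.index]
    if unknown:
        raise KeyError(f"gene ids not in expression matrix: {unknown}")
    ids_a = [r.sample_id for r in meta if r.condition == condition_a]
    ids_b = [r.sample_id for r in meta if r.condition == condition_b]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError(
            f"need >= 2 samples per condition "
            f"({condition_a!r}: {len(ids_a)}, {condition_b!r}: {len(ids_b)})"
        )
    sub = expr.frame.loc[gene_ids]
    a = sub[ids_a].to_numpy()
    b = sub[ids_b].to_numpy()
    res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
    pvalues = np.asarray(res.pvalue, float)
    padj = multipletests(pvalues, method="fdr_bh")[1]
    med_a = np.median(a, axis=1)
    med_b = np.median(b, axis=1)
    log2fc = np.log2((med_b + pseudocount) / (med_a + pseudocount))
    direction = np.where(
        (padj < alpha) & (log2fc > 0),
        "up",
        np.where((padj < alpha) & (log2fc < 0), "down", "ns"),
    )
    table = pd.DataFrame(
        {
            "median_a": med_a,
            "median_b": med_b,
            "log2_fold_change": log2fc,
            "pvalue": pvalues,
            "padj": padj,
            "direction": direction,
        },
        index=gene_ids,
    )
    counts = {
        key: int((direction == key).sum()) for key in ("up", "down", "ns")
    }
    return GeneSetComparison(table=table, counts=counts)
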