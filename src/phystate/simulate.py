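"""Synthetic studies with the statistical structure the analysis assumes.

The generator emulates the reference design of a serial-transfer batch
stress test: per stage, two CO2 conditions x two diurnal phases x two
growth phases x replicates (24 stage-1 transcriptomes at the defaults).
Planted descriptor transcripts carry a state-dependent shift of
``effect`` in log10-FPKM (direction fixed per gene); background genes
are state-independent with a long-tailed abundance distribution so the
5-FPKM similarity filter is exercised nontrivially.  Two independent
dysregulation knobs emulate pre-collapse behavior: ``mixing`` is the
per-(sample, descriptor) probability that the descriptor's state
assignment is scrambled, and ``position_jitter_scale`` multiplies the
within-state noise, inflating inter-replicate variability.

Expression noise is normal in log10 space (log-normal FPKM), matching
the log10 transform used by descriptor selection, and has two parts:
an independent per-(gene, sample) component (``within_state_sd``) and a
replicate-level "state depth" component (``replicate_depth_sd``) shared
by all descriptors of an axis within one sample.  Dysregulation is
likewise replicate-heterogeneous: a sample's effective scramble
probability is drawn around the stage's ``mixing`` level (Beta with
concentration ``MIXING_CONCENTRATION``), so replicate cultures lose
state coherence to different degrees and the dysregulated stage shows
both a drift toward the center of the state space and inflated
inter-replicate dispersion, the paired pre-collapse signatures.  The second part
emulates the fact that replicate cultures sampled at nominally the same
phase sit at slightly different points of the light/dark or early/late
transition, which shifts all of an axis's descriptors coherently —
the dominant source of replicate scatter in state-space position,
which purely independent gene noise (averaged over many descriptors)
cannot reproduce.  ``position_jitter_scale`` multiplies both
components.

Randomness: one ``numpy.random.default_rng(seed)`` per generator call,
with draws in a fixed documented order, so the same seed reproduces
identical values on any platform.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .growth import log_logistic_lag
from .io import (
    ExpressionMatrix,
    SampleMetadata,
    TimeSeriesTable,
    metadata_frame,
    write_table,
)

AXIS_X = "diurnal"
AXIS_Y = "growth_phase"

#: Beta concentration of the per-sample effective scramble probability;
#: higher values make replicates dysregulate more uniformly.
MIXING_CONCENTRATION = 16.0


def _per_stage(value, stages: int, name: str) -> tuple[float, ...]:
    if np.isscalar(value):
        return tuple(float(value) for _ in range(stages))
    out = tuple(float(v) for v in value)
    if not out:
        raise ValueError(f"{name} must not be empty")
    if len(out) > stages:  # truncate; extend by repeating the last entry
        out = out[:stages]
    elif len(out) < stages:
        out = out + (out[-1],) * (stages - len(out))
    return out


@dataclass
class SyntheticConfig:
    """Study conditions of the default synthetic stress test.

    Defaults mirror the reference design: 3000 genes of which 60 + 220
    are planted diurnal / growth-phase descriptors, a 0.6 log10-FPKM
    state separation against a 0.12 within-state SD, triplicate
    cultures in two CO2 conditions, and three stages with descriptor
    scrambling and doubled replicate jitter in the final (pre-collapse)
    stage.
    """

    n_genes: int = 3000
    n_x_descriptors: int = 60
    n_y_descriptors: int = 220
    effect: float = 0.6  # log10-FPKM separation of state medians
    within_state_sd: float = 0.12  # log10-FPKM, independent per gene
    replicate_depth_sd: float = 0.25  # fractional state-depth spread per sample
    descriptor_log10_mean: float = 1.5
    descriptor_log10_sd: float = 0.3
    baseline_log10_mean: float = 0.5
    baseline_log10_sd: float = 0.8
    conditions: tuple[str, ...] = ("lc", "hc")
    replicates: int = 3
    stages: int = 3
    mixing: tuple[float, ...] | float = (0.0, 0.0, 0.4)
    position_jitter_scale: tuple[float, ...] | float = (1.0, 1.0, 2.0)
    # growth-curve block
    growth_k: float = 2.0e6  # cells/mL
    growth_mu: float = 0.9  # day^-1
    growth_n0: float = 1.0e5  # cells/mL
    growth_lag_per_stage: tuple[float, ...] | float = (0.5, 1.5, 3.0)
    growth_days: float = 12.0
    growth_dt: float = 0.5
    growth_noise_cv: float = 0.05
    # photosynthetic-efficiency block
    fvfm_base: float = 0.65
    fvfm_cv_per_stage: tuple[float, ...] | float = (0.02, 0.02, 0.06)
    fvfm_timepoints_per_stage: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_x_descriptors + self.n_y_descriptors > self.n_genes:
            raise ValueError("descriptor counts exceed n_genes")
        if self.effect <= 0 or self.within_state_sd <= 0:
            raise ValueError("effect and within_state_sd must be > 0")
        if self.replicate_depth_sd < 0:
            raise ValueError("replicate_depth_sd must be >= 0")
        self.mixing = _per_stage(self.mixing, self.stages, "mixing")
        if any(not 0 <= m <= 0.5 for m in self.mixing):
            raise ValueError("mixing must lie in [0, 0.5] per stage")
        self.position_jitter_scale = _per_stage(
            self.position_jitter_scale, self.stages, "position_jitter_scale"
        )
        if any(j < 1 for j in self.position_jitter_scale):
            raise ValueError("position_jitter_scale must be >= 1 per stage")
        self.growth_lag_per_stage = _per_stage(
            self.growth_lag_per_stage, self.stages, "growth_lag_per_stage"
        )
        self.fvfm_cv_per_stage = _per_stage(
            self.fvfm_cv_per_stage, self.stages, "fvfm_cv_per_stage"
        )
        if not 0 < self.fvfm_base < 1:
            raise ValueError("fvfm_base must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticStudy:
    """Fully labeled synthetic study with ground truth."""

    expr: ExpressionMatrix
    meta: list[SampleMetadata]
    truth: pd.DataFrame  # gene_id, axis, direction (+1 = higher in light/early)
    growth: TimeSeriesTable
    fm: TimeSeriesTable
    fo: TimeSeriesTable
    config: SyntheticConfig


def _sample_plan(cfg: SyntheticConfig) -> list[SampleMetadata]:
    records = []
    for stage in range(1, cfg.stages + 1):
        for condition in cfg.conditions:
            for diurnal in ("light", "dark"):
                for growth in ("early", "late"):
                    for rep in range(1, cfg.replicates + 1):
                        sid = f"st{stage}_{condition}_{diurnal}_{growth}_r{rep}"
                        records.append(
                            SampleMetadata(
                                sample_id=sid,
                                condition=condition,
                                stage=stage,
                                diurnal_phase=diurnal,
                                growth_phase=growth,
                                replicate=f"r{rep}",
                            )
                        )
    return records


def generate_expression_dataset(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, list[SampleMetadata], pd.DataFrame]:
    """Expression matrix, metadata and planted-descriptor truth table.

    Draw order (one rng): descriptor directions, descriptor base
    means, background base means, then per sample (plan order) the two
    per-axis state depths, the sample's effective scramble probability,
    the mixing flips, and the noise vector.
    """
    rng = np.random.default_rng(cfg.seed)
    n_desc = cfg.n_x_descriptors + cfg.n_y_descriptors
    width = len(str(cfg.n_genes))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]
    axes = [AXIS_X] * cfg.n_x_descriptors + [AXIS_Y] * cfg.n_y_descriptors

    directions = rng.choice([-1, 1], size=n_desc)
    desc_base = rng.normal(
        cfg.descriptor_log10_mean, cfg.descriptor_log10_sd, size=n_desc
    )
    bg_base = rng.normal(
        cfg.baseline_log10_mean, cfg.baseline_log10_sd, size=cfg.n_genes - n_desc
    )

    meta = _sample_plan(cfg)
    axis_is_x = np.array([axis == AXIS_X for axis in axes])
    log_values = np.empty((cfg.n_genes, len(meta)))
    for col, record in enumerate(meta):
        stage_ix = record.stage - 1
        scale = cfg.position_jitter_scale[stage_ix]
        sd = cfg.within_state_sd * scale
        is_alpha = np.where(
            axis_is_x,
            record.diurnal_phase == "light",
            record.growth_phase == "early",
        )
        # replicate-level state depth, one value per axis per sample,
        # coherently deepening or flattening that axis's signature
        depth = rng.normal(0.0, cfg.replicate_depth_sd * scale, size=2)
        depth_per_gene = np.where(axis_is_x, depth[0], depth[1])
        mixing = cfg.mixing[stage_ix]
        if mixing > 0:
            # replicate-heterogeneous dysregulation: this sample's own
            # scramble probability, centered on the stage's level
            mixing = rng.beta(
                MIXING_CONCENTRATION * mixing,
                MIXING_CONCENTRATION * (1.0 - mixing),
            )
        flips = rng.random(n_desc) < mixing
        effective_alpha = is_alpha ^ flips
        shift = (
            np.where(effective_alpha, 1.0, -1.0)
            * directions
            * (cfg.effect / 2)
            * (1.0 + depth_per_gene)
        )
        means = np.concatenate([desc_base + shift, bg_base])
        log_values[:, col] = means + rng.normal(0.0, sd, size=cfg.n_genes)

    frame = pd.DataFrame(
        np.power(10.0, log_values),
        index=gene_ids,
        columns=[r.sample_id for r in meta],
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids[:n_desc],
            "axis": axes,
            "direction": directions,
        }
    )
    return ExpressionMatrix(frame), meta, truth


def generate_growth_series(
    k: float,
    mu: float,
    lag: float,
    n0: float,
    times: Sequence[float],
    noise_cv: float = 0.0,
    seed: int | None = None,
    series_id: str = "series",
) -> TimeSeriesTable:
    """Lag-logistic cell-count series with multiplicative log-normal noise.

    The curve is the inverse of the growth fit's model (ln N(t) =
    ln n0 + A/(1 + exp(4 mu (lag - t)/A + 2)), A = ln(K/n0)); noise_cv
    is the coefficient of variation of the multiplicative noise.
    """
    if not (k > n0 > 0):
        raise ValueError("need K > n0 > 0")
    if mu <= 0 or lag < 0:
        raise ValueError("need mu > 0 and lag >= 0")
    t = np.asarray(times, float)
    if t.size and not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    ln_n = log_logistic_lag(t, np.log(n0), np.log(k / n0), mu, lag)
    counts = np.exp(ln_n)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        counts = counts * np.exp(rng.normal(0.0, sigma, size=t.size))
    frame = pd.DataFrame({"series_id": series_id, "time": t, "value": counts})
    return TimeSeriesTable(frame, kind="counts")


def generate_fvfm_series(
    base: float,
    cv_per_stage: Sequence[float],
    timepoints_per_stage: int = 12,
    replicates: int = 3,
    seed: int | None = None,
    condition: str | None = None,
) -> tuple[TimeSeriesTable, TimeSeriesTable]:
    """(Fm, Fo) fluorescence series with stage-dependent replicate CV.

    Per time-point the replicate Fv/Fm values are drawn normal around
    ``base`` with SD base*cv; values are clipped into (0, 1) with a
    warning if the requested CV pushes them out.  Fm varies log-normally
    around 1 and Fo = Fm*(1 - Fv/Fm), so downstream Fv/Fm recovery is
    exact.
    """
    if not 0 < base < 1:
        raise ValueError("base Fv/Fm must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    prefix = f"{condition}_" if condition else ""
    rows_fm, rows_fo = [], []
    clipped = False
    for stage_ix, cv in enumerate(cv_per_stage):
        stage = stage_ix + 1
        for j in range(timepoints_per_stage):
            t = stage_ix * timepoints_per_stage + j
            fvfm = rng.normal(base, base * cv, size=replicates)
            if (fvfm <= 0).any() or (fvfm >= 1).any():
                clipped = True
                fvfm = np.clip(fvfm, 1e-6, 1.0 - 1e-6)
            fm = np.exp(rng.normal(0.0, 0.1, size=replicates))
            fo = fm * (1.0 - fvfm)
            for rep in range(replicates):
                common = {
                    "series_id": f"{prefix}r{rep + 1}",
                    "time": float(t),
                    "stage": stage,
                    "replicate": f"r{rep + 1}",
                }
                if condition:
                    common["condition"] = condition
                rows_fm.append({**common, "value": fm[rep]})
                rows_fo.append({**common, "value": fo[rep]})
    if clipped:
        warnings.warn(
            "requested Fv/Fm CV pushed values outside (0, 1); clipped",
            stacklevel=2,
        )
    cols = ["series_id", "time", "value", "stage", "replicate"] + (
        ["condition"] if condition else []
    )
    fm_frame = pd.DataFrame(rows_fm)[cols]
    fo_frame = pd.DataFrame(rows_fo)[cols]
    return (
        TimeSeriesTable(fm_frame, kind="fluorescence"),
        TimeSeriesTable(fo_frame, kind="fluorescence"),
    )


def generate_full_study(cfg: SyntheticConfig) -> SyntheticStudy:
    """Expression, growth and fluorescence generators with consistent labels."""
    expr, meta, truth = generate_expression_dataset(cfg)
    seed_rng = np.random.default_rng(cfg.seed + 1)

    growth_frames = []
    times = np.arange(0.0, cfg.growth_days + 1e-9, cfg.growth_dt)
    for condition in cfg.conditions:
        for stage in range(1, cfg.stages + 1):
            for rep in range(1, cfg.replicates + 1):
                child_seed = int(seed_rng.integers(0, 2**31 - 1))
                ts = generate_growth_series(
                    cfg.growth_k,
                    cfg.growth_mu,
                    cfg.growth_lag_per_stage[stage - 1],
                    cfg.growth_n0,
                    times,
                    noise_cv=cfg.growth_noise_cv,
                    seed=child_seed,
                    series_id=f"{condition}_st{stage}_r{rep}",
                )
                frame = ts.frame.assign(
                    condition=condition, stage=stage, replicate=f"r{rep}"
                )
                growth_frames.append(frame)
    growth = TimeSeriesTable(pd.concat(growth_frames, ignore_index=True),
                             kind="counts")

    fm_frames, fo_frames = [], []
    for condition in cfg.conditions:
        child_seed = int(seed_rng.integers(0, 2**31 - 1))
        fm, fo = generate_fvfm_series(
            cfg.fvfm_base,
            cfg.fvfm_cv_per_stage,
            timepoints_per_stage=cfg.fvfm_timepoints_per_stage,
            replicates=cfg.replicates,
            seed=child_seed,
            condition=condition,
        )
        fm_frames.append(fm.frame)
        fo_frames.append(fo.frame)
    fm = TimeSeriesTable(pd.concat(fm_frames, ignore_index=True),
                         kind="fluorescence")
    fo = TimeSeriesTable(pd.concat(fo_frames, ignore_index=True),
                         kind="fluorescence")
    return SyntheticStudy(expr, meta, truth, growth, fm, fo, cfg)


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write every study table in the pipeline's external formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth_descriptors.tsv",
        "growth": out / "growth_counts.tsv",
        "fm": out / "fluorescence_fm.tsv",
        "fo": out / "fluorescence_fo.tsv",
        "config": out / "config.json",
    }
    write_table(study.expr, paths["expression"])
    write_table(metadata_frame(study.meta), paths["metadata"])
    write_table(study.truth, paths["truth"])
    write_table(study.growth, paths["growth"])
    write_table(study.fm, paths["fm"])
    write_table(study.fo, paths["fo"])
    write_table(study.config.to_dict(), paths["config"])
    return paths
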