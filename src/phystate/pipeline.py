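"""End-to-end orchestration of the resilience analysis.

Stage order: validate -> (simulate) -> select descriptors on the
reference stage -> map all samples -> reference regions +
classification -> Spearman similarity matrix -> replicate dispersion +
Mann-Whitney -> Fv/Fm CV + Wilcoxon -> growth fits.  Every output is
written under the configured output directory and listed, with a
sha256 checksum and the full configuration echo, in ``manifest.json``;
rerunning with the same seed reproduces the manifest byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import descriptors as desc
from . import io as pio
from . import simulate as sim
from . import statespace as ss
from . import stats as rs
from .growth import compute_fvfm, fit_logistic_with_lag


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``inputs`` (paths to expression/metadata/counts/
    fluorescence tables) or ``simulate`` (a synthetic-study block) must
    be present.
    """

    out_dir: str | Path = "phystate_out"
    seed: int = 0
    simulate: sim.SyntheticConfig | None = None
    inputs: dict[str, str] | None = None
    criteria: desc.DescriptorCriteria = field(
        default_factory=desc.DescriptorCriteria
    )
    reference_stage: int = 1
    min_fpkm: float = 5.0
    distance_stage_pair: tuple[int, int] | None = None
    cv_stage_pair: tuple[int, int] | None = None
    strict: bool = False

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of 'simulate' or 'inputs' must be configured"
            )

    @classmethod
    def from_file(
        cls,
        path: str | Path,
        out_dir: str | Path | None = None,
        seed: int | None = None,
        strict: bool | None = None,
    ) -> "PipelineConfig":
        """Load a YAML (or JSON) configuration file."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if out_dir is not None:
            raw["out_dir"] = str(out_dir)
        if seed is not None:
            raw["seed"] = seed
        if strict is not None:
            raw["strict"] = strict
        if "simulate" in raw and raw["simulate"] is not None:
            block = dict(raw["simulate"])
            block.setdefault("seed", raw.get("seed", 0))
            for key in ("conditions",):
                if key in block:
                    block[key] = tuple(block[key])
            raw["simulate"] = sim.SyntheticConfig(**block)
        if "criteria" in raw and raw["criteria"] is not None:
            raw["criteria"] = desc.DescriptorCriteria(**raw["criteria"])
        for key in ("distance_stage_pair", "cv_stage_pair"):
            if raw.get(key) is not None:
                raw[key] = tuple(int(v) for v in raw[key])
        return cls(**raw)

    def echo(self) -> dict:
        # out_dir is deliberately not echoed: the manifest must be
        # byte-identical across reruns regardless of where they land
        d: dict = {
            "seed": self.seed,
            "reference_stage": self.reference_stage,
            "min_fpkm": self.min_fpkm,
            "distance_stage_pair": list(self.distance_stage_pair)
            if self.distance_stage_pair
            else None,
            "cv_stage_pair": list(self.cv_stage_pair) if self.cv_stage_pair else None,
            "strict": self.strict,
            "criteria": dataclasses.asdict(self.criteria),
            "inputs": self.inputs,
            "simulate": self.simulate.to_dict() if self.simulate else None,
        }
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Any stage error aborts with a stage-named message; outputs written
    so far are retained next to a ``FAILED`` marker file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    current_stage = "setup"

    def stage(name: str):
        nonlocal current_stage
        current_stage = name
        return name

    try:
        # -- data acquisition -------------------------------------------------
        if config.simulate is not None:
            stage("simulate")
            cfg = dataclasses.replace(config.simulate, seed=config.seed)
            study = sim.generate_full_study(cfg)
            data_paths = sim.write_study(study, out / "data")
            outputs.update({f"data_{k}": p for k, p in data_paths.items()})
            expr, meta = study.expr, study.meta
            growth_ts, fm_ts, fo_ts = study.growth, study.fm, study.fo
        else:
            stage("load")
            paths = config.inputs or {}
            expr = pio.read_expression_matrix(paths["expression"])
            meta = pio.read_sample_metadata(paths["metadata"])
            growth_ts = (
                pio.read_time_series(paths["counts"], kind="counts")
                if "counts" in paths
                else None
            )
            fm_ts = (
                pio.read_time_series(paths["fm"], kind="fluorescence")
                if "fm" in paths
                else None
            )
            fo_ts = (
                pio.read_time_series(paths["fo"], kind="fluorescence")
                if "fo" in paths
                else None
            )

        stage("validate")
        report = pio.validate_dataset(expr, meta, strict=config.strict)
        outputs["validation"] = out / "validation.json"
        pio.write_table({"findings": report.findings}, outputs["validation"])

        stage("select_descriptors")
        x_set, y_set = desc.select_descriptor_sets(
            expr, meta, config.criteria, config.reference_stage
        )
        outputs["descriptors"] = out / "descriptors.json"
        outputs["descriptors"].write_text(
            json.dumps(
                {"diurnal": x_set.to_dict(), "growth_phase": y_set.to_dict()},
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        summary = pd.concat(
            [
                desc.summarize_descriptor_profiles(s)
                for s in (x_set, y_set)
                if len(s)
            ],
            ignore_index=True,
        )
        outputs["descriptor_summary"] = out / "descriptor_summary.tsv"
        pio.write_table(summary, outputs["descriptor_summary"])

        stage("map_states")
        positions = ss.map_samples(expr, x_set, y_set)
        regions = ss.build_reference_regions(
            positions, meta, config.reference_stage
        )
        labels = [
            ss.classify_position(
                (row["s_x"], row["s_y"]), regions
            )
            for _, row in positions.iterrows()
        ]
        positions_out = positions.assign(classified_state=labels).reset_index()
        outputs["positions"] = out / "positions.tsv"
        pio.write_table(positions_out, outputs["positions"])
        outputs["regions"] = out / "regions.json"
        ss.regions_to_json(regions, outputs["regions"])

        stage("similarity")
        scc = rs.pairwise_spearman(expr, min_fpkm=config.min_fpkm)
        outputs["scc"] = out / "scc.tsv"
        pio.write_table(
            scc.frame.reset_index().rename(columns={"index": "sample_id"}),
            outputs["scc"],
        )

        stage("dispersion")
        distances = rs.replicate_distance_per_timepoint(positions, meta)
        outputs["distances"] = out / "distances.tsv"
        pio.write_table(distances, outputs["distances"])
        stages_present = [int(s) for s in sorted(distances["stage"].unique())]
        pair = config.distance_stage_pair or (
            stages_present[0],
            stages_present[-1],
        )
        if pair[0] != pair[1] and all(p in stages_present for p in pair):
            res = rs.test_distance_shift(
                distances.loc[distances["stage"] == pair[0], "distance"],
                distances.loc[distances["stage"] == pair[1], "distance"],
            )
            payload = {"stage_pair": list(pair), **res.to_dict()}
        else:
            payload = {"stage_pair": list(pair), "note": "single stage; no test"}
        outputs["distance_test"] = out / "distance_test.json"
        pio.write_table(payload, outputs["distance_test"])

        if fm_ts is not None and fo_ts is not None:
            stage("cv_fvfm")
            merged = fm_ts.frame.rename(columns={"value": "fm"}).copy()
            merged["fo"] = fo_ts.frame["value"].to_numpy()
            merged["value"] = compute_fvfm(
                merged["fm"].to_numpy(), merged["fo"].to_numpy()
            )
            keys = [
                c for c in ("condition", "stage", "time") if c in merged.columns
            ]
            cv_table = rs.cv_over_replicates(merged, group_keys=keys)
            outputs["cv"] = out / "cv_fvfm.tsv"
            pio.write_table(cv_table, outputs["cv"])
            stages_present = [int(s) for s in sorted(cv_table["stage"].unique())]
            pair = config.cv_stage_pair or (
                stages_present[0],
                stages_present[-1],
            )
            if pair[0] != pair[1]:
                a, b = [], []
                conds = (
                    sorted(cv_table["condition"].unique())
                    if "condition" in cv_table.columns
                    else [None]
                )
                for cond in conds:
                    sub = (
                        cv_table
                        if cond is None
                        else cv_table[cv_table["condition"] == cond]
                    )
                    ca = sub[sub["stage"] == pair[0]].sort_values("time")["cv"]
                    cb = sub[sub["stage"] == pair[1]].sort_values("time")["cv"]
                    n = min(len(ca), len(cb))
                    a.extend(ca.iloc[:n])
                    b.extend(cb.iloc[:n])
                res = rs.test_cv_shift(a, b, fallback="mannwhitney")
                payload = {"stage_pair": list(pair), **res.to_dict()}
            else:
                payload = {"stage_pair": list(pair), "note": "single stage"}
            outputs["cv_test"] = out / "cv_test.json"
            pio.write_table(payload, outputs["cv_test"])

        if growth_ts is not None:
            stage("growth_fits")
            fits = {}
            for sid in growth_ts.series_ids():
                series = growth_ts.get_series(sid)
                single = pio.TimeSeriesTable(
                    series[["series_id", "time", "value"]], kind="counts"
                )
                fits[sid] = fit_logistic_with_lag(single).to_dict()
            outputs["growth_fits"] = out / "growth_fits.json"
            pio.write_table(fits, outputs["growth_fits"])

        stage("manifest")
        manifest = {
            "config": config.echo(),
            "seed": config.seed,
            "outputs": {
                name: {
                    "path": str(path.relative_to(out)),
                    "sha256": _sha256(path),
                }
                for name, path in sorted(outputs.items())
            },
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        return manifest
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {current_stage!r}: {exc}\n")
        raise PipelineStageError(f"stage {current_stage!r} failed: {exc}") from exc
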