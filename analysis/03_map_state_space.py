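#!/usr/bin/env python
"""Map every transcriptome into the 2D physiological state space.

Builds the four stage-1 reference regions (centroid + 1.96-SD circle),
classifies all samples, and tabulates how classification degrades by
stage: stage 1 maps to the four corners, the dysregulated final stage
drifts into the non-distinctive area.
"""

import json
from pathlib import Path

import pandas as pd

from phystate.io import read_expression_matrix, read_sample_metadata, write_table
from phystate.statespace import (
    DescriptorSet,
    build_reference_regions,
    classify_position,
    map_samples,
    regions_to_json,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    expr = read_expression_matrix(ROOT / "data" / "expression.tsv")
    meta = read_sample_metadata(ROOT / "data" / "metadata.tsv")
    payload = json.loads((ROOT / "descriptors.json").read_text())
    x_set = DescriptorSet.from_dict(payload["diurnal"])
    y_set = DescriptorSet.from_dict(payload["growth_phase"])

    positions = map_samples(expr, x_set, y_set)
    regions = build_reference_regions(positions, meta, reference_stage=1)
    by_id = {r.sample_id: r for r in meta}
    labels = {
        sid: classify_position((row["s_x"], row["s_y"]), regions)
        for sid, row in positions.iterrows()
    }

    out = positions.assign(
        stage=[by_id[s].stage for s in positions.index],
        true_state=[by_id[s].state for s in positions.index],
        classified_state=[labels[s] for s in positions.index],
    ).reset_index()
    write_table(out, ROOT / "positions.tsv")
    regions_to_json(regions, ROOT / "regions.json")

    print("classification by stage (fraction of samples):")
    table = (
        out.assign(correct=out["true_state"] == out["classified_state"],
                   nondistinctive=out["classified_state"] == "non-distinctive")
        .groupby("stage")[["correct", "nondistinctive"]]
        .mean()
    )
    print(table.to_string(float_format=lambda v: f"{v:.2f}"))
    print("reference region radii:",
          {s: round(r.radius, 3) for s, r in regions.items()})
    print(f"wrote {ROOT / 'positions.tsv'} and regions.json")


if __name__ == "__main__":
    main()
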