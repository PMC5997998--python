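#!/usr/bin/env python
"""Replicate-coherence and early-warning statistics of the stress test.

Computes the Spearman similarity matrix over well-expressed transcripts
(>= 5 FPKM in every sample), the replicate dispersion in state space
with a Mann-Whitney U test between the first and final stages, and the
across-replicate CV of Fv/Fm with a paired Wilcoxon signed-rank test —
the two early-warning signals of the pre-collapse stage.
"""

import json
from pathlib import Path

import pandas as pd

from phystate import stats as rs
from phystate.growth import compute_fvfm
from phystate.io import (
    read_expression_matrix,
    read_sample_metadata,
    read_time_series,
    write_table,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    expr = read_expression_matrix(ROOT / "data" / "expression.tsv")
    meta = read_sample_metadata(ROOT / "data" / "metadata.tsv")
    positions = pd.read_csv(ROOT / "positions.tsv", sep="\t").set_index("sample_id")

    scc = rs.pairwise_spearman(expr, min_fpkm=5.0)
    write_table(scc.frame.reset_index().rename(columns={"index": "sample_id"}),
                ROOT / "scc.tsv")
    print(f"Spearman similarity over {scc.n_genes_used} genes passing the "
          "5-FPKM filter in every sample")

    distances = rs.replicate_distance_per_timepoint(positions, meta)
    write_table(distances, ROOT / "distances.tsv")
    first, last = int(distances["stage"].min()), int(distances["stage"].max())
    res = rs.test_distance_shift(
        distances.loc[distances["stage"] == first, "distance"],
        distances.loc[distances["stage"] == last, "distance"],
    )
    print(f"replicate dispersion, stage {last} vs stage {first}: "
          f"median {distances.loc[distances['stage'] == last, 'distance'].median():.3f} "
          f"vs {distances.loc[distances['stage'] == first, 'distance'].median():.3f}; "
          f"Mann-Whitney U = {res.statistic:.0f}, p = {res.pvalue:.2e}")

    fm = read_time_series(ROOT / "data" / "fluorescence_fm.tsv", "fluorescence")
    fo = read_time_series(ROOT / "data" / "fluorescence_fo.tsv", "fluorescence")
    tidy = fm.frame.copy()
    tidy["value"] = compute_fvfm(fm.frame["value"].to_numpy(),
                                 fo.frame["value"].to_numpy())
    cv = rs.cv_over_replicates(tidy, group_keys=("condition", "stage", "time"))
    write_table(cv, ROOT / "cv_fvfm.tsv")
    a, b = [], []
    for cond in sorted(cv["condition"].unique()):
        sub = cv[cv["condition"] == cond]
        ca = sub[sub["stage"] == first].sort_values("time")["cv"]
        cb = sub[sub["stage"] == last].sort_values("time")["cv"]
        n = min(len(ca), len(cb))
        a.extend(ca.iloc[:n])
        b.extend(cb.iloc[:n])
    wil = rs.test_cv_shift(a, b)
    print(f"Fv/Fm CV, stage {last} vs stage {first} "
          f"(paired by time, both conditions): W+ = {wil.statistic:.0f}, "
          f"p = {wil.pvalue:.2e} ({wil.method})")

    (ROOT / "shift_tests.json").write_text(json.dumps(
        {"distance_shift": res.to_dict(), "cv_shift": wil.to_dict()},
        indent=2, sort_keys=True) + "\n")
    print(f"wrote scc.tsv, distances.tsv, cv_fvfm.tsv, shift_tests.json")


if __name__ == "__main__":
    main()
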