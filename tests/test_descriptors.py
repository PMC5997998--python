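import numpy as np
import pandas as pd
import pytest

from phystate.descriptors import (
    DescriptorCriteria,
    compare_gene_set_between_conditions,
    log_transform,
    select_descriptor_sets,
    select_state_descriptors,
    selection_statistics,
    summarize_descriptor_profiles,
)
from phystate.io import ExpressionMatrix, SampleMetadata


def _make_meta(n_per_state=12, stage=1):
    meta = []
    i = 0
    for cond in ("lc", "hc"):
        for d in ("light", "dark"):
            for g in ("early", "late"):
                for r in range(n_per_state // 4):
                    meta.append(
                        SampleMetadata(f"s{i}", cond, stage, d, g, f"r{r}")
                    )
                    i += 1
    return meta


class TestLogTransform:
    def test_worked_values(self, rng):
        frame = pd.DataFrame({"s1": [99.0, 0.0]}, index=["g1", "g2"])
        out = log_transform(ExpressionMatrix(frame), pseudocount=1.0)
        assert out.loc["g1", "s1"] == pytest.approx(2.0)
        assert out.loc["g2", "s1"] == 0.0

    def test_zero_with_zero_pseudocount_is_error(self):
        frame = pd.DataFrame({"s1": [1.0, 0.0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="pseudocount 0"):
            log_transform(ExpressionMatrix(frame), pseudocount=0.0)


class TestSelection:
    def test_uninformative_gene_not_selected(self, rng):
        # identical per-state distributions carry no state signal
        meta = _make_meta(12)
        values = rng.lognormal(2, 0.5, size=(10, len(meta)))
        expr = ExpressionMatrix(
            pd.DataFrame(values, index=[f"g{i}" for i in range(10)],
                         columns=[m.sample_id for m in meta])
        )
        with pytest.warns(UserWarning, match="no state descriptors"):
            dset = select_state_descriptors(expr, meta, "diurnal")
        assert len(dset) == 0

    def test_large_shift_with_larger_spread_fails_separation_criterion(self):
        # 2.5-fold median shift but per-state SDs of 1.0 in log10 space:
        # criteria (1)-(2) can pass, criterion (3) must reject
        meta = _make_meta(12)
        light = [m for m in meta if m.diurnal_phase == "light"]
        dark = [m for m in meta if m.diurnal_phase == "dark"]
        # deterministic symmetric pattern with sample SD 1.0, median 0
        base = np.array([-1.5, -1.0, -0.5, -0.25, -0.1, 0.0,
                         0.0, 0.1, 0.25, 0.5, 1.0, 1.5])
        pattern = base / base.std(ddof=1)
        log_vals = {}
        for i, m in enumerate(light):
            log_vals[m.sample_id] = 2.0 + pattern[i]
        for i, m in enumerate(dark):
            log_vals[m.sample_id] = 2.0 + np.log10(2.5) + pattern[i]
        frame = pd.DataFrame(
            {sid: [10 ** v] for sid, v in log_vals.items()}, index=["g1"]
        )
        # selection works on log10(FPKM + 1); with values near 100 the
        # pseudocount barely perturbs the constructed geometry
        stats = selection_statistics(
            ExpressionMatrix(frame), meta, "diurnal",
            DescriptorCriteria(alpha=0.999, multiple_testing="none"),
        )
        assert abs(stats.loc["g1", "median_diff"]) >= np.log10(2.3)
        assert not stats.loc["g1", "selected"]
        assert abs(stats.loc["g1", "median_diff"]) < stats.loc["g1", "mean_sd"]

    def test_selection_is_symmetric_under_label_swap(self, default_study):
        expr, meta = default_study.expr, default_study.meta
        swapped_meta = [
            SampleMetadata(
                m.sample_id,
                m.condition,
                m.stage,
                {"light": "dark", "dark": "light"}[m.diurnal_phase],
                m.growth_phase,
                m.replicate,
            )
            for m in meta
        ]
        a = select_state_descriptors(expr, meta, "diurnal")
        b = select_state_descriptors(expr, swapped_meta, "diurnal")
        assert a.gene_ids == b.gene_ids
        for ea, eb in zip(a.entries, b.entries):
            assert ea.epsilon == -eb.epsilon

    def test_stricter_criteria_never_add_descriptors(self, default_study):
        expr, meta = default_study.expr, default_study.meta
        base = set(
            select_state_descriptors(expr, meta, "diurnal").gene_ids
        )
        for stricter in (
            DescriptorCriteria(fold_change_min=4.0),
            DescriptorCriteria(separation_sd_multiple=2.0),
            DescriptorCriteria(alpha=0.001),
        ):
            subset = set(
                select_state_descriptors(expr, meta, "diurnal", stricter).gene_ids
            )
            assert subset <= base

    def test_too_few_reference_samples_is_an_error(self, rng):
        meta = _make_meta(12)[:3]
        frame = pd.DataFrame(
            rng.lognormal(2, 0.5, (5, 3)),
            index=[f"g{i}" for i in range(5)],
            columns=[m.sample_id for m in meta],
        )
        with pytest.raises(ValueError, match=">= 2"):
            select_state_descriptors(ExpressionMatrix(frame), meta, "diurnal")

    def test_sets_are_disjoint_across_axes(self, default_sets):
        x_set, y_set = default_sets
        assert not set(x_set.gene_ids) & set(y_set.gene_ids)
        assert np.isclose(x_set.weights.sum(), 1.0)
        assert np.isclose(y_set.weights.sum(), 1.0)


class TestSummary:
    def test_one_row_per_descriptor_with_geometry(self, default_sets):
        x_set, _ = default_sets
        table = summarize_descriptor_profiles(x_set)
        assert len(table) == len(x_set)
        assert set(table["axis"]) == {"diurnal"}
        gapped = table["theta"].notna()
        assert (table.loc[gapped, "theta"] > 0).all()
        assert table.loc[~gapped, "theta_c"].isna().all()


class TestGeneSetComparison:
    def _paired_matrix(self, rng, n_genes=10, shift_genes=5, shift=np.log10(4)):
        meta = []
        ids_a, ids_b = [], []
        for cond, ids in (("lc", ids_a), ("hc", ids_b)):
            for i in range(12):
                sid = f"{cond}{i}"
                ids.append(sid)
                meta.append(SampleMetadata(sid, cond, 1, "light", "early", f"r{i}"))
        log_a = rng.normal(1.5, 0.1, size=(n_genes, 12))
        log_b = rng.normal(1.5, 0.1, size=(n_genes, 12))
        log_b[:shift_genes] -= shift
        frame = pd.DataFrame(
            10 ** np.hstack([log_a, log_b]),
            index=[f"g{i}" for i in range(n_genes)],
            columns=ids_a + ids_b,
        )
        return ExpressionMatrix(frame), meta

    def test_identical_conditions_yield_no_calls(self):
        meta = []
        cols = []
        for cond in ("lc", "hc"):
            for i in range(4):
                sid = f"{cond}{i}"
                cols.append(sid)
                meta.append(SampleMetadata(sid, cond, 1, "light", "early", f"r{i}"))
        values = np.tile(np.array([[10.0], [20.0], [40.0]]), (1, 8))
        expr = ExpressionMatrix(
            pd.DataFrame(values, index=["g0", "g1", "g2"], columns=cols)
        )
        res = compare_gene_set_between_conditions(
            expr, meta, ["g0", "g1", "g2"], "lc", "hc"
        )
        assert np.allclose(res.table["log2_fold_change"], 0.0)
        assert res.counts == {"up": 0, "down": 0, "ns": 3}

    def test_planted_downshift_is_called_exactly(self, rng):
        expr, meta = self._paired_matrix(rng)
        res = compare_gene_set_between_conditions(
            expr, meta, [f"g{i}" for i in range(10)], "lc", "hc", alpha=0.001
        )
        down = set(res.table.index[res.table["direction"] == "down"])
        assert down == {f"g{i}" for i in range(5)}
        assert res.counts["down"] == 5 and res.counts["up"] == 0

    def test_unknown_gene_id_is_named(self, rng):
        expr, meta = self._paired_matrix(rng)
        with pytest.raises(KeyError, match="nope"):
            compare_gene_set_between_conditions(expr, meta, ["g0", "nope"],
                                                "lc", "hc")
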