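import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import lambda_oracle, random_profile_params
from phystate.io import SampleMetadata
from phystate.statespace import (
    DegenerateProfileError,
    DescriptorProfile,
    DescriptorSet,
    ReferenceRegion,
    build_reference_regions,
    classify_position,
    closer_state,
    map_sample_to_state_space,
    transcript_position_score,
)


class TestDescriptorProfile:
    def test_gap_geometry(self, profile_p):
        assert profile_p.epsilon == 1
        assert profile_p.theta == 1.0
        assert profile_p.theta_c == 2.0

    def test_overlapping_distributions_have_no_gap(self):
        p = DescriptorProfile("g", "diurnal", 1.0, 2.0, 0.5, 2.2, 1.8, 3.0)
        assert p.theta == 0.0
        assert p.theta_c is None

    def test_equal_medians_rejected(self):
        with pytest.raises(DegenerateProfileError):
            DescriptorProfile("g", "diurnal", 1.0, 1.0, 0.5, 1.5, 0.6, 1.4)

    def test_from_samples_uses_median_and_extremes(self):
        p = DescriptorProfile.from_samples(
            "g", "growth_phase", [0.5, 1.0, 1.5], [2.5, 3.0, 3.5]
        )
        assert (p.q2_alpha, p.min_alpha, p.max_alpha) == (1.0, 0.5, 1.5)
        assert (p.q2_beta, p.min_beta, p.max_beta) == (3.0, 2.5, 3.5)

    def test_round_trip_through_dict(self, profile_p):
        assert DescriptorProfile.from_dict(profile_p.to_dict()) == profile_p


class TestCloserState:
    @pytest.mark.parametrize(
        "kappa,expected", [(1.0, 1), (3.4, -1), (2.0, 0), (0.0, 1), (5.0, -1)]
    )
    def test_worked_values(self, profile_p, kappa, expected):
        assert closer_state(kappa, profile_p) == expected


class TestPositionScore:
    @pytest.mark.parametrize(
        "kappa,expected,branch",
        [
            (1.0, 1.5, "at_median"),  # at the alpha median
            (0.5, 2.0, "below_median"),  # alpha extreme, fully alpha-like
            (3.5, -2.0, "above_median"),  # beta extreme, fully beta-like
            (2.0, 0.0, "in_gap"),  # gap center: uncommitted
            (1.75, 0.5, "in_gap"),
            (3.0, -1.5, "at_median"),
        ],
    )
    def test_worked_values_on_reference_profile(self, profile_p, kappa, expected,
                                                branch):
        b = transcript_position_score(kappa, profile_p)
        assert b.lam == pytest.approx(expected, abs=1e-12)
        assert b.branch == branch

    def test_gap_edge_continuity(self, profile_p):
        # at the gap edge the range interpolation and the gap
        # interpolation must give the same score
        edge = profile_p.max_alpha  # 1.5
        via_range = transcript_position_score(edge, profile_p).lam
        via_gap = 2 * profile_p.epsilon * (profile_p.theta_c - edge) / profile_p.theta
        assert via_range == pytest.approx(1.0, abs=1e-12)
        assert via_gap == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_values_clamp(self, profile_p):
        low = transcript_position_score(-5.0, profile_p)
        high = transcript_position_score(10.0, profile_p)
        assert (low.lam, low.branch) == (2.0, "clamped_high")
        assert (high.lam, high.branch) == (-2.0, "clamped_low")

    def test_tie_without_gap_scores_zero(self):
        p = DescriptorProfile("g", "diurnal", 1.0, 2.0, 0.5, 1.8, 1.2, 2.5)
        b = transcript_position_score(1.5, p)
        assert b.lam == 0.0
        assert b.delta == 0

    @settings(max_examples=300, derandomize=True)
    @given(seed=st.integers(0, 10_000), offset=st.floats(-6, 6))
    def test_matches_oracle_and_stays_bounded(self, seed, offset):
        params = random_profile_params(np.random.default_rng(seed))
        p = DescriptorProfile("g", "diurnal", *params)
        kappa = p.theta_c + offset if p.theta_c is not None else offset
        lam = transcript_position_score(kappa, p).lam
        assert abs(lam) <= 2.0
        assert lam == pytest.approx(lambda_oracle(kappa, *params), abs=1e-12)

    @settings(max_examples=300, derandomize=True)
    @given(seed=st.integers(0, 10_000), offset=st.floats(-6, 6))
    def test_swapping_state_labels_negates_the_score(self, seed, offset):
        q2a, q2b, mina, maxa, minb, maxb = random_profile_params(
            np.random.default_rng(seed)
        )
        p = DescriptorProfile("g", "diurnal", q2a, q2b, mina, maxa, minb, maxb)
        swapped = DescriptorProfile("g", "diurnal", q2b, q2a, minb, maxb, mina, maxa)
        kappa = (q2a + q2b) / 2 + offset
        lam = transcript_position_score(kappa, p).lam
        lam_swapped = transcript_position_score(kappa, swapped).lam
        assert lam_swapped == pytest.approx(-lam, abs=1e-12)

    def test_score_is_plus_minus_1_5_at_the_state_medians(self):
        for seed in range(50):
            params = random_profile_params(np.random.default_rng(seed))
            p = DescriptorProfile("g", "diurnal", *params)
            assert transcript_position_score(p.q2_alpha, p).lam == 1.5
            assert transcript_position_score(p.q2_beta, p).lam == -1.5


class TestMapping:
    def _two_gene_sets(self, profile_p):
        x1 = DescriptorProfile("x1", "diurnal", 1.0, 3.0, 0.5, 1.5, 2.5, 3.5)
        x2 = DescriptorProfile("x2", "diurnal", 1.0, 3.0, 0.5, 1.5, 2.5, 3.5)
        y1 = DescriptorProfile("y1", "growth_phase", 1.0, 3.0, 0.5, 1.5, 2.5, 3.5)
        x_set = DescriptorSet("diurnal", [x1, x2])
        y_set = DescriptorSet("growth_phase", [y1])
        return x_set, y_set

    def test_all_zero_scores_map_to_origin(self, profile_p):
        x_set, y_set = self._two_gene_sets(profile_p)
        # kappa at the gap center scores 0 for every descriptor
        pos = map_sample_to_state_space(
            {"x1": 2.0, "x2": 2.0, "y1": 2.0}, x_set, y_set, "s"
        )
        assert (pos.s_x, pos.s_y) == (0.0, 0.0)

    def test_weighted_average_of_scores(self, profile_p):
        x_set, y_set = self._two_gene_sets(profile_p)
        # lambda(1.0) = 1.5 and lambda(1.75) = 0.5, equal weights -> 1.0
        pos = map_sample_to_state_space(
            {"x1": 1.0, "x2": 1.75, "y1": 1.0}, x_set, y_set, "s"
        )
        assert pos.s_x == pytest.approx(1.0, abs=1e-12)
        assert pos.s_y == pytest.approx(1.5, abs=1e-12)

    def test_missing_descriptor_gene_is_an_error(self, profile_p):
        x_set, y_set = self._two_gene_sets(profile_p)
        with pytest.raises(KeyError, match="y1"):
            map_sample_to_state_space({"x1": 1.0, "x2": 1.0}, x_set, y_set, "s")

    def test_coordinates_stay_within_bounds(self, profile_p):
        x_set, y_set = self._two_gene_sets(profile_p)
        for kappa in np.linspace(-10, 10, 21):
            pos = map_sample_to_state_space(
                {"x1": kappa, "x2": -kappa, "y1": kappa}, x_set, y_set, "s"
            )
            assert abs(pos.s_x) <= 2 and abs(pos.s_y) <= 2


class TestReferenceRegions:
    def _meta_for(self, positions):
        meta = []
        for sid in positions.index:
            d, g, r = sid.split("_")[:3]
            meta.append(SampleMetadata(sid, "lc", 1, d, g, r))
        return meta

    def _square_positions(self):
        rows = {}
        offsets = [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        centers = {
            ("light", "early"): (2, 2),
            ("light", "late"): (2, -2),
            ("dark", "early"): (-2, 2),
            ("dark", "late"): (-2, -2),
        }
        for (d, g), (cx, cy) in centers.items():
            for i, (ox, oy) in enumerate(offsets):
                rows[f"{d}_{g}_r{i}"] = (cx + ox, cy + oy)
        return pd.DataFrame(rows, index=["s_x", "s_y"]).T

    def test_four_regions_with_hand_computed_radius(self):
        positions = self._square_positions()
        regions = build_reference_regions(positions, self._meta_for(positions))
        assert len(regions) == 4
        reg = regions["light-early"]
        assert reg.centroid == (2.0, 2.0)
        # per-axis ddof-1 variance of {1,1,3,3} is 4/3; total SD of the
        # scatter is sqrt(4/3 + 4/3)
        assert reg.radius == pytest.approx(1.96 * math.sqrt(8 / 3), abs=1e-12)

    def test_identical_positions_give_zero_radius(self):
        positions = self._square_positions()
        positions.loc[:, :] = positions.groupby(
            [s.rsplit("_", 1)[0] for s in positions.index]
        ).transform("mean")
        regions = build_reference_regions(positions, self._meta_for(positions))
        assert all(r.radius == 0 for r in regions.values())

    def test_single_sample_state_is_an_error(self):
        positions = self._square_positions().iloc[[0, 4, 8, 12, 13, 14, 15]]
        with pytest.raises(ValueError, match=">= 2"):
            build_reference_regions(positions, self._meta_for(positions))

    def test_classification_rules(self):
        regions = {
            "light-early": ReferenceRegion("light-early", (1.5, 1.5), 0.5),
            "dark-late": ReferenceRegion("dark-late", (-1.5, -1.5), 0.5),
        }
        assert classify_position((1.5, 1.5), regions) == "light-early"
        assert classify_position((1.4, 1.6), regions) == "light-early"
        assert classify_position((0.0, 0.0), regions) == "non-distinctive"
        # nearest but outside its radius
        assert classify_position((1.5, 0.2), regions) == "non-distinctive"
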