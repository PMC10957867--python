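"""Composite construction, exclusions, centering, instrument encoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivsem import (SimulationConfig, apply_exclusions, build_aele_index,
                   build_analysis_frame, build_gi_composite, encode_distance,
                   simulate_survey)
from ivsem.preprocess import reverse_q26, sdq_total_from_subscales
from ivsem.simulate import AELE_COLUMNS


class TestInvestmentComposite:
    @pytest.mark.parametrize("items,expected", [
        ((3, 1, 4, 4), 3.75),            # maximum after reversing Q26
        ((1, 4, 1, 1), 1.0),             # minimum after reversing Q26
        ((2, np.nan, 3, 2), 7 / 3),      # mean of the available items
        ((2, 2, 2, 2), 9 / 4),
    ])
    def test_worked_examples(self, items, expected):
        assert build_gi_composite(*items) == pytest.approx(expected)

    def test_all_missing_gives_missing(self):
        assert np.isnan(build_gi_composite(np.nan, np.nan, np.nan, np.nan))

    @pytest.mark.parametrize("kwargs,item", [
        (dict(q15=4, q26=2, q27=2, q38=2), "q15"),    # q15 is a 3-point scale
        (dict(q15=2, q26=5, q27=2, q38=2), "q26"),
        (dict(q15=2, q26=2, q27=0, q38=2), "q27"),
    ])
    def test_out_of_range_names_item(self, kwargs, item):
        with pytest.raises(ValueError, match=item):
            build_gi_composite(**kwargs)

    @given(st.integers(min_value=1, max_value=4))
    @settings(deadline=None)
    def test_q26_reversal_is_an_involution(self, v):
        assert reverse_q26(reverse_q26(v)) == v

    def test_composite_range_on_generated_data(self):
        ds = simulate_survey(SimulationConfig(n_children=2000, seed=0,
                                              missing_rate=0.0))
        gi = build_gi_composite(ds.data.q15, ds.data.q26, ds.data.q27,
                                ds.data.q38)
        assert gi.min() >= 1.0 and gi.max() <= 3.75


class TestAdversityIndex:
    @pytest.mark.parametrize("events,expected", [
        ([0] * 8, 0),
        ([1] * 8, 8),
        ([0, 0, 0, 0, 0, 1, 1, 0], 2),   # e.g. parents separated + a death
    ])
    def test_counts(self, events, expected):
        assert build_aele_index(events) == expected

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            build_aele_index([0, 1, 2, 0, 0, 0, 0, 0])

    def test_missing_item_handling(self):
        events = [1, 1, np.nan, 0, 0, 0, 0, 0]
        assert np.isnan(build_aele_index(events))
        assert build_aele_index(events, require_complete=False) == 2

    def test_wrong_width_rejected(self):
        with pytest.raises(ValueError, match="8"):
            build_aele_index([0, 1, 0])


class TestDistanceEncoding:
    @pytest.mark.parametrize("level,expected", [
        ("overseas", (0, 0, 0)),          # reference category
        ("same_town", (1, 0, 0)),
        ("within_10_miles", (0, 1, 0)),
        ("further_in_uk", (0, 0, 1)),
    ])
    def test_mapping(self, level, expected):
        assert encode_distance(level) == expected

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="moon"):
            encode_distance("moon")

    def test_vectorized_rows_are_valid_dummies(self):
        arr = encode_distance(pd.Series(["same_town", "overseas",
                                         "further_in_uk"]))
        assert arr.tolist() == [[1, 0, 0], [0, 0, 0], [0, 0, 1]]


class TestExclusions:
    @staticmethod
    def _records(n=1566, n_dead=78, n_cores=58, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"id": np.arange(n)})
        df["has_living_grandparent"] = True
        df["coresides_with_grandparent"] = False
        dead = rng.choice(n, size=n_dead, replace=False)
        df.loc[dead, "has_living_grandparent"] = False
        alive = df.index[df.has_living_grandparent]
        cores = rng.choice(alive, size=n_cores, replace=False)
        df.loc[cores, "coresides_with_grandparent"] = True
        return df

    def test_survey_like_counts(self):
        kept, log = apply_exclusions(self._records())
        assert log.n_input == 1566
        assert log.n_no_living_grandparent == 78      # 1488 retained at step 1
        assert log.n_coresident == 58
        assert log.n_retained == len(kept) == 1430

    def test_empty_input(self):
        kept, log = apply_exclusions(self._records(0, 0, 0))
        assert len(kept) == 0 and log.n_retained == 0

    def test_idempotent_and_order_independent(self):
        df = self._records(200, 13, 7)
        kept1, _ = apply_exclusions(df)
        kept2, log2 = apply_exclusions(kept1)
        assert kept1.equals(kept2)
        assert log2.n_no_living_grandparent == log2.n_coresident == 0
        shuffled = df.sample(frac=1, random_state=1)
        _, log3 = apply_exclusions(shuffled)
        assert log3.n_retained == 180 and log3.n_no_living_grandparent == 13

    def test_missing_flags_excluded_with_warning(self):
        df = self._records(50, 5, 3)
        df["has_living_grandparent"] = df["has_living_grandparent"].astype(object)
        df.loc[0, "has_living_grandparent"] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            _, log = apply_exclusions(df)
        assert log.n_missing_flags == 1
        with pytest.raises(ValueError):
            apply_exclusions(df, on_missing="error")


class TestAnalysisFrame:
    def test_centering_and_dummies(self):
        ds = simulate_survey(SimulationConfig(n_children=500, seed=1,
                                              missing_rate=0.0))
        frame = build_analysis_frame(ds)
        assert abs(frame.data.gi_c.mean()) < 1e-10
        assert abs(frame.data.aele_c.mean()) < 1e-10
        dummies = frame.data[["d1", "d2", "d3"]].to_numpy()
        assert set(map(tuple, dummies)) <= {(0, 0, 0), (1, 0, 0),
                                            (0, 1, 0), (0, 0, 1)}

    def test_constant_adversity_degenerates_cleanly(self):
        ds = simulate_survey(SimulationConfig(n_children=100, seed=2,
                                              missing_rate=0.0, aele_prob=0.0))
        frame = build_analysis_frame(ds)
        assert (frame.data.aele_c == 0).all()
        assert (frame.data[["d1_x_aele", "d2_x_aele", "d3_x_aele"]] == 0).all().all()

    def test_hand_made_interaction_column(self):
        df = pd.DataFrame({
            "distance": ["same_town", "overseas", "within_10_miles",
                         "further_in_uk", "same_town"],
            "q15": [1, 2, 3, 2, 1], "q26": [4, 3, 1, 2, 4],
            "q27": [1, 2, 4, 3, 1], "q38": [1, 2, 4, 3, 1],
            "sdq_total": [10.0, 12.0, 8.0, 20.0, 15.0],
        })
        for i, c in enumerate(AELE_COLUMNS):
            df[c] = [0, 1, 0, 1, 0] if i == 0 else 0
        frame = build_analysis_frame(df, min_complete=5)
        expected = (frame.data.gi_c * frame.data.aele_c).to_numpy()
        np.testing.assert_allclose(frame.data.gi_x_aele, expected, atol=1e-12)
        # gi for row 0 by hand: (1 + (5-4) + 1 + 1)/4 = 1.0
        assert frame.data.gi_c.iloc[0] == pytest.approx(1.0 - frame.gi_mean)

    def test_external_means_are_respected(self):
        ds = simulate_survey(SimulationConfig(n_children=200, seed=3,
                                              missing_rate=0.0))
        frame = build_analysis_frame(ds, means=(2.0, 1.0))
        assert frame.gi_mean == 2.0 and frame.aele_mean == 1.0
        assert abs(frame.data.aele_c.mean()) > 0.01   # not re-centered

    def test_too_few_complete_rows_raises(self):
        ds = simulate_survey(SimulationConfig(n_children=30, seed=4,
                                              missing_rate=0.9))
        with pytest.raises(ValueError, match="complete rows"):
            build_analysis_frame(ds, min_complete=25)


def test_sdq_total_sums_four_difficulty_subscales():
    assert sdq_total_from_subscales(3, 4, 5, 1) == 13
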