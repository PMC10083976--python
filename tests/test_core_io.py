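import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traitchange.core_io import (
    PANEL_COLUMNS,
    LongPanel,
    ScoringKey,
    cronbach_alpha,
    read_long_panel,
    reverse_code,
    score_scales,
    select_longitudinal_informant,
    write_long_panel,
)
from traitchange.errors import IntegrityError, SchemaError, ValidationError
from traitchange.synthetic import default_bfas_config, generate_panel

from conftest import item_panel


def _rows(*tuples):
    return pd.DataFrame(
        [dict(zip(PANEL_COLUMNS, t)) for t in tuples], columns=PANEL_COLUMNS
    )


class TestLongPanelValidation:
    def test_well_formed_panel_round_trips_identity(self):
        df = _rows(
            ("p1", None, "self", 1, 0.0, "item1", 3.0),
            ("p1", None, "self", 2, 6.0, "item1", 4.0),
            ("p2", "i1", "other", 1, 0.0, "item1", 2.0),
            ("p2", "i1", "other", 2, 6.0, "item1", 2.0),
        )
        panel = LongPanel(df)
        assert len(panel.data) == 4
        assert panel.waves == [1, 2]
        assert panel.wave_months == {1: 0.0, 2: 6.0}

    def test_duplicate_key_rejected_with_key_named(self):
        df = _rows(
            ("p1", None, "self", 1, 0.0, "item1", 3.0),
            ("p1", None, "self", 1, 0.0, "item1", 4.0),
        )
        with pytest.raises(IntegrityError, match="p1"):
            LongPanel(df)

    def test_missing_column_is_schema_error(self):
        with pytest.raises(SchemaError, match="value"):
            LongPanel(pd.DataFrame({"person_id": ["p1"]}))

    def test_out_of_range_likert_value_rejected(self):
        df = _rows(("p1", None, "self", 1, 0.0, "item1", 7.0))
        with pytest.raises(ValidationError, match=r"\[1, 5\]"):
            LongPanel(df, item_level=True)

    def test_month_must_be_constant_within_wave(self):
        df = _rows(
            ("p1", None, "self", 1, 0.0, "item1", 3.0),
            ("p2", None, "self", 1, 2.0, "item1", 3.0),
        )
        with pytest.raises(IntegrityError, match="wave"):
            LongPanel(df)

    def test_first_wave_month_must_be_zero(self):
        df = _rows(("p1", None, "self", 1, 3.0, "item1", 3.0))
        with pytest.raises(IntegrityError, match="must be 0"):
            LongPanel(df)


def test_csv_round_trip_preserves_synthetic_panel(tmp_path):
    cfg = default_bfas_config(seed=7, n_persons=20, retention=(20, 15, 15, 10))
    panel, _ = generate_panel(cfg)
    path = tmp_path / "panel.csv"
    write_long_panel(panel, path)
    back = read_long_panel(path)
    assert panel.equals(back)


def test_read_long_panel_schema_mapping(tmp_path):
    df = _rows(("p1", None, "self", 1, 0.0, "item1", 3.0)).rename(
        columns={"person_id": "pid"}
    )
    path = tmp_path / "renamed.csv"
    df.to_csv(path, index=False)
    panel = read_long_panel(path, schema={"person_id": "pid"})
    assert panel.data.loc[0, "person_id"] == "p1"


class TestScoring:
    def test_constant_items_give_constant_aspect(self, toy_key):
        key = ScoringKey(
            pd.DataFrame(
                {
                    "item": [f"x{i}" for i in range(10)],
                    "scale": "S",
                    "domain": "S",
                    "sign": 1,
                }
            ),
            require_two_aspects=False,
        )
        panel = item_panel(np.full((3, 10), 3.0), [f"x{i}" for i in range(10)])
        scores = score_scales(panel, key)
        assert (scores.data["value"] == 3.0).all()

    def test_reverse_coding_formula(self):
        # values (5, 1) with signs (+1, -1) -> reverse-coded (5, 5) -> mean 5
        key = ScoringKey(
            pd.DataFrame(
                {"item": ["i1", "i2"], "scale": "S", "domain": "S",
                 "sign": [1, -1]}
            ),
            require_two_aspects=False,
        )
        panel = item_panel(np.array([[5.0, 1.0]]), ["i1", "i2"])
        scores = score_scales(panel, key)
        assert scores.data["value"].iloc[0] == pytest.approx(5.0)

    def test_domain_is_mean_of_constituent_items(self, toy_key):
        # aspect A1 scores 2.0 (after reverse-coding), A2 scores 4.0
        panel = item_panel(np.array([[2.0, 4.0, 4.0, 4.0]]),
                           ["a1", "a2", "a3", "a4"])
        scores = score_scales(panel, toy_key)
        by_var = scores.data.set_index("variable")["value"]
        assert by_var["A1"] == pytest.approx(2.0)
        assert by_var["A2"] == pytest.approx(4.0)
        assert by_var["A"] == pytest.approx(3.0)

    def test_unknown_item_raises_key_error(self, toy_key):
        panel = item_panel(np.array([[3.0]]), ["mystery"])
        with pytest.raises(KeyError, match="mystery"):
            score_scales(panel, toy_key)

    def test_scoring_invariant_to_row_order(self, toy_key):
        rng = np.random.default_rng(0)
        panel = item_panel(rng.integers(1, 6, (6, 4)).astype(float),
                           ["a1", "a2", "a3", "a4"])
        shuffled = LongPanel(
            panel.data.sample(frac=1.0, random_state=1).reset_index(drop=True),
            likert_bounded=False,
        )
        a = score_scales(panel, toy_key)
        b = score_scales(shuffled, toy_key)
        assert a.equals(b)

    def test_missing_item_policy_80_percent(self):
        items = [f"x{i}" for i in range(10)]
        key = ScoringKey(
            pd.DataFrame({"item": items, "scale": "S", "domain": "S", "sign": 1}),
            require_two_aspects=False,
        )
        vals = np.full((2, 10), 3.0)
        vals[0, 8:] = np.nan  # 8/10 present -> scored
        vals[1, 3:] = np.nan  # 3/10 present -> missing
        panel = item_panel(vals, items)
        scores = score_scales(panel, key)
        scored_persons = set(scores.data["person_id"])
        assert scored_persons == {"P0"}

    @given(st.floats(min_value=1.0, max_value=5.0))
    def test_reverse_coding_is_involution(self, x):
        assert reverse_code(reverse_code(x)) == pytest.approx(x)


class TestCronbachAlpha:
    def test_identical_columns_alpha_one(self):
        col = np.array([1.0, 2.0, 3.0, 4.0])
        assert cronbach_alpha(np.column_stack([col, col, col])) == pytest.approx(1.0)

    def test_two_item_closed_form(self):
        # 2 items, each variance 1, covariance 0.5 -> alpha = 2*(1-2/3) = 2/3
        rng = np.random.default_rng(3)
        chol = np.linalg.cholesky([[1.0, 0.5], [0.5, 1.0]])
        x = rng.standard_normal((200_0, 2)) @ chol.T
        # standardise empirically so the sample moments are exact
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        r = np.corrcoef(x.T)[0, 1]
        expected = 2 * (1 - 2 / (2 + 2 * r))
        assert cronbach_alpha(x) == pytest.approx(expected, abs=1e-12)

    def test_alpha_matches_spearman_brown_for_two_items(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((50, 2))
        x[:, 1] = 0.6 * x[:, 0] + 0.8 * rng.standard_normal(50)
        alpha = cronbach_alpha(x)
        v1, v2 = x.var(0, ddof=1)
        c = np.cov(x.T, ddof=1)[0, 1]
        # standardized-agnostic closed form for k=2
        expected = 2 * (1 - (v1 + v2) / (v1 + v2 + 2 * c))
        assert alpha == pytest.approx(expected, abs=1e-12)

    def test_simulated_parallel_items_recover_population_alpha(self):
        rng = np.random.default_rng(5)
        n, k = 5000, 10
        truth = rng.standard_normal(n)
        target = 0.80
        s2 = k * (1 - target) / target
        items = truth[:, None] + rng.standard_normal((n, k)) * np.sqrt(s2)
        assert 0.78 <= cronbach_alpha(items) <= 0.82

    def test_zero_variance_returns_nan_with_warning(self):
        x = np.array([[1.0, -1.0]] * 5)
        with pytest.warns(UserWarning, match="alpha undefined"):
            assert np.isnan(cronbach_alpha(x))


class TestInformantSelection:
    @staticmethod
    def _panel(informant_waves: dict[str, list[int]]) -> LongPanel:
        months = {1: 0.0, 2: 6.0, 3: 13.0, 4: 19.0}
        rows = [("p1", None, "self", w, months[w], "T", 3.0) for w in (1, 2, 3, 4)]
        for inf, waves in informant_waves.items():
            rows += [("p1", inf, "other", w, months[w], "T", 3.0) for w in waves]
        return LongPanel(_rows(*rows), item_level=False)

    def test_singleton_eligible_pool_kept(self):
        panel = self._panel({"i1": [1, 3]})
        sel = select_longitudinal_informant(panel, seed=0)
        assert sel.chosen == {"p1": "i1"}
        assert (sel.panel.data[sel.panel.data["rater_role"] == "other"]
                ["informant_id"] == "i1").all()

    def test_single_wave_informants_all_ineligible(self):
        panel = self._panel({"i1": [1], "i2": [2], "i3": [4]})
        sel = select_longitudinal_informant(panel, seed=0)
        assert sel.chosen == {}
        assert sel.ineligible == ["p1"]
        assert (sel.panel.data["rater_role"] == "self").all()

    def test_selection_deterministic_under_seed(self):
        cfg = default_bfas_config(seed=11, n_persons=40,
                                  retention=(1.0,) * 4, n_informants=3,
                                  informant_wave_prob=0.6)
        panel, _ = generate_panel(cfg)
        a = select_longitudinal_informant(panel, seed=42)
        b = select_longitudinal_informant(panel, seed=42)
        assert a.chosen == b.chosen
        assert a.panel.equals(b.panel)
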