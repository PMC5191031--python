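"""Splitting, metrics identities, classifier training and rm-ANOVA."""

from __future__ import annotations

import numpy as np
import pytest

from erders_bmi import (
    DecoderModel,
    SplitPlan,
    evaluate,
    f_score,
    split,
    strategy_grid,
    train_decoder,
)
from erders_bmi.decoding import (
    cross_session_average,
    metrics_from_confusion,
    rm_anova_2x2,
)
from tests.conftest import feature_data


class TestSplit:
    def test_stratified_counts_80_20(self, rng):
        x = rng.standard_normal((200, 3))
        y = np.array(["a"] * 100 + ["b"] * 100)
        plan = SplitPlan(train_fraction=0.8, seed=1)
        xtr, ytr, xte, yte = split(x, y, plan)
        assert len(ytr) == 160 and len(yte) == 40
        for c in ("a", "b"):
            assert (ytr == c).sum() == 80
            assert (yte == c).sum() == 20

    def test_same_seed_identical_partition(self, rng):
        x = rng.standard_normal((60, 2))
        y = np.array(["a", "b"] * 30)
        p = SplitPlan(train_fraction=0.6, seed=9)
        a = split(x, y, p)
        b = split(x, y, p)
        for u, v in zip(a, b):
            assert np.array_equal(u, v)

    def test_odd_counts_floor_to_train(self, rng):
        x = rng.standard_normal((21, 2))
        y = np.array(["a"] * 11 + ["b"] * 10)
        xtr, ytr, _, yte = split(x, y, SplitPlan(train_fraction=0.5, seed=0))
        assert (ytr == "a").sum() == 5  # floor(0.5 * 11)
        assert (ytr == "b").sum() == 5

    def test_disallowed_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitPlan(train_fraction=0.7)

    def test_single_trial_class_rejected(self, rng):
        x = rng.standard_normal((3, 2))
        y = np.array(["a", "a", "b"])
        with pytest.raises(ValueError):
            split(x, y, SplitPlan(train_fraction=0.5, seed=0))


class TestMetrics:
    @pytest.mark.parametrize(
        "precision,recall,expected",
        [
            (76.86, 75.48, 76.16),  # printed strategy-table cross-check
            (91.96, 90.56, 91.25),
            (85.84, 82.13, 83.94),
        ],
    )
    def test_f_score_matches_published_values(self, precision, recall, expected):
        assert round(f_score(precision, recall), 2) == expected

    def test_perfect_predictions(self):
        rep = metrics_from_confusion(np.array([[20, 0], [0, 20]]), ("a", "b"))
        assert rep.accuracy == 100.0
        assert rep.f_scores == {"a": 100.0, "b": 100.0}

    def test_metric_identities(self):
        cm = np.array([[17, 3], [5, 15]])
        rep = metrics_from_confusion(cm, ("a", "b"))
        assert rep.n_test == cm.sum()
        assert rep.recall["a"] == pytest.approx(100 * 17 / 20, abs=1e-10)
        assert rep.precision["a"] == pytest.approx(100 * 17 / 22, abs=1e-10)
        # accuracy equals support-weighted recall
        weighted = (rep.recall["a"] * 20 + rep.recall["b"] * 20) / 40
        assert rep.accuracy == pytest.approx(weighted, abs=1e-10)
        for c in ("a", "b"):
            assert rep.f_scores[c] == pytest.approx(
                f_score(rep.precision[c], rep.recall[c]), abs=1e-10
            )

    def test_empty_predicted_class_zero_convention(self):
        rep = metrics_from_confusion(np.array([[0, 10], [0, 10]]), ("a", "b"))
        assert rep.precision["a"] == 0.0
        assert "a" in rep.degenerate_precision

    def test_cross_session_average(self):
        assert cross_session_average([74.34, 76.85, 85.38, 88.43]) == pytest.approx(
            81.25
        )


class TestTrainDecoder:
    @pytest.fixture(scope="class")
    def session_features(self, small_epochs):
        return feature_data(small_epochs)

    @pytest.mark.parametrize("kind", ["LDA", "SVM", "BPNN"])
    def test_separable_training_data_fit_perfectly(self, kind, small_epochs):
        data, labels = feature_data(small_epochs)
        plan = SplitPlan(train_fraction=0.8, seed=3)
        xtr, ytr, xte, yte = split(data, labels, plan)
        model = train_decoder(
            xtr, ytr, kind, plan, m=2, fs=small_epochs.fs,
            channel_labels=small_epochs.channel_labels, window_s=(4.0, 7.0),
        )
        rep = evaluate(model, xtr, ytr)
        assert rep.accuracy >= 90.0  # synthetic classes are separable

    def test_label_shuffle_gives_chance_on_held_out_trials(self, small_epochs, rng):
        """Permutation null: with shuffled labels the decoder cannot beat
        chance on held-out trials (CSP+classifier see only training data)."""
        data, labels = feature_data(small_epochs)
        shuffled = rng.permutation(labels)
        plan = SplitPlan(train_fraction=0.5, seed=3)
        xtr, ytr, xte, yte = split(data, shuffled, plan)
        model = train_decoder(xtr, ytr, "LDA", plan, m=2, fs=small_epochs.fs)
        rep = evaluate(model, xte, yte)
        # binomial 95% band around 50% for 30 held-out trials
        assert 25.0 <= rep.accuracy <= 75.0

    def test_identical_input_identical_parameters(self, small_epochs):
        data, labels = feature_data(small_epochs)
        plan = SplitPlan(train_fraction=0.8, seed=3)
        kw = dict(m=2, fs=small_epochs.fs)
        m1 = train_decoder(data, labels, "LDA", plan, **kw)
        m2 = train_decoder(data, labels, "LDA", plan, **kw)
        assert m1.to_json() == m2.to_json()

    def test_model_immune_to_test_labels(self, small_epochs, rng):
        """Shuffling test labels changes metrics but not the trained model."""
        data, labels = feature_data(small_epochs)
        plan = SplitPlan(train_fraction=0.8, seed=3)
        xtr, ytr, xte, yte = split(data, labels, plan)
        model = train_decoder(xtr, ytr, "LDA", plan, m=2, fs=small_epochs.fs)
        before = model.to_json()
        _ = evaluate(model, xte, rng.permutation(yte))
        assert model.to_json() == before

    def test_json_round_trip_preserves_predictions(self, small_epochs, tmp_path):
        data, labels = feature_data(small_epochs)
        plan = SplitPlan(train_fraction=0.8, seed=3)
        xtr, ytr, xte, yte = split(data, labels, plan)
        model = train_decoder(xtr, ytr, "BPNN", plan, m=2, fs=small_epochs.fs)
        path = tmp_path / "decoder.json"
        model.to_json(path)
        back = DecoderModel.from_json(path)
        assert np.array_equal(model.predict(xte), back.predict(xte))


class TestStrategyGrid:
    def test_grid_layout_and_best_strategy(self, small_epochs):
        data, labels = feature_data(small_epochs)
        result = strategy_grid(
            {"s1": (data, labels)}, seed=4, m=2, fs=small_epochs.fs, cv_folds=5
        )
        assert list(result.table.index) == [f"S{i}" for i in range(1, 10)]
        assert result.table.loc["S1", "classifier"] == "LDA"
        assert result.table.loc["S9", "classifier"] == "BPNN"
        assert np.allclose(
            result.table["Average"], result.table["s1"], atol=1e-12
        )  # single session: average equals that session
        assert result.best_strategy in result.table.index

    def test_equal_accuracies_average_identity(self):
        assert cross_session_average([83.0, 83.0, 83.0]) == 83.0


class TestRmAnova:
    @staticmethod
    def _oracle(table):
        """Independent route: statsmodels AnovaRM on the long-format table."""
        import pandas as pd
        from statsmodels.stats.anova import AnovaRM

        n = table.shape[0]
        rows = [
            (s, a, b, table[s, a, b])
            for s in range(n)
            for a in range(2)
            for b in range(2)
        ]
        df = pd.DataFrame(rows, columns=["subject", "A", "B", "y"])
        res = AnovaRM(df, "y", "subject", within=["A", "B"]).fit().anova_table
        return {
            "F_A": res.loc["A", "F Value"],
            "F_B": res.loc["B", "F Value"],
            "F_AB": res.loc["A:B", "F Value"],
            "p_A": res.loc["A", "Pr > F"],
            "p_B": res.loc["B", "Pr > F"],
            "p_AB": res.loc["A:B", "Pr > F"],
        }

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        table = 80.0 + 5.0 * rng.standard_normal((4, 2, 2))
        ours = rm_anova_2x2(table)
        oracle = self._oracle(table)
        for key in ("F_A", "F_B", "F_AB", "p_A", "p_B", "p_AB"):
            assert ours[key] == pytest.approx(oracle[key], abs=1e-8)

    def test_pure_main_effect_without_noise(self):
        table = np.zeros((4, 2, 2))
        table[:, 1, :] = 10.0  # factor A shifts every subject equally
        table += np.arange(4)[:, None, None]  # subject offsets only
        res = rm_anova_2x2(table)
        assert res["F_A"] == float("inf") and res["p_A"] == 0.0
        assert res["F_B"] == 0.0 and res["p_B"] == 1.0

    def test_all_cells_equal_gives_zero_f(self):
        res = rm_anova_2x2(np.full((3, 2, 2), 7.0))
        assert res["F_A"] == 0.0 and res["F_B"] == 0.0 and res["F_AB"] == 0.0

    def test_missing_cell_rejected(self):
        bad = np.full((3, 2, 2), 1.0)
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova_2x2(bad)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            rm_anova_2x2(np.zeros((1, 2, 2)))
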