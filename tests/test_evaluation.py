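"""Prediction, Table-style metrics, cross-validation and survey filters."""

import numpy as np
import pandas as pd
import pytest

from weedhmm.core import FieldSeries, LHTriplet, SpeciesParameters
from weedhmm.evaluation import (
    compute_metrics,
    cross_validate,
    cv_table,
    partition_folds,
    predict_next_class,
    predictive_distribution,
    select_species,
)
from weedhmm.inference import SearchConfig
from weedhmm.kernels import TransitionKernel, exact_kernel_enumeration

from conftest import ACTIONS, make_dataset


class TestMetrics:
    def test_hand_computed_absence_cells(self):
        m = compute_metrics(predicted=[1, 2, 1], observed=[1, 1, 1])
        assert m.absence_efficiency == pytest.approx(2 / 3)
        assert m.presence_efficiency is None
        assert m.class_error_absence == (pytest.approx(1.0), pytest.approx(0.0))
        assert m.class_error_presence is None

    def test_perfect_absence_prediction_leaves_error_undefined(self):
        m = compute_metrics(predicted=[1, 1, 1], observed=[1, 1, 1])
        assert m.absence_efficiency == 1.0
        assert m.class_error_absence is None
        assert m.as_row()["class_error_absence"] == "n.a."

    def test_under_predicted_presence_has_negative_class_error(self):
        m = compute_metrics(predicted=[2, 3], observed=[3, 4])
        # both predictions are presence classes, so presence is detected...
        assert m.presence_efficiency == 1.0
        # ...but each is one class too low
        assert m.class_error_presence == (pytest.approx(-1.0), pytest.approx(0.0))

    def test_always_wrong_predictor_scores_zero(self):
        m = compute_metrics(predicted=[2, 2, 1, 1], observed=[1, 1, 3, 4])
        assert m.absence_efficiency == 0.0
        assert m.presence_efficiency == 0.0
        assert m.class_error_absence == (pytest.approx(1.0), pytest.approx(0.0))
        assert m.class_error_presence == (pytest.approx(-2.5), pytest.approx(0.5))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        obs = rng.integers(1, 5, size=50)
        pred = rng.integers(1, 5, size=50)
        perm = rng.permutation(50)
        a = compute_metrics(pred, obs)
        b = compute_metrics(pred[perm], obs[perm])
        assert a.absence_efficiency == pytest.approx(b.absence_efficiency)
        assert a.presence_efficiency == pytest.approx(b.presence_efficiency)
        assert a.class_error_absence == pytest.approx(b.class_error_absence)
        assert a.class_error_presence == pytest.approx(b.class_error_presence)
        assert (a.n_absence, a.n_presence) == (b.n_absence, b.n_presence)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([1], [1, 2])


class TestFolds:
    def test_survey_sized_partition(self):
        folds = partition_folds(329, 4, seed=0)
        assert [len(f) for f in folds] == [83, 82, 82, 82]
        all_items = np.concatenate(folds)
        assert len(np.unique(all_items)) == 329

    def test_partition_is_deterministic_in_the_seed(self):
        a = partition_folds(100, 4, seed=5)
        b = partition_folds(100, 4, seed=5)
        c = partition_folds(100, 4, seed=6)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))

    def test_too_few_fields(self):
        with pytest.raises(ValueError):
            partition_folds(3, 4, seed=0)


class TestPrediction:
    def test_empty_bank_without_production_predicts_absence_forever(self):
        p0 = np.zeros(6)
        p0[0] = 1.0
        params = SpeciesParameters(lht={"WC": LHTriplet(0.6, 0.5, 0.0)}, p0=p0)
        kernels = {"WC": exact_kernel_enumeration(params.lht["WC"])}
        for t in range(4):
            pred = predict_next_class(("WC",) * (t + 1), (1,) * t, params, kernels)
            assert pred == 1

    def test_uniform_kernels_tie_break_to_the_smallest_class(self):
        kern = TransitionKernel(
            np.full((6, 4), 0.25),
            np.full((6, 4, 6), 1 / 6),
            np.ones((6, 4), dtype=bool),
        )
        params = SpeciesParameters(
            lht={"WC": LHTriplet(0.5, 0.5, 1.0)}, p0=np.full(6, 1 / 6)
        )
        dist = predictive_distribution(("WC", "WC"), (3,), params, {"WC": kern})
        assert np.allclose(dist, 0.25)
        assert predict_next_class(("WC", "WC"), (3,), params, {"WC": kern}) == 1

    def test_informative_kernels_predict_simulated_classes_above_chance(self):
        """Simulating the class-level chain at known parameters, one-step
        predictions agree with the realised class in most steps."""
        lht = LHTriplet(0.6, 0.8, 8.0)
        kern = exact_kernel_enumeration(lht)
        p0 = np.array([0.5, 0.0, 0.0, 0.0, 0.0, 0.5])
        params = SpeciesParameters(lht={"WC": lht}, p0=p0)
        rng = np.random.default_rng(12)
        hits = total = 0
        for _ in range(60):
            cy = rng.choice(6, p=p0)
            obs = []
            for t in range(5):
                cx = rng.choice(4, p=kern.emergence[cy])
                pred = predict_next_class(
                    ("WC",) * (t + 1), tuple(obs), params, {"WC": kern}
                )
                hits += pred == cx + 1
                total += 1
                obs.append(cx + 1)
                cy = rng.choice(6, p=kern.bank_update[cy, cx])
        assert hits / total > 0.5

    def test_impossible_prefix_warns_and_falls_back(self):
        p0 = np.zeros(6)
        p0[0] = 1.0
        params = SpeciesParameters(lht={"WC": LHTriplet(0.0, 0.9, 5.0)}, p0=p0)
        kernels = {"WC": exact_kernel_enumeration(params.lht["WC"])}
        with pytest.warns(RuntimeWarning):
            pred = predict_next_class(("WC", "WC"), (3,), params, kernels)
        assert pred == 1

    def test_strict_single_step_conditions_on_latest_observation_only(self, truth):
        kernels = {a: exact_kernel_enumeration(t) for a, t in truth.lht.items()}
        long_prefix = predictive_distribution(
            ("WC", "WC", "M", "WC"), (1, 1, 4), truth, kernels, strict_single_step=True
        )
        short = predictive_distribution(
            ("M", "WC"), (4,), truth, kernels, strict_single_step=True
        )
        assert np.allclose(long_prefix, short)


@pytest.fixture(scope="module")
def report(small_dataset):
    return cross_validate(
        small_dataset,
        n_folds=3,
        search=SearchConfig(
            population_size=30, max_iterations=80, seed=0, polish_maxfev=200
        ),
        seed=0,
    )


class TestCrossValidation:
    def test_every_observation_is_predicted_once(self, small_dataset, report):
        assert len(report.predictions) == small_dataset.n_observations
        assert set(report.fold_assignment) == {
            s.field_id for s in small_dataset.series
        }

    def test_report_is_deterministic(self, small_dataset, report):
        again = cross_validate(
            small_dataset,
            n_folds=3,
            search=SearchConfig(
                population_size=30, max_iterations=80, seed=0, polish_maxfev=200
            ),
            seed=0,
        )
        pd.testing.assert_frame_equal(report.predictions, again.predictions)

    def test_table_row_shape(self, report):
        df = cv_table([report])
        assert list(df["species"]) == [report.species_id]
        assert "absence_efficiency" in df.columns


class TestSelectSpecies:
    @staticmethod
    def build_records():
        """32 species engineered so exactly the 18 'good' ones survive the
        120-survey and 10%-pair filters."""
        rows = []
        years = range(2001, 2009)
        for f in range(40):
            for y in years:
                a = ACTIONS[(f + y) % 4]
                # good species: everywhere in even fields, every year
                if f % 2 == 0:
                    for i in range(18):
                        rows.append((f"F{f}", y, a, f"GOOD{i:02d}", 2))
        df = pd.DataFrame(
            rows, columns=["field_id", "year", "action", "species_id", "abundance_class"]
        )
        extra = []
        # 7 species with exactly 119 occurrence records (fail the count rule)
        for i in range(7):
            n = 0
            for f in range(40):
                for y in years:
                    if n >= 119:
                        break
                    extra.append(
                        (f"F{f}", y, ACTIONS[(f + y) % 4], f"RARE{i}", 3)
                    )
                    n += 1
        # 7 abundant species only ever seen under two actions (fail pair rule)
        for i in range(7):
            for f in range(40):
                for y in years:
                    if ACTIONS[(f + y) % 4] in ("WC", "OR"):
                        extra.append((f"F{f}", y, ACTIONS[(f + y) % 4], f"SEAS{i}", 2))
        return pd.concat(
            [
                df,
                pd.DataFrame(
                    extra,
                    columns=[
                        "field_id", "year", "action", "species_id", "abundance_class",
                    ],
                ),
            ],
            ignore_index=True,
        )

    def test_empty_table_gives_empty_list(self):
        empty = pd.DataFrame(
            columns=["field_id", "year", "action", "species_id", "abundance_class"]
        )
        assert select_species(empty) == []

    def test_exactly_the_engineered_species_pass(self):
        records = self.build_records()
        kept = select_species(records)
        assert kept == sorted(f"GOOD{i:02d}" for i in range(18))

    def test_119_surveys_is_below_the_threshold(self):
        records = self.build_records()
        counts = (
            records[records["abundance_class"] > 1].groupby("species_id").size()
        )
        assert counts["RARE0"] == 119
        assert "RARE0" not in select_species(records)
        # lowering the threshold by one admits it (its pairs are spread
        # evenly enough to clear the 10% rule)
        assert "RARE0" in select_species(records, min_surveys=119)
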