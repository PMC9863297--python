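"""Best-subset MLR workflow: fitting, splitting, metrics, applicability domain."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from eutsol import qspr, synth
from eutsol.exceptions import DomainError, FitError, ValidationError
from eutsol.sigma import DescriptorTable


def make_table(n=30, p=5, seed=0):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        rng.standard_normal((n, p)), columns=[f"d{i + 1}" for i in range(p)]
    )
    return frame, rng


class TestStandardize:
    def test_columns_become_zero_mean_unit_sd(self):
        frame, _ = make_table()
        table = DescriptorTable(frame=frame * 7 + 3)
        scaled, params = qspr.standardize(table)
        means = scaled.frame.mean()
        sds = scaled.frame.std(ddof=1)
        assert np.allclose(means, 0.0, atol=1e-12)
        assert np.allclose(sds, 1.0, atol=1e-12)
        assert set(params) == set(frame.columns)

    def test_sample_sd_convention_on_three_points(self):
        scaled, params = qspr.standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        assert params["a"] == pytest.approx((2.0, 1.0))
        assert scaled.frame["a"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_already_standardized_unchanged(self):
        frame, _ = make_table()
        first, _ = qspr.standardize(frame)
        second, _ = qspr.standardize(first.frame)
        assert np.allclose(first.frame.to_numpy(), second.frame.to_numpy(), atol=1e-12)

    def test_constant_column_error_names_it(self):
        with pytest.raises(FitError, match="flat"):
            qspr.standardize(pd.DataFrame({"flat": [1.0, 1.0, 1.0]}))


class TestCorrelationFilter:
    def test_perfectly_correlated_pair_keeps_one(self):
        frame, _ = make_table(p=1)
        frame["d2"] = 2.0 * frame["d1"]
        kept = qspr.correlation_filter(frame)
        assert len(kept.descriptor_names) == 1

    def test_orthogonal_columns_all_survive(self):
        frame = pd.DataFrame(np.eye(4), columns=list("abcd"))
        kept = qspr.correlation_filter(frame, r2_threshold=0.5)
        assert kept.descriptor_names == list("abcd")

    def test_planted_duplicates_leave_seven_of_ten(self):
        frame, _ = make_table(n=200, p=7, seed=4)
        for i, src in enumerate(("d1", "d2", "d3")):
            frame[f"dup{i}"] = frame[src] * (1.0 + 1e-9)
        kept = qspr.correlation_filter(frame)
        assert len(kept.descriptor_names) == 7
        surviving_pairs = kept.frame.corr().to_numpy() ** 2
        np.fill_diagonal(surviving_pairs, 0.0)
        assert surviving_pairs.max() <= 0.5


class TestKennardStone:
    def test_collinear_points_pick_extremes_first(self):
        frame = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0, 4.0]})
        plan = qspr.kennard_stone(frame, train_fraction=0.8)
        assert set(plan.train_indices[:2]) == {0, 4}
        assert len(plan.train_indices) == 4

    def test_full_fraction_empties_test_set_with_warning(self):
        frame, _ = make_table(n=6, p=2)
        with pytest.warns(UserWarning, match="empty test set"):
            plan = qspr.kennard_stone(frame, train_fraction=1.0)
        assert plan.test_indices == ()

    def test_duplicated_rows_tie_break_to_lowest_index(self):
        frame = pd.DataFrame({"x": [0.0, 2.0, 2.0, 5.0]})
        plan = qspr.kennard_stone(frame, train_fraction=0.75)
        # extremes {0,3} first; rows 1 and 2 tie -> row 1 selected
        assert plan.train_indices == (0, 3, 1)
        assert plan.test_indices == (2,)

    def test_deterministic_and_covering(self):
        frame, _ = make_table(n=40, p=3, seed=9)
        p1 = qspr.kennard_stone(frame)
        p2 = qspr.kennard_stone(frame.copy())
        assert p1 == p2
        assert sorted(p1.train_indices + p1.test_indices) == list(range(40))
        assert len(p1.train_indices) == 32

    def test_too_few_samples_rejected(self):
        with pytest.raises(DomainError):
            qspr.kennard_stone(pd.DataFrame({"x": [1.0]}))


class TestFitPredict:
    def test_exact_linear_recovery(self):
        frame, _ = make_table(n=25, p=4, seed=1)
        y = 2.0 * frame["d1"] - 0.5 * frame["d3"] + 0.25
        model = qspr.fit_mlr(frame, y, subset=("d1", "d3"))
        assert model.coefficients == pytest.approx((2.0, -0.5), abs=1e-10)
        assert model.intercept == pytest.approx(0.25, abs=1e-10)

    def test_intercept_only_signal(self):
        frame, _ = make_table(n=20, p=2, seed=2)
        y = np.full(20, 1.5) + 0.0 * frame["d1"]
        model = qspr.fit_mlr(frame, y)
        assert model.coefficients == pytest.approx((0.0, 0.0), abs=1e-12)
        assert model.intercept == pytest.approx(1.5)

    def test_matches_pseudo_inverse_oracle(self):
        frame, rng = make_table(n=30, p=3, seed=5)
        y = rng.standard_normal(30)
        model = qspr.fit_mlr(frame, y)
        design = np.column_stack([np.ones(30), frame.to_numpy()])
        beta = np.linalg.pinv(design) @ y
        assert model.intercept == pytest.approx(beta[0], abs=1e-8)
        assert model.coefficients == pytest.approx(tuple(beta[1:]), abs=1e-8)

    def test_residuals_orthogonal_to_design(self):
        frame, rng = make_table(n=30, p=3, seed=6)
        y = rng.standard_normal(30)
        model = qspr.fit_mlr(frame, y)
        resid = y - np.asarray(qspr.predict(model, frame))
        design = np.column_stack([np.ones(30), frame.to_numpy()])
        assert np.allclose(design.T @ resid, 0.0, atol=1e-8)

    def test_rank_deficiency_raises(self):
        frame, rng = make_table(n=20, p=2, seed=3)
        frame["d3"] = frame["d1"] + frame["d2"]
        with pytest.raises(FitError):
            qspr.fit_mlr(frame, rng.standard_normal(20))

    def test_predict_applies_stored_standardization(self):
        frame, rng = make_table(n=40, p=3, seed=8)
        raw = frame * 4.0 + 10.0
        table = DescriptorTable(frame=raw)
        scaled, params = qspr.standardize(table)
        y = 1.0 * scaled.frame["d1"] - 2.0
        model = qspr.fit_mlr(scaled.frame, y, standardization=params)
        via_raw = qspr.predict(model, raw, standardized=False)
        via_scaled = qspr.predict(model, scaled.frame, standardized=True)
        assert np.allclose(via_raw, via_scaled, atol=1e-10)

    def test_missing_descriptor_named(self):
        model = qspr.published_edaravone_model()
        with pytest.raises(ValidationError, match="GrAB3"):
            qspr.predict(model, {"EEtot": 0, "EEmisfit": 0, "muE": 0, "pot2inv": 0, "HBA": 0})

    def test_prediction_is_affine(self):
        model = qspr.published_edaravone_model()
        zero = {n: 0.0 for n in model.descriptor_names}
        a = {n: 1.0 for n in model.descriptor_names}
        shift = {n: 3.0 for n in model.descriptor_names}
        delta1 = qspr.predict(model, {k: a[k] + 0 for k in a}) - qspr.predict(model, zero)
        delta2 = qspr.predict(model, {k: a[k] + shift[k] for k in a}) - qspr.predict(
            model, shift
        )
        assert delta1 == pytest.approx(delta2, abs=1e-12)


class TestPublishedModel:
    def test_shape_and_coefficients(self):
        model = qspr.published_edaravone_model()
        assert model.k == 6
        coef = dict(zip(model.descriptor_names, model.coefficients))
        assert coef["muE"] == -1.2071
        assert coef["EEmisfit"] == 0.5324

    def test_zero_vector_returns_intercept(self):
        model = qspr.published_edaravone_model()
        zero = {n: 0.0 for n in model.descriptor_names}
        assert qspr.predict(model, zero) == pytest.approx(-1.1069)
        assert abs(qspr.predict(model, zero)) == pytest.approx(1.1069)

    def test_unit_perturbations_shift_by_each_coefficient(self):
        model = qspr.published_edaravone_model()
        zero = {n: 0.0 for n in model.descriptor_names}
        base = qspr.predict(model, zero)
        for name, coef in zip(model.descriptor_names, model.coefficients):
            bumped = dict(zero, **{name: 1.0})
            assert qspr.predict(model, bumped) - base == pytest.approx(coef, abs=1e-12)

    def test_external_standardization_blocks_raw_input(self):
        model = qspr.published_edaravone_model()
        with pytest.raises(DomainError):
            qspr.predict(model, {n: 0.0 for n in model.descriptor_names}, standardized=False)

    def test_json_round_trip_is_exact(self, tmp_path):
        model = qspr.published_edaravone_model()
        path = tmp_path / "model.json"
        model.to_json(path)
        assert qspr.MLRModel.from_json(path) == model


class TestMae95:
    def test_single_large_residual_trimmed(self):
        res = [0.0] * 19 + [100.0]
        assert qspr.mae95(res) == 0.0

    def test_constant_residuals(self):
        assert qspr.mae95([-0.3] * 40) == pytest.approx(0.3)

    def test_degenerate_single_residual_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert qspr.mae95([5.0]) == 0.0

    def test_ceiling_rule(self):
        # n=21 -> ceil(1.05)=2 discarded
        res = [0.1] * 19 + [10.0, 20.0]
        assert qspr.mae95(res) == pytest.approx(0.1)


class TestValidate:
    def test_perfect_predictions(self):
        frame, _ = make_table(n=20, p=2, seed=10)
        y = (3.0 * frame["d1"]).to_numpy()
        model = qspr.fit_mlr(frame, y)
        test_frame, _ = make_table(n=6, p=2, seed=11)
        y_test = (3.0 * test_frame["d1"]).to_numpy()
        report = qspr.validate(model, frame, y, test_frame, y_test)
        for value in (report.r2_adj, report.q2_loo, report.q2_f1, report.q2_f2):
            assert value == pytest.approx(1.0, abs=1e-10)
        assert report.mae95_train == pytest.approx(0.0, abs=1e-12)

    def test_q2f1_equals_q2f2_when_means_agree(self):
        frame, rng = make_table(n=24, p=2, seed=12)
        y = frame["d1"].to_numpy() + 0.1 * rng.standard_normal(24)
        model = qspr.fit_mlr(frame, y)
        test_frame = pd.DataFrame({"d1": [-1.0, 1.0], "d2": [0.3, -0.3]})
        y_test = np.array([y.mean() - 0.5, y.mean() + 0.5])  # test mean == train mean
        report = qspr.validate(model, frame, y, test_frame, y_test)
        assert report.q2_f1 == pytest.approx(report.q2_f2, abs=1e-12)

    def test_q2_loo_matches_explicit_refit_oracle(self):
        frame, rng = make_table(n=18, p=3, seed=13)
        y = frame["d1"].to_numpy() - 0.5 * frame["d3"].to_numpy() + 0.2 * rng.standard_normal(18)
        model = qspr.fit_mlr(frame, y)
        report = qspr.validate(model, frame, y)
        press = 0.0
        for i in range(18):
            keep = [j for j in range(18) if j != i]
            sub = qspr.fit_mlr(frame.iloc[keep], y[keep])
            pred_i = float(np.asarray(qspr.predict(sub, frame.iloc[[i]]))[0])
            press += (y[i] - pred_i) ** 2
        q2_oracle = 1.0 - press / float(((y - y.mean()) ** 2).sum())
        assert report.q2_loo == pytest.approx(q2_oracle, abs=1e-10)

    def test_q2f2_never_exceeds_q2f1(self):
        rng = np.random.default_rng(14)
        for seed in range(10):
            frame, _ = make_table(n=30, p=3, seed=seed)
            y = frame["d1"].to_numpy() + 0.3 * rng.standard_normal(30)
            model = qspr.fit_mlr(frame.iloc[:24], y[:24])
            report = qspr.validate(model, frame.iloc[:24], y[:24], frame.iloc[24:], y[24:])
            assert report.q2_f2 <= report.q2_f1 + 1e-12

    def test_empty_test_set_flags_external_metrics(self):
        frame, rng = make_table(n=15, p=2, seed=15)
        y = rng.standard_normal(15)
        model = qspr.fit_mlr(frame, y)
        report = qspr.validate(model, frame, y)
        assert not report.external_defined
        assert report.q2_f1 is None and report.mae95_test is None


class TestExhaustiveSearch:
    def test_planted_two_descriptor_truth_found(self):
        frame, _ = make_table(n=40, p=10, seed=16)
        y = 2.0 * frame["d3"] - 1.0 * frame["d7"]
        split = qspr.kennard_stone(frame)
        ranked = qspr.exhaustive_search(frame, y, split, k=2, top_m=3)
        best_model, best_report = ranked[0]
        assert set(best_model.descriptor_names) == {"d3", "d7"}
        assert best_report.mae95_test == pytest.approx(0.0, abs=1e-10)

    def test_k1_ranking_matches_correlation_with_response(self):
        rng = np.random.default_rng(17)
        q, _ = np.linalg.qr(rng.standard_normal((30, 4)))
        frame = pd.DataFrame(q, columns=list("abcd"))
        y = (0.9 * frame["c"] + 0.4 * frame["a"] + 0.1 * frame["d"]).to_numpy()
        split = qspr.SplitPlan(train_indices=tuple(range(30)), test_indices=())
        ranked = qspr.exhaustive_search(frame, y, split, k=1, top_m=4)
        order = [m.descriptor_names[0] for m, _ in ranked]
        corr = {n: abs(np.corrcoef(frame[n], y)[0, 1]) for n in frame.columns}
        assert order[0] == max(corr, key=corr.get) == "c"

    def test_top_m_larger_than_subsets_returns_all(self):
        frame, rng = make_table(n=20, p=3, seed=18)
        y = rng.standard_normal(20)
        split = qspr.kennard_stone(frame)
        ranked = qspr.exhaustive_search(frame, y, split, k=1, top_m=99)
        assert len(ranked) == 3

    def test_ranking_independent_of_column_order(self):
        frame, _ = make_table(n=36, p=6, seed=19)
        y = (1.5 * frame["d2"] - 0.7 * frame["d5"]).to_numpy() + 0.05 * np.random.default_rng(
            19
        ).standard_normal(36)
        split = qspr.kennard_stone(frame)
        ranked = qspr.exhaustive_search(frame, y, split, k=2, top_m=5)
        shuffled = frame[list(frame.columns[::-1])]
        ranked2 = qspr.exhaustive_search(shuffled, y, split, k=2, top_m=5)
        names1 = [tuple(sorted(m.descriptor_names)) for m, _ in ranked]
        names2 = [tuple(sorted(m.descriptor_names)) for m, _ in ranked2]
        assert names1 == names2

    def test_combination_cap_enforced(self):
        frame, rng = make_table(n=30, p=20, seed=20)
        split = qspr.kennard_stone(frame)
        with pytest.raises(DomainError, match="cap"):
            qspr.exhaustive_search(
                frame, rng.standard_normal(30), split, k=8, combination_cap=100
            )

    def test_matches_brute_force_re_enumeration(self):
        frame, rng = make_table(n=24, p=5, seed=21)
        y = frame["d1"].to_numpy() + 0.1 * rng.standard_normal(24)
        split = qspr.kennard_stone(frame)
        ranked = qspr.exhaustive_search(frame, y, split, k=2, top_m=100)
        train, test = list(split.train_indices), list(split.test_indices)
        scores = {}
        for combo in itertools.combinations(frame.columns, 2):
            m = qspr.fit_mlr(frame.iloc[train], y[train], subset=combo)
            resid = y[test] - np.asarray(qspr.predict(m, frame.iloc[test]))
            scores[combo] = qspr.mae95(resid)
        expected = sorted(scores, key=lambda c: (scores[c], c))
        assert [m.descriptor_names for m, _ in ranked] == expected


class TestPlantedRecovery:
    def test_true_subset_recovered_on_planted_tables(self):
        """Planted 6-descriptor tables (study-scale n=72, noise 0.03) are recovered.

        The 3-standard-error coefficient check is coverage, not a per-draw
        certainty (a |z| > 3 excursion occurs at the ~0.3% rate even under a
        correct model), so the fraction of in-band coefficients is asserted.
        """
        hits = 0
        z_in_band = []
        for seed in range(10):
            spec = synth.PlantedModelSpec(seed=seed)
            table = synth.gen_descriptor_dataset(spec)
            split = qspr.kennard_stone(table)
            ranked = qspr.exhaustive_search(table, table.response, split, k=6, top_m=1)
            best_model, _ = ranked[0]
            truth = {f"d{i + 1}" for i in spec.true_subset}
            if set(best_model.descriptor_names) == truth:
                hits += 1
                coef = dict(zip(best_model.descriptor_names, best_model.coefficients))
                se = dict(zip(best_model.descriptor_names, best_model.coefficient_se))
                for idx, true_c in zip(spec.true_subset, spec.true_coefficients):
                    name = f"d{idx + 1}"
                    z_in_band.append(abs(coef[name] - true_c) < 3 * se[name])
        assert hits >= 9
        assert np.mean(z_in_band) >= 0.97


class TestApplicabilityDomain:
    def test_leverages_sum_to_parameter_count(self):
        frame, rng = make_table(n=30, p=4, seed=22)
        y = rng.standard_normal(30)
        model = qspr.fit_mlr(frame, y)
        ad = qspr.applicability_domain(model, frame, y)
        assert ad.leverages.sum() == pytest.approx(model.k + 1, abs=1e-9)

    def test_intercept_only_leverages_are_uniform(self):
        frame = pd.DataFrame(index=range(12))
        y = np.arange(12, dtype=float)
        model = qspr.MLRModel(descriptor_names=(), coefficients=(), intercept=float(y.mean()))
        ad = qspr.applicability_domain(model, frame, y)
        assert np.allclose(ad.leverages, 1.0 / 12)

    def test_h_star_conventions(self):
        frame, rng = make_table(n=57, p=6, seed=23)
        y = rng.standard_normal(57)
        model = qspr.fit_mlr(frame, y)
        printed = qspr.applicability_domain(model, frame, y)
        standard = qspr.applicability_domain(model, frame, y, h_star_convention="standard")
        assert printed.h_star == pytest.approx(3 * 5 / 57)
        assert printed.h_star == pytest.approx(0.2632, abs=1e-4)
        assert standard.h_star == pytest.approx(3 * 7 / 57)

    def test_zero_noise_has_no_outliers(self):
        frame, _ = make_table(n=30, p=3, seed=24)
        y = (frame["d1"] - frame["d2"]).to_numpy()
        model = qspr.fit_mlr(frame, y)
        ad = qspr.applicability_domain(model, frame, y)
        assert ad.n_outliers == 0

    def test_outlier_definition_is_three_sigma(self):
        frame, rng = make_table(n=60, p=2, seed=25)
        y = frame["d1"].to_numpy() + 0.1 * rng.standard_normal(60)
        y[0] += 5.0  # gross outlier
        model = qspr.fit_mlr(frame, y)
        ad = qspr.applicability_domain(model, frame, y)
        assert bool(ad.outlier_flags[0])
        assert (np.abs(ad.std_residuals) > 3.0).tolist() == ad.outlier_flags.tolist()


class TestSizeScan:
    def test_planted_two_descriptor_truth_is_optimal_size(self):
        frame, _ = make_table(n=40, p=6, seed=26)
        y = (2.0 * frame["d1"] - 1.0 * frame["d4"]).to_numpy()
        split = qspr.kennard_stone(frame)
        scan = qspr.size_scan(frame, y, split, k_range=[1, 2, 3])
        assert scan.loc[2, "best_mae95_test"] == pytest.approx(0.0, abs=1e-10)
        assert scan.loc[1, "best_mae95_test"] > 1e-6

    def test_single_k_equals_exhaustive_search(self):
        frame, rng = make_table(n=30, p=4, seed=27)
        y = rng.standard_normal(30)
        split = qspr.kennard_stone(frame)
        scan = qspr.size_scan(frame, y, split, k_range=[1])
        ranked = qspr.exhaustive_search(frame, y, split, k=1, top_m=1)
        assert scan.loc[1, "best_mae95_test"] == pytest.approx(ranked[0][1].mae95_test)

    def test_train_error_non_increasing_in_k(self):
        rng = np.random.default_rng(28)
        frame, _ = make_table(n=45, p=6, seed=28)
        signal = (frame["d1"] + frame["d2"]).to_numpy()
        y = signal + 0.3 * signal.std() * rng.standard_normal(45)
        split = qspr.kennard_stone(frame)
        scan = qspr.size_scan(frame, y, split, k_range=[1, 2, 3, 4], top_m=1000)
        train_errors = scan["best_mae95_train"].to_numpy()
        assert all(a >= b - 1e-12 for a, b in zip(train_errors, train_errors[1:]))
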