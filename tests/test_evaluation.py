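"""Evaluation toolkit: biased-feature testing, disease subspace, RDA signal
loss, feature impact, marker selection, detection stage."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from fairspace import (
    DebiasModel,
    FeatureMatrix,
    RunConfig,
    SampleMetadata,
    SyntheticSpec,
    debias_fit,
    debias_transform,
    disease_subspace,
    evaluate_detection,
    feature_impact,
    generate_cohort,
    identify_biased_features,
    log_transform,
    score_samples,
    select_markers,
    select_markers_multi,
    train_detector,
    variance_explained_by_bias,
)
from fairspace.evaluation import DiseaseSubspace, _rda_adjusted_r2


def _meta(disease, group):
    return SampleMetadata(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(len(disease))],
        "disease_label": disease, "group_label": group}))


class TestIdentifyBiasedFeatures:
    def test_identical_control_groups_zero_flags(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(30, 10))
        X = FeatureMatrix([f"s{i}" for i in range(60)],
                          [f"f{j}" for j in range(10)],
                          np.vstack([base, base]))
        meta = _meta(["control"] * 60, ["maj"] * 30 + ["min"] * 30)
        rep = identify_biased_features(X, meta,
                                       RunConfig(n_permutations=199))
        assert rep.n_biased == 0

    def test_planted_shift_flagged_nulls_controlled(self):
        """One feature with d=2 among 99 nulls: the shifted feature is
        flagged; false positives stay within the BH null envelope."""
        rng = np.random.default_rng(12)
        n = 100
        X = rng.normal(size=(2 * n, 100))
        group = np.array(["maj"] * n + ["min"] * n)
        X[group == "min", 0] += 2.0
        fm = FeatureMatrix([f"s{i}" for i in range(2 * n)],
                           [f"f{j}" for j in range(100)], X)
        meta = _meta(["control"] * 2 * n, group)
        rep = identify_biased_features(fm, meta,
                                       RunConfig(n_permutations=9999, seed=1))
        assert bool(rep.table.loc[0, "biased"])
        # 99th percentile of Binomial(99, 0.05) is 10
        assert rep.table.loc[1:, "biased"].sum() <= 10

    def test_constant_feature_convention(self):
        X = np.ones((8, 2))
        X[:, 1] = np.arange(8)
        fm = FeatureMatrix([f"s{i}" for i in range(8)], ["c", "v"], X)
        meta = _meta(["control"] * 8, ["maj"] * 4 + ["min"] * 4)
        rep = identify_biased_features(fm, meta, RunConfig(n_permutations=99))
        assert rep.table.loc[0, "effect_size"] == 0.0
        assert rep.table.loc[0, "p_raw"] == 1.0


class TestDiseaseSubspace:
    def test_direction_matches_population_discriminant(self):
        """N=1 on two separated Gaussians: within 10 degrees of the
        closed-form discriminant direction Sigma^-1 (mu1 - mu0)."""
        rng = np.random.default_rng(3)
        p, n = 10, 2000
        A = rng.normal(size=(p, p)) * 0.15
        cov = A @ A.T + np.eye(p)
        mu = np.zeros(p); mu[0] = 1.5; mu[1] = -0.5
        X0 = rng.multivariate_normal(np.zeros(p), cov, n)
        X1 = rng.multivariate_normal(mu, cov, n)
        fm = FeatureMatrix([f"s{i}" for i in range(2 * n)],
                           [f"f{j}" for j in range(p)], np.vstack([X0, X1]))
        meta = _meta(["control"] * n + ["case"] * n, ["maj", "min"] * n)
        ds = disease_subspace(fm, meta, N=1)
        w = np.linalg.solve(cov, mu)
        cos = abs(ds.directions[:, 0] @ w) / np.linalg.norm(w)
        assert np.degrees(np.arccos(min(cos, 1.0))) < 10.0

    def test_orthonormal_and_deflation(self, small_cohort):
        X, meta, _ = small_cohort
        ds = disease_subspace(X, meta, N=5)
        D = ds.directions
        np.testing.assert_allclose(D.T @ D, np.eye(D.shape[1]), atol=1e-8)

    def test_rank_truncation_warns(self):
        rng = np.random.default_rng(1)
        fm = FeatureMatrix([f"s{i}" for i in range(12)],
                           [f"f{j}" for j in range(40)],
                           rng.normal(size=(12, 40)))
        meta = _meta(["control"] * 6 + ["case"] * 6, ["maj", "min"] * 6)
        with pytest.warns(UserWarning, match="truncating"):
            ds = disease_subspace(fm, meta, N=30)
        assert ds.directions.shape[1] <= 10


class TestRDASignalLoss:
    def test_disease_inside_bias_span_r2_one(self, small_cohort):
        X, meta, truth = small_cohort
        model = debias_fit(X, meta)
        model.bias_directions = truth.bias_basis
        # disease directions = a rotation of the same span
        rot, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(2, 2)))
        ds = DiseaseSubspace(truth.bias_basis @ rot, np.ones(2))
        rep = variance_explained_by_bias(ds, model, X)
        np.testing.assert_allclose(rep.adjusted_r2, 1.0, atol=1e-8)

    def test_empty_bias_subspace_zero(self, small_cohort):
        X, meta, truth = small_cohort
        model = debias_fit(X, meta, RunConfig(es_bias_prime=np.inf))
        ds = DiseaseSubspace(truth.disease_basis, np.ones(2))
        rep = variance_explained_by_bias(ds, model, X)
        np.testing.assert_array_equal(rep.adjusted_r2, 0.0)

    def test_invariant_to_reparameterization(self, small_cohort):
        X, meta, truth = small_cohort
        model = debias_fit(X, meta)
        model.bias_directions = truth.bias_basis  # rank-2 span
        ds = DiseaseSubspace(truth.disease_basis, np.ones(2))
        r1 = variance_explained_by_bias(ds, model, X).adjusted_r2
        rng = np.random.default_rng(5)
        rot, _ = np.linalg.qr(rng.normal(size=(2, 2)))
        model.bias_directions = model.bias_directions @ rot
        r2 = variance_explained_by_bias(ds, model, X).adjusted_r2
        np.testing.assert_allclose(r1, r2, atol=1e-10)

    def test_matches_vegan_rda_oracle(self, tmp_path):
        """Ezekiel-adjusted RDA R^2 agrees with the vegan R package on a
        small instance."""
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(40, 3))
        Z = rng.normal(size=(40, 2))
        Y[:, 0] += Z[:, 0] * 0.8
        ours = _rda_adjusted_r2(Y, Z)
        np.savetxt(tmp_path / "Y.tsv", Y, delimiter="\t")
        np.savetxt(tmp_path / "Z.tsv", Z, delimiter="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            Y <- as.matrix(read.table("{tmp_path}/Y.tsv"))
            Z <- as.matrix(read.table("{tmp_path}/Z.tsv"))
            cat(RsquareAdj(rda(Y ~ Z))$adj.r.squared)
        """)
        try:
            out = subprocess.run(["Rscript", "-e", script], check=True,
                                 capture_output=True, text=True, timeout=120)
        except (FileNotFoundError, subprocess.SubprocessError):
            pytest.skip("Rscript/vegan unavailable")
        assert ours == pytest.approx(float(out.stdout.strip()), abs=1e-6)


class TestFeatureImpact:
    def test_zeroed_feature_ranks_first(self):
        rng = np.random.default_rng(2)
        before = rng.normal(size=(20, 8))
        after = before.copy()
        after[:, 3] = 0.0
        fb = FeatureMatrix([f"s{i}" for i in range(20)],
                           [f"f{j}" for j in range(8)], before)
        fa = FeatureMatrix(fb.sample_ids, fb.feature_ids, after)
        meta = _meta(["control"] * 20, ["maj"] * 10 + ["min"] * 10)
        top = feature_impact(fb, fa, meta, impact_quantile=0.25)
        assert top[0] == "f3"

    def test_no_change_degenerate_flagged(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(10, 4))
        fm = FeatureMatrix([f"s{i}" for i in range(10)],
                           [f"f{j}" for j in range(4)], vals)
        meta = _meta(["control"] * 10, ["maj"] * 5 + ["min"] * 5)
        with pytest.warns(UserWarning, match="degenerate"):
            top = feature_impact(fm, fm, meta, impact_quantile=0.5)
        assert top == ["f0", "f1"]  # pure tie-break by ID

    def test_planted_axis_bias_in_impacted_set(self):
        spec = SyntheticSpec(
            n_features=40, bias_dims=1, bias_effect_sizes=(2.0,),
            disease_dims=1, disease_effect_sizes=(1.0,),
            bias_basis=np.eye(40)[:, :1], disease_basis=np.eye(40)[:, 1:2],
            n_majority_control=200, n_majority_case=50,
            n_minority_control=200, n_minority_case=50, seed=9)
        X, meta, _ = generate_cohort(spec)
        model = debias_fit(X, meta)
        adj = debias_transform(model, X)
        top = feature_impact(X, adj, meta, impact_quantile=0.25)
        assert "F00000" in top


class TestSelectMarkers:
    def test_hand_ranking(self):
        diffs = np.array([[5.0, 1.0, 3.0], [5.0, 1.0, 3.0]])
        assert select_markers(diffs, ["r1", "r2", "r3"], top_k=2) == ["r1", "r3"]

    def test_top_k_zero_and_overflow(self):
        diffs = np.array([[1.0, 2.0]])
        assert select_markers(diffs, ["a", "b"], top_k=0) == []
        with pytest.warns(UserWarning, match="returning all"):
            assert len(select_markers(diffs, ["a", "b"], top_k=5)) == 2

    def test_row_permutation_stable(self):
        rng = np.random.default_rng(0)
        diffs = rng.normal(size=(6, 20))
        ids = [f"r{j}" for j in range(20)]
        a = select_markers(diffs, ids, top_k=7)
        b = select_markers(diffs[rng.permutation(6)], ids, top_k=7)
        assert a == b

    def test_multi_type_union(self):
        d1 = pd.DataFrame([[9.0, 0.0, 0.0, 0.0]], columns=list("abcd"))
        d2 = pd.DataFrame([[0.0, 0.0, 9.0, 8.0]], columns=list("abcd"))
        got = select_markers_multi({"t1": d1, "t2": d2}, top_k=2)
        assert set(got) == {"a", "b", "c", "d"} - set()  # disjoint tops union
        assert len(got) == 4


class TestLogTransform:
    def test_known_values_and_monotone(self):
        fm = FeatureMatrix(["s"], ["a", "b", "c"],
                           np.array([[0.0, 0.001, 0.002]]))
        out = log_transform(fm)
        np.testing.assert_allclose(out.values[0, :2], [0.0, np.log(2)],
                                   atol=1e-12)
        assert out.values[0, 2] > out.values[0, 1] > out.values[0, 0]

    def test_negative_domain_error_names_cell(self):
        fm = FeatureMatrix(["s0"], ["bad"], np.array([[-0.01]]))
        with pytest.raises(ValueError, match="bad"):
            log_transform(fm)


class TestDetector:
    def _cohort(self, seed=0, n_features=60):
        spec = SyntheticSpec(
            n_features=n_features,
            n_majority_control=100, n_majority_case=100,
            n_minority_control=50, n_minority_case=10,
            bias_dims=1, bias_effect_sizes=(0.8,),
            disease_dims=2, disease_effect_sizes=(2.0, 2.0), seed=seed)
        return generate_cohort(spec), spec

    def test_separable_training_auroc_one(self):
        (X, meta, _), _ = self._cohort()
        # make it trivially separable
        vals = X.values.copy()
        vals[~meta.aligned_to(X).is_control, 0] += 100.0
        X2 = FeatureMatrix(X.sample_ids, X.feature_ids, vals)
        det = train_detector(X2, meta, X.feature_ids)
        s = score_samples(det, X2)
        rep = evaluate_detection(s, meta.aligned_to(X2),
                                 n_permutations=99)
        assert rep.overall["auroc"] == 1.0

    def test_permuted_labels_near_chance(self):
        (X, meta, _), _ = self._cohort(seed=4, n_features=40)
        rng = np.random.default_rng(0)
        t = meta.table.copy()
        t["disease_label"] = rng.permutation(t["disease_label"].to_numpy())
        meta_perm = SampleMetadata(t.reset_index(drop=True))
        det = train_detector(X, meta_perm, X.feature_ids)
        # score an independent null cohort
        (X_test, meta_test, _), _ = self._cohort(seed=5, n_features=40)
        s = score_samples(det, X_test)
        rep = evaluate_detection(s, meta_test.aligned_to(X_test),
                                 n_permutations=99)
        assert 0.35 <= rep.overall["auroc"] <= 0.65

    def test_single_class_training_rejected(self):
        (X, meta, _), _ = self._cohort()
        t = meta.table.copy()
        t["disease_label"] = "control"
        with pytest.raises(ValueError, match="both classes"):
            train_detector(X, SampleMetadata(t.reset_index(drop=True)),
                           X.feature_ids)

    def test_probability_scores_in_unit_interval(self):
        (X, meta, _), _ = self._cohort()
        det = train_detector(X, meta, X.feature_ids, probability=True)
        pr = score_samples(det, X, kind="probability")
        assert np.all((pr >= 0) & (pr <= 1))
        # margin and probability agree in rank
        from fairspace.stats import auroc
        y = (~meta.aligned_to(X).is_control).astype(int)
        assert abs(auroc(pr, y) - auroc(score_samples(det, X), y)) < 0.05


class TestEvaluateDetection:
    def test_group_without_both_classes_reported_missing(self):
        rng = np.random.default_rng(0)
        meta = _meta(["case"] * 5 + ["control"] * 5 + ["case"] * 5,
                     ["min"] * 5 + ["maj"] * 10)
        s = rng.normal(size=15)
        rep = evaluate_detection(s, meta, n_permutations=99)
        assert rep.per_group["min"]["auroc"] is None
        assert rep.per_group["maj"]["auroc"] is not None

    def test_homogeneous_groups_bracket_overall(self):
        rng = np.random.default_rng(1)
        n = 200
        y = rng.integers(0, 2, n)
        s = y * 1.0 + rng.normal(size=n)
        group = np.array(["maj", "min"])[rng.integers(0, 2, n)]
        meta = _meta(np.where(y == 1, "case", "control"), group)
        rep = evaluate_detection(s, meta, n_permutations=99)
        aurocs = [rep.per_group[g]["auroc"] for g in ("maj", "min")]
        assert min(aurocs) - 0.02 <= rep.overall["auroc"] <= max(aurocs) + 0.02

    def test_null_healthy_score_p_roughly_uniform(self):
        """Identical score distributions across groups: permutation p is
        approximately uniform over seeds."""
        rng = np.random.default_rng(2)
        ps = []
        for i in range(40):
            meta = _meta(["control"] * 40 + ["case"] * 10,
                         ["maj"] * 20 + ["min"] * 20 + ["maj"] * 10)
            s = rng.normal(size=50)
            rep = evaluate_detection(s, meta, n_permutations=199, seed=i)
            ps.append(rep.healthy_score_test["p_value"])
        ps = np.asarray(ps)
        assert 0.25 <= ps.mean() <= 0.75
        assert (ps < 0.05).mean() <= 0.2
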