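"""DLDA signature training, scoring, adaptation and auxiliary immune scores."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from immunesig import (
    ExpressionMatrix,
    adapt_signature,
    aggregate_probes,
    concordance,
    expand_probes,
    igg_score,
    probe_sum_score,
    ri_score,
    train_dlda,
    zscale,
)
from immunesig.discrimination import roc_auc
from immunesig.signature import IGG_GENES, PD1_PROBES, PDL1_PROBES, RI_QUADRANTS
from immunesig.simulate import SyntheticConfig, signature_genes, simulate_cohort


def matrix_from(values, features=None, samples=None, **kwargs):
    values = np.asarray(values, dtype=float)
    features = features or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=features, columns=samples), **kwargs
    )


def gaussian_discriminant_oracle(train_values, labels, test_values, floor=1e-6):
    """Independent check: log-likelihood ratio of per-feature Gaussians with
    pooled variance and equal priors, evaluated feature by feature."""
    labels = np.asarray(labels, dtype=bool)
    pos, neg = train_values[:, labels], train_values[:, ~labels]
    n1, n0 = pos.shape[1], neg.shape[1]
    scores = np.zeros(test_values.shape[1])
    for j in range(train_values.shape[0]):
        mu1, mu0 = pos[j].mean(), neg[j].mean()
        pooled = (
            ((pos[j] - mu1) ** 2).sum() + ((neg[j] - mu0) ** 2).sum()
        ) / (n1 + n0 - 2)
        sd = np.sqrt(max(pooled, floor))
        scores += sps.norm.logpdf(test_values[j], mu1, sd) - sps.norm.logpdf(
            test_values[j], mu0, sd
        )
    return scores


class TestTrainDLDA:
    def test_hand_computed_two_feature_model(self):
        # class means (1,1) and (-1,-1), unit pooled variance
        pos = np.array([[2.0, 0.0], [0.0, 2.0]])
        neg = np.array([[-2.0, 0.0], [0.0, -2.0]])
        X = matrix_from(np.hstack([pos, neg]))
        model = train_dlda(X, [1, 1, 0, 0])
        # pooled variance = (2+2)/(4-2) = 2 per feature -> w = 2/2 = 1
        assert np.allclose(model.weights, [1.0, 1.0])
        assert np.allclose(model.midpoints, [0.0, 0.0])
        scores = model.score(matrix_from([[1.0], [1.0]]))
        assert np.isclose(scores.is_score.iloc[0], 2.0)
        assert scores.group.iloc[0] == "Gp-R"

    def test_unit_variance_example(self):
        # construct exact class means (1,1)/(-1,-1) with pooled variance 1
        d = np.sqrt(0.5)
        pos = np.array([[1 + d, 1 - d], [1 + d, 1 - d]])
        neg = np.array([[-1 + d, -1 - d], [-1 + d, -1 - d]])
        model = train_dlda(matrix_from(np.hstack([pos, neg])), [1, 1, 0, 0])
        assert np.allclose(model.weights, [2.0, 2.0])
        assert np.allclose(model.midpoints, [0.0, 0.0])
        scored = model.score(matrix_from([[1.0], [1.0]]))
        assert np.isclose(scored.is_score.iloc[0], 4.0)

    def test_single_class_labels_rejected(self):
        X = matrix_from(np.random.default_rng(0).normal(size=(3, 6)))
        with pytest.raises(ValueError, match="each class"):
            train_dlda(X, [1] * 6)

    def test_midpoint_vector_scores_zero_and_is_gp_nr(self):
        rng = np.random.default_rng(2)
        X = matrix_from(rng.normal(size=(4, 20)))
        model = train_dlda(X, rng.random(20) < 0.5)
        mid = matrix_from(model.midpoints[:, None], features=model.features)
        scored = model.score(mid)
        assert abs(scored.is_score.iloc[0]) < 1e-12
        assert scored.group.iloc[0] == "Gp-NR"  # IS <= 0 rule

    def test_matches_gaussian_discriminant_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_feat = rng.integers(2, 8)
            n_train = rng.integers(8, 30)
            n_test = rng.integers(1, 10)
            train = rng.normal(size=(n_feat, n_train)) * rng.uniform(0.5, 2)
            labels = np.zeros(n_train, dtype=bool)
            labels[: n_train // 2 + 1] = True
            rng.shuffle(labels)
            if labels.sum() < 2 or (~labels).sum() < 2:
                continue
            test = rng.normal(size=(n_feat, n_test))
            model = train_dlda(matrix_from(train), labels)
            scored = model.score(matrix_from(test))
            oracle = gaussian_discriminant_oracle(train, labels, test)
            assert np.abs(scored.is_score.to_numpy() - oracle).max() < 1e-9

    def test_shift_and_rescale_equivariance(self):
        rng = np.random.default_rng(7)
        train = rng.normal(size=(5, 30))
        labels = rng.random(30) < 0.5
        test = rng.normal(size=(5, 10))
        base = train_dlda(matrix_from(train), labels).score(matrix_from(test))
        shifted = train_dlda(matrix_from(train + 3.0), labels).score(
            matrix_from(test + 3.0)
        )
        assert np.allclose(base.is_score, shifted.is_score, atol=1e-9)
        scale = rng.uniform(0.5, 4.0, size=(5, 1))
        rescaled = train_dlda(matrix_from(train * scale), labels).score(
            matrix_from(test * scale)
        )
        assert np.allclose(base.is_score, rescaled.is_score, atol=1e-9)

    def test_group_fractions_partition_every_cohort(self, small_cohort, ref_model):
        _, matrix, _, _ = small_cohort
        scores = ref_model.score(matrix)
        frac_r = (scores.group == "Gp-R").mean()
        frac_nr = (scores.group == "Gp-NR").mean()
        assert frac_r + frac_nr == 1.0


class TestAdaptation:
    def test_refit_on_full_feature_set_is_unchanged(self, ref_model):
        from immunesig.reference import reference_training_cohort

        train_X, labels, _, _ = reference_training_cohort()
        refit = adapt_signature(ref_model, ref_model.features, train_X, labels)
        assert np.allclose(refit.weights, ref_model.weights)

    def test_nineteen_gene_model_adapts_to_sixteen(self, ref_model):
        from immunesig.reference import reference_training_cohort

        train_X, labels, _, _ = reference_training_cohort()
        available = ref_model.features[:-3]  # platform supports 16 of 19
        refit = adapt_signature(ref_model, available, train_X, labels)
        assert len(refit.features) == 16
        assert refit.metadata["dropped_features"] == ref_model.features[-3:]

    def test_too_few_shared_features_rejected(self, ref_model):
        from immunesig.reference import reference_training_cohort

        train_X, labels, _, _ = reference_training_cohort()
        with pytest.raises(ValueError, match="16"):
            adapt_signature(ref_model, ref_model.features[:10], train_X, labels)

    def test_missing_features_at_scoring_time_named(self, ref_model, small_cohort):
        _, matrix, _, _ = small_cohort
        reduced = matrix.replace(data=matrix.data.drop(index=ref_model.features[0]))
        with pytest.raises(KeyError, match=ref_model.features[0]):
            ref_model.score(reduced)


class TestConcordance:
    def test_identical_and_negated_scores(self, small_cohort, ref_model):
        _, matrix, _, _ = small_cohort
        scores = ref_model.score(matrix)
        r, disc = concordance(scores, scores)
        assert r == pytest.approx(1.0)
        assert disc == 0
        negated = dataclasses.replace(
            scores, data=scores.data.assign(is_score=-scores.data["is_score"])
        )
        r_neg, _ = concordance(scores, negated)
        assert r_neg == pytest.approx(-1.0)

    def test_probe_vs_gene_scoring_highly_concordant(self, ref_model):
        # mirrors the published probe/gene concordance check (r = 0.99)
        config = SyntheticConfig(n_samples=400, n_datasets=1, seed=23)
        matrix, _, _ = simulate_cohort(config)
        probes, pmap = expand_probes(matrix, 2, seed=5, offset_sd=0.2, noise_sd=0.1)
        gene_again = aggregate_probes(probes, pmap)
        direct = ref_model.score(matrix)
        via_probes = ref_model.score(gene_again)
        r, disc = concordance(direct, via_probes)
        assert r >= 0.95
        assert disc / len(direct) <= 0.05


class TestAuxiliaryScores:
    def zmatrix(self, values, features):
        m = matrix_from(values, features=features)
        return m.replace(zscaled=True, centered=True)

    def test_igg_score_sums_eleven_genes(self):
        assert len(IGG_GENES) == 11
        zeros = self.zmatrix(np.zeros((11, 3)), list(IGG_GENES))
        assert np.allclose(igg_score(zeros), 0.0)
        ones = self.zmatrix(np.ones((11, 2)), list(IGG_GENES))
        assert np.allclose(igg_score(ones), 11.0)

    def test_igg_requires_zscaled_input_and_some_genes(self):
        raw = matrix_from(np.zeros((11, 2)), features=list(IGG_GENES))
        with pytest.raises(ValueError, match="z-scaled"):
            igg_score(raw)
        other = self.zmatrix(np.zeros((2, 2)), ["X1", "X2"])
        with pytest.raises(ValueError, match="none"):
            igg_score(other)

    def test_pd1_single_probe_is_identity(self):
        z = self.zmatrix([[0.3, -0.7]], list(PD1_PROBES))
        assert np.allclose(probe_sum_score(z, PD1_PROBES), [0.3, -0.7])

    def test_pdl1_two_probe_sum_and_degradation(self):
        z = self.zmatrix([[0.5, 1.0], [0.5, -1.0]], list(PDL1_PROBES))
        assert np.allclose(probe_sum_score(z, PDL1_PROBES), [1.0, 0.0])
        partial = self.zmatrix([[0.5, 1.0]], [PDL1_PROBES[0]])
        with pytest.warns(UserWarning, match="absent"):
            result = probe_sum_score(partial, PDL1_PROBES)
        assert np.allclose(result, [0.5, 1.0])


class TestRIScore:
    def test_sum_and_quadrant(self):
        out = ri_score(pd.Series({"a": 30.0}), pd.Series({"a": 10.0}))
        assert out.loc["a", "ri"] == 40.0
        assert out.loc["a", "quadrant"] == "IS>-25 & RS>25"

    def test_boundary_is_strict(self):
        out = ri_score(pd.Series({"a": 25.0}), pd.Series({"a": -25.0}))
        assert out.loc["a", "quadrant"] == "IS<=-25 & RS<=25"

    def test_quadrants_partition_all_samples(self):
        rng = np.random.default_rng(3)
        n = 200
        ids = [f"s{i}" for i in range(n)]
        rs = pd.Series(rng.uniform(0, 60, n), index=ids)
        is_ = pd.Series(rng.uniform(-60, 40, n), index=ids)
        out = ri_score(rs, is_)
        assert len(out) == n
        assert set(out["quadrant"]).issubset(set(RI_QUADRANTS))

    def test_missing_inputs_excluded(self):
        rs = pd.Series({"a": 30.0, "b": np.nan})
        is_ = pd.Series({"a": 1.0, "b": 2.0})
        assert list(ri_score(rs, is_).index) == ["a"]


class TestDiscriminationOfIS:
    def test_is_beats_every_single_signature_gene(self, ref_model):
        """The multivariate immune score discriminates pCR better than any
        one signature gene in >=90% of simulated cohorts."""
        wins = 0
        reps = 50
        for rep in range(reps):
            config = SyntheticConfig(n_samples=2000, n_datasets=1, seed=600 + rep)
            matrix, clinical, _ = simulate_cohort(config)
            outcome = clinical.data["pcr"].to_numpy(dtype=bool)
            scores = ref_model.score(matrix)
            auc_is = roc_auc(scores.is_score.to_numpy(), outcome).auc
            best_gene = max(
                roc_auc(matrix.data.loc[g].to_numpy(), outcome).auc
                for g in signature_genes()
            )
            wins += auc_is > best_gene
        assert wins >= 0.9 * reps
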