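import numpy as np
import pytest
from scipy import stats

from triomics.matrixio import ExpressionMatrix
from triomics.multivariate import MultivariateFit
from triomics.scores import (
    compute_scores,
    cluster_patients,
    cluster_vs_clinical,
    predict_protein,
    screen_zscore,
    screen_consistency,
)
from triomics.synthetic import SimulationConfig, simulate_cohort, random_support
from triomics.preprocess import log_transform
from tests.conftest import make_cohort, cohort_logs
from tests.helpers import adjusted_rand
from tests.test_interactome import make_assoc


def mk_fit(protein_id, betas, alpha=0.0, gamma=0.0):
    return MultivariateFit(
        protein_id, alpha, gamma, dict(betas), 0.1, 5, 0, sorted(betas)
    )


def mirna_matrix(values, prefix="m"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"{prefix}{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        "miRNA",
    )


class TestComputeScores:
    def test_single_coefficient_copies_row(self, rng):
        logM = mirna_matrix(rng.normal(size=(3, 8)))
        scores = compute_scores([mk_fit("p0", {"m1": 1.0})], logM)
        np.testing.assert_allclose(scores.values[0], logM.values[1], atol=1e-15)

    def test_cancellation(self):
        logM = mirna_matrix(np.vstack([np.arange(5.0), np.arange(5.0)]))
        scores = compute_scores([mk_fit("p0", {"m0": 1.0, "m1": -1.0})], logM)
        np.testing.assert_allclose(scores.values[0], 0.0, atol=1e-15)

    def test_matches_double_loop_oracle(self, rng):
        logM = mirna_matrix(rng.normal(size=(6, 10)))
        fits = [
            mk_fit(f"p{i}", {f"m{j}": rng.normal() for j in rng.choice(6, 3, replace=False)})
            for i in range(4)
        ]
        scores = compute_scores(fits, logM)
        for i, fit in enumerate(fits):
            for p in range(10):
                expected = sum(
                    b * logM.values[logM.feature_ids.index(m), p]
                    for m, b in fit.beta_hats.items()
                )
                assert scores.values[i, p] == pytest.approx(expected, abs=1e-12)

    def test_empty_fit_gives_zero_row(self, rng):
        logM = mirna_matrix(rng.normal(size=(2, 5)))
        scores = compute_scores([mk_fit("p0", {})], logM)
        np.testing.assert_array_equal(scores.values[0], 0.0)

    def test_missing_mirna_raises(self, rng):
        logM = mirna_matrix(rng.normal(size=(2, 5)))
        with pytest.raises(KeyError, match="ghost"):
            compute_scores([mk_fit("p0", {"ghost": 1.0})], logM)

    def test_linearity(self, rng):
        logM = mirna_matrix(rng.normal(size=(5, 7)))
        b1 = {"m0": 0.5, "m2": -1.0}
        b2 = {"m2": 0.3, "m4": 0.9}
        combined = {"m0": 0.5, "m2": -0.7, "m4": 0.9}
        s1 = compute_scores([mk_fit("p", b1)], logM).values
        s2 = compute_scores([mk_fit("p", b2)], logM).values
        s12 = compute_scores([mk_fit("p", combined)], logM).values
        np.testing.assert_allclose(s12, s1 + s2, atol=1e-10)


class TestClusterPatients:
    def test_two_orthogonal_profiles(self):
        a = np.array([1.0, 0.0, 2.0, -1.0])
        b = np.array([-3.0, 5.0, 0.5, 2.0])
        values = np.column_stack([a, a + 0.01, b, b - 0.01])
        from triomics.scores import PatientScoreMatrix

        scores = PatientScoreMatrix(values, [f"p{i}" for i in range(4)],
                                    ["s0", "s1", "s2", "s3"])
        _, labels = cluster_patients(scores, 2)
        assert labels["s0"] == labels["s1"]
        assert labels["s2"] == labels["s3"]
        assert labels["s0"] != labels["s2"]

    def test_single_patient_rejected(self):
        from triomics.scores import PatientScoreMatrix

        scores = PatientScoreMatrix(np.ones((2, 1)), ["p0", "p1"], ["s0"])
        with pytest.raises(ValueError):
            cluster_patients(scores, 2)

    def test_subtype_recovery_over_replicates(self):
        aris = []
        for rep in range(20):
            rng = np.random.default_rng(500 + rep)
            support = random_support(rng, 10, 30, 3, (0.8, 1.2))
            config = SimulationConfig(
                n_samples=80, n_proteins=10, n_mirnas=30, support=support,
                gamma=1.0, noise_sd=0.1, n_subtypes=2,
                subtype_shift=[0.0, 2.5], seed=900 + rep,
            )
            mirna, _, _, truth = simulate_cohort(config)
            logM = log_transform(mirna)
            fits = [
                mk_fit(f"p{i}", {
                    logM.feature_ids[j]: truth.beta[i, j]
                    for j in np.nonzero(truth.beta[i])[0]
                })
                for i in range(10)
            ]
            scores = compute_scores(fits, logM)
            _, labels = cluster_patients(scores, 2)
            got = np.array([labels[s] for s in scores.sample_ids])
            aris.append(adjusted_rand(truth.subtype_labels, got))
        assert np.mean(aris) >= 0.8


class TestClusterVsClinical:
    def test_perfect_association(self):
        labels = {f"s{i}": i % 2 for i in range(40)}
        clinical = {f"s{i}": "A" if i % 2 == 0 else "B" for i in range(40)}
        result = cluster_vs_clinical(labels, clinical)
        assert result.p_value < 0.001

    def test_flat_table_p_one(self):
        labels, clinical = {}, {}
        i = 0
        for c in (0, 1):
            for v in ("A", "B"):
                for _ in range(10):
                    labels[f"s{i}"] = c
                    clinical[f"s{i}"] = v
                    i += 1
        result = cluster_vs_clinical(labels, clinical)
        assert result.p_value == pytest.approx(1.0)

    def test_single_category_rejected(self):
        labels = {f"s{i}": i % 2 for i in range(10)}
        clinical = {f"s{i}": "A" for i in range(10)}
        with pytest.raises(ValueError):
            cluster_vs_clinical(labels, clinical)

    def test_exact_fallback_for_sparse_2x2(self):
        labels = {f"s{i}": i % 2 for i in range(8)}
        clinical = {f"s{i}": "A" if i < 4 else "B" for i in range(8)}
        result = cluster_vs_clinical(labels, clinical)
        assert result.test == "fisher-exact"

    def test_null_pvalues_roughly_uniform(self):
        pvals = []
        for rep in range(200):
            rng = np.random.default_rng(3000 + rep)
            labels = {f"s{i}": int(rng.integers(2)) for i in range(200)}
            clinical = {f"s{i}": "AB"[rng.integers(2)] for i in range(200)}
            try:
                pvals.append(cluster_vs_clinical(labels, clinical).p_value)
            except ValueError:
                pass
        ks = stats.kstest(pvals, "uniform")
        # chi-square p-values are discrete-ish but close to uniform under the null
        assert ks.pvalue > 1e-4


class TestPredictProtein:
    def _fitted(self, noise_sd, seed, n=200):
        rng = np.random.default_rng(seed)
        support = random_support(rng, 6, 25, 3, (0.7, 1.0))
        config = SimulationConfig(
            n_samples=n, n_proteins=6, n_mirnas=25, support=support,
            gamma=1.0, noise_sd=noise_sd, seed=seed,
        )
        cohort_a = simulate_cohort(config)
        config_b = SimulationConfig(**{**config.__dict__, "seed": seed + 1})
        cohort_b = simulate_cohort(config_b)
        return cohort_a, cohort_b

    def test_self_prediction_exact_without_noise(self):
        mirna, mrna, protein, truth = make_cohort(
            n_samples=50, n_proteins=2, n_mirnas=6,
            support=[[(0, -1.0), (3, 0.5)], []], gamma=1.0, noise_sd=0.0,
        )
        logP, logE, logM, _ = cohort_logs(mirna, mrna, protein)
        fit = mk_fit(
            "prot_000",
            {logM.feature_ids[0]: -1.0, logM.feature_ids[3]: 0.5},
            alpha=0.0, gamma=1.0,
        )
        pred, result = predict_protein(fit, logE.values[0], logM, logP.values[0])
        np.testing.assert_allclose(pred, logP.values[0], atol=1e-8)
        assert result.r == pytest.approx(1.0, abs=1e-9)

    def test_empty_support_reduces_to_mrna(self, rng):
        logE = rng.normal(size=40)
        logP_obs = 2.0 * logE + rng.normal(0, 0.3, 40)
        logM = mirna_matrix(rng.normal(size=(3, 40)))
        fit = mk_fit("p", {}, alpha=0.5, gamma=1.0)
        pred, result = predict_protein(fit, logE, logM, logP_obs)
        np.testing.assert_allclose(pred, 0.5 + logE, atol=1e-12)
        expected_r, _ = stats.pearsonr(logE, logP_obs)
        assert result.r == pytest.approx(expected_r, abs=1e-12)

    def test_missing_mirnas_dropped_and_counted(self, rng):
        logM = mirna_matrix(rng.normal(size=(2, 10)))
        fit = mk_fit("p", {"m0": 1.0, "ghost": 2.0}, gamma=0.0)
        pred, result = predict_protein(fit, np.zeros(10), logM, rng.normal(size=10))
        assert result.n_mirnas_used == 1
        assert result.n_mirnas_missing == 1
        np.testing.assert_allclose(pred, logM.values[0], atol=1e-12)

    def test_degenerate_flagged(self, rng):
        logM = mirna_matrix(rng.normal(size=(1, 10)))
        fit = mk_fit("p", {"ghost": 1.0}, gamma=0.0)
        _, result = predict_protein(fit, np.zeros(10), logM, rng.normal(size=10))
        assert result.degenerate

    def test_transfer_r_monotone_in_noise(self):
        from triomics.univariate import fit_all_pairs
        from triomics.multivariate import fit_all_multivariate

        medians = []
        for noise_sd in (0.5, 0.25, 0.1):
            cohort_a, cohort_b = self._fitted(noise_sd, seed=60, n=150)
            logP, logE, logM, gm = cohort_logs(*cohort_a[:3])
            table = fit_all_pairs(logP, logE, logM, gm)
            fits = fit_all_multivariate(
                logP, logE, logM, gm, table, cv_folds=5, cv_seed=0
            )
            logPb, logEb, logMb, _ = cohort_logs(*cohort_b[:3])
            rs = []
            for i, fit in enumerate(fits):
                if not fit.beta_hats:
                    continue
                _, result = predict_protein(
                    fit, logEb.values[i], logMb, logPb.values[i]
                )
                rs.append(result.r)
            medians.append(float(np.median(rs)))
        assert medians[0] < medians[1] < medians[2]


class TestScreen:
    def test_zscore_known_values(self, rng):
        raw = rng.normal(5.0, 2.0, size=(1, 50))
        raw[0, 0] = raw[0, 1:].mean()  # close to screen mean
        z = screen_zscore(mirna_matrix(raw, prefix="pert"))
        np.testing.assert_allclose(z.values.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.values.std(axis=1), 1.0, atol=1e-12)

    def test_two_sd_value(self):
        base = np.array([[0.0, 1.0, -1.0, 2.0, -2.0]])
        mean, sd = base.mean(), base.std()
        z = screen_zscore(mirna_matrix(base, prefix="pert"))
        idx = 3  # value 2.0
        assert z.values[0, idx] == pytest.approx((2.0 - mean) / sd)
        spike = np.zeros((1, 41))
        spike[0, 0] = 1.0  # one perturbation stands out
        zs = screen_zscore(mirna_matrix(spike, prefix="pert"))
        assert zs.significant_mask()[0, 0]

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="zero screen SD"):
            screen_zscore(mirna_matrix(np.ones((1, 5)), prefix="pert"))

    def test_too_few_perturbations(self):
        with pytest.raises(ValueError, match="three"):
            screen_zscore(mirna_matrix(np.array([[1.0, 2.0]]), prefix="pert"))

    def test_consistency_rules(self):
        assoc = make_assoc(
            [[0.5, 0.7, -0.4]],
            significant=np.array([[True, True, True]]),
        )
        from triomics.scores import ScreenZScores

        z = ScreenZScores(
            np.array([[2.5, -2.5, 1.5]]), ["p0"], ["m0", "m1", "m2"], 1.96
        )
        validated = screen_consistency(assoc, z)
        assert ("m0", "p0") in validated        # sign consistent, above threshold
        assert ("m1", "p0") not in validated    # inconsistent sign
        assert ("m2", "p0") not in validated    # below threshold

    def test_consistency_negative_direction(self):
        assoc = make_assoc([[-0.5]], significant=np.array([[True]]))
        from triomics.scores import ScreenZScores

        z = ScreenZScores(np.array([[-3.0]]), ["p0"], ["m0"], 1.96)
        assert screen_consistency(assoc, z) == [("m0", "p0")]
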