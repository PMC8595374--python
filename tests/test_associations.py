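"""MANCOVA joint tests, post-hoc regressions, multinomial cluster models."""

import numpy as np
import pandas as pd
import pytest

from trajmorbid.associations import (association_table, cluster_association,
                                     mancova, posthoc_regressions,
                                     replication_harness)


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(123)


@pytest.fixture(scope="module")
def null_setup(rng):
    scores = rng.normal(size=(500, 3))
    covs = {"age": rng.normal(30, 3, 500),
            "sex": rng.integers(0, 2, 500).astype(float)}
    return scores, covs


class TestMancova:
    def test_matches_statsmodels_pillai(self, null_setup, rng):
        from statsmodels.multivariate.manova import MANOVA

        scores, covs = null_setup
        pred = 0.2 * scores[:, 0] + rng.normal(size=500)
        res = mancova(scores, pred, covs)
        Xm = np.column_stack([np.ones(500), pred, covs["age"], covs["sex"]])
        L = np.zeros((1, 4))
        L[0, 1] = 1.0
        row = MANOVA(scores, Xm).mv_test(
            hypotheses=[("p", L, None)]).results["p"]["stat"].loc[
            "Pillai's trace"]
        assert res.joint_F == pytest.approx(float(row["F Value"]), rel=1e-9)
        assert res.joint_p == pytest.approx(float(row["Pr > F"]), rel=1e-9)

    def test_null_type_one_error_calibrated(self, null_setup, rng):
        scores, covs = null_setup
        hits = sum(mancova(scores, rng.normal(size=500), covs).joint_p < 0.05
                   for _ in range(400))
        assert 0.025 <= hits / 400 <= 0.075

    def test_perfect_association(self, null_setup):
        scores, covs = null_setup
        res = mancova(scores, scores[:, 0], covs)
        assert res.joint_p == 0.0 and res.joint_F == np.inf

    def test_constant_predictor_rejected(self, null_setup):
        scores, covs = null_setup
        with pytest.raises(ValueError, match="constant predictor"):
            mancova(scores, np.ones(500), covs)

    def test_collinear_covariate_named(self, null_setup, rng):
        scores, _ = null_setup
        pred = rng.normal(size=500)
        with pytest.raises(ValueError, match="collinear"):
            mancova(scores, pred, {"twice": 2 * pred})

    def test_listwise_deletion_reported(self, null_setup, rng):
        scores, covs = null_setup
        pred = rng.normal(size=500)
        pred[:50] = np.nan
        res = mancova(scores, pred, covs)
        assert res.n_nonmissing == 450


class TestPosthoc:
    def test_inverse_regression_limit(self, rng):
        # MDS scores have exactly orthogonal columns; emulate that so the
        # off-dimension betas vanish identically as sigma -> 0
        raw = rng.normal(size=(800, 3))
        q, _ = np.linalg.qr(raw - raw.mean(0))
        z = q / q.std(0)
        pred = 2 * z[:, 0] + rng.normal(scale=1e-8, size=800)
        betas, ps = posthoc_regressions(z, pred)
        assert betas[0] == pytest.approx(0.5, abs=1e-6)
        assert abs(betas[1]) < 1e-6 and abs(betas[2]) < 1e-6

    def test_null_pvalues_uniform(self, rng):
        from scipy import stats

        scores = rng.normal(size=(300, 1))
        ps = [posthoc_regressions(scores, rng.normal(size=300))[1][0]
              for _ in range(400)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestClusterAssociation:
    def test_reduces_to_contingency_odds_ratio(self, rng):
        labels = rng.integers(1, 3, 600)
        x = (rng.random(600) < np.where(labels == 2, 0.7, 0.4)).astype(float)
        res = cluster_association(labels, x, reference=1)
        a = np.sum((labels == 2) & (x == 1))
        b = np.sum((labels == 2) & (x == 0))
        c = np.sum((labels == 1) & (x == 1))
        d = np.sum((labels == 1) & (x == 0))
        assert res.odds_ratios[2] == pytest.approx(a * d / (b * c), rel=1e-4)

    def test_null_or_near_one(self, rng):
        labels = rng.integers(1, 4, 900)
        covered = 0
        for _ in range(20):
            res = cluster_association(labels, rng.normal(size=900),
                                      reference=1)
            covered += all(p > 0.05 or 0.7 < orr < 1.4
                           for orr, p in zip(res.odds_ratios.values(),
                                             res.p_values.values()))
        assert covered >= 18

    def test_separating_predictor_flagged(self, rng):
        labels = np.repeat([1, 2], 50)
        x = (labels == 2).astype(float)  # perfect separation
        try:
            res = cluster_association(labels, x, reference=1)
            assert res.flagged
        except ValueError:
            pass  # hard failure is also an acceptable flag

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="two clusters"):
            cluster_association(np.ones(50), np.zeros(50))


class TestAssociationTable:
    def test_posthoc_only_when_joint_significant(self, rng):
        scores = rng.normal(size=(400, 3))
        variables = pd.DataFrame({
            "planted": scores[:, 0] * 0.8 + rng.normal(size=400),
            "noise": rng.normal(size=400),
        })
        tab = association_table(scores, variables, threshold=0.002)
        planted = tab[tab.variable == "planted"].iloc[0]
        noise = tab[tab.variable == "noise"].iloc[0]
        assert planted.p < 0.002 and np.isfinite(planted.beta1)
        assert np.isnan(noise.beta1)


class TestReplicationHarness:
    def test_copy_of_primary_reproduces_scores(self, alphabet, small_cases):
        from trajmorbid.dissimilarity import (CostModel, estimate_transitions,
                                              pairwise_matrix)
        from trajmorbid.embedding import classical_mds
        from trajmorbid.sequences import build_sequences

        cases = small_cases[:40]
        # fully observed sequences: self-distance is exactly 0, so the
        # projection of a duplicated cohort is exact (censored tails carry
        # a positive expected self-cost, making it approximate there)
        seqs = build_sequences(cases, alphabet, target_length=14)
        tmod = estimate_transitions(seqs, alphabet)
        cm = CostModel()
        D = pairwise_matrix(seqs, cm, tmod)
        emb = classical_mds(D.values, 3)
        rng = np.random.default_rng(0)
        variables = pd.DataFrame({"v": rng.normal(size=len(cases))})
        out = replication_harness(emb.scores, emb, seqs, seqs, cm, tmod,
                                  variables, variables)
        assert np.allclose(out["replication_scores"], emb.scores, atol=1e-6)

    def test_empty_replication_rejected(self, alphabet, small_cases):
        from trajmorbid.dissimilarity import (CostModel, estimate_transitions,
                                              pairwise_matrix)
        from trajmorbid.embedding import classical_mds
        from trajmorbid.sequences import build_sequences

        seqs = build_sequences(small_cases[:20], alphabet)
        tmod = estimate_transitions(seqs, alphabet)
        D = pairwise_matrix(seqs, CostModel(), tmod)
        emb = classical_mds(D.values, 2)
        with pytest.raises(ValueError, match="empty replication"):
            replication_harness(emb.scores, emb, [], seqs, CostModel(), tmod,
                                pd.DataFrame(), pd.DataFrame())
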