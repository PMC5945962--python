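"""Staging, stage distributions, bootstrap PVD, and validation analyses."""

import numpy as np
import pandas as pd
import pytest

from hdebm import (BiomarkerMatrix, EventDistributionFit, GaussianParams,
                   StageAssignments, bootstrap_pvd, longitudinal_consistency,
                   phenotype_regression, predict_conversion,
                   stage_distribution, stage_subject, stage_subjects)

from conftest import matrix_from_groups, planted_table


def unit_fits(z, shift=-4.0):
    return {f"bm{i}": EventDistributionFit(GaussianParams(0.0, 1.0),
                                           GaussianParams(shift, 1.0),
                                           0.5, True, 1)
            for i in range(z)}


def assignments_from(stages, visits=None, subject_ids=None):
    n = len(stages)
    frame = pd.DataFrame({
        "subject_id": subject_ids if subject_ids is not None
        else [f"s{j}" for j in range(n)],
        "visit_months": visits if visits is not None else 0,
        "stage": stages,
    })
    return StageAssignments(frame, np.zeros((n, max(stages) + 2)))


class TestStageSubjects:
    def test_all_normal_values_stage_zero(self):
        z = 5
        assert stage_subject(np.zeros(z), np.arange(z), unit_fits(z)) == 0

    def test_all_abnormal_values_stage_z(self):
        z = 5
        assert stage_subject(np.full(z, -4.0), np.arange(z), unit_fits(z)) == z

    def test_ties_resolve_to_smallest_stage(self):
        # identical components: every stage equally likely -> stage 0
        z = 3
        fits = {f"bm{i}": EventDistributionFit(GaussianParams(0, 1),
                                               GaussianParams(0, 1),
                                               0.5, True, 1) for i in range(z)}
        assert stage_subject(np.zeros(z), np.arange(z), fits) == 0

    def test_missing_value_rejected(self):
        z = 3
        with pytest.raises(ValueError, match="complete"):
            stage_subject([0.0, np.nan, 0.0], np.arange(z), unit_fits(z))

    def test_planted_stage_recovery(self):
        """3-SD separation: >= 95% of subjects staged within +-1 of truth."""
        rng = np.random.default_rng(0)
        table, seq, stages = planted_table(10, 100, rng, shift=3.0)
        got = stage_subjects(table, seq).table["stage"].to_numpy()
        assert np.mean(np.abs(got - stages) <= 1) >= 0.95

    def test_frontier_monotonicity(self):
        """Making the frontier biomarker more abnormal never lowers the stage."""
        z = 5
        fits = unit_fits(z)
        seq = np.arange(z)
        x = np.array([-4.0, -4.0, -1.0, 0.0, 0.0])  # frontier at position 3
        base_stage = stage_subject(x, seq, fits)
        for delta in (0.5, 1.0, 2.0, 3.0):
            x2 = x.copy()
            x2[2] -= delta
            assert stage_subject(x2, seq, fits) >= base_stage


class TestStageDistribution:
    def test_single_group_all_stage_zero(self):
        a = assignments_from([0, 0, 0, 0])
        groups = pd.Series("HC", index=a.table["subject_id"])
        dist = stage_distribution(a, groups, n_stages=4)
        expect = np.zeros(5)
        expect[0] = 1.0
        assert np.allclose(dist.loc["HC", [f"stage_{k}" for k in range(5)]], expect)

    def test_proportions_sum_to_one_per_group(self):
        rng = np.random.default_rng(1)
        stages = rng.integers(0, 7, 60).tolist()
        a = assignments_from(stages)
        groups = pd.Series(rng.choice(["HC", "preHD", "HD"], 60),
                           index=a.table["subject_id"])
        dist = stage_distribution(a, groups, n_stages=6)
        stage_cols = [f"stage_{k}" for k in range(7)]
        assert np.allclose(dist[stage_cols].sum(axis=1), 1.0)
        assert np.allclose(dist["lower_half"] + dist["upper_half"], 1.0)

    def test_early_planted_group_occupies_lower_half(self):
        """A premanifest-A-like group planted at early stages lands mostly in
        the lower half of the staging range."""
        rng = np.random.default_rng(2)
        table, seq, stages = planted_table(10, 30, rng, shift=3.0)
        early = stages <= 4
        got = stage_subjects(table, seq)
        groups = pd.Series(np.where(early, "preHD_A", "preHD_B"),
                           index=got.table["subject_id"])
        dist = stage_distribution(got, groups, n_stages=10)
        assert dist.loc["preHD_A", "lower_half"] >= 0.7

    def test_unknown_group_rejected(self):
        a = assignments_from([0, 1])
        groups = pd.Series(["HC"], index=["s0"])  # s1 missing
        with pytest.raises(ValueError, match="no group label"):
            stage_distribution(a, groups, n_stages=2)


class TestBootstrapPVD:
    @staticmethod
    def _staged_matrix(z=4, n_per_stage=10, seed=3, noise=0.05):
        """Controls at stage 0 and patients spread over stages 1..z with the
        identity ordering planted: ordering is unambiguous at low noise."""
        rng = np.random.default_rng(seed)
        hc = rng.standard_normal((n_per_stage * z, z)) * noise
        stages = np.repeat(np.arange(1, z + 1), n_per_stage)
        hd = rng.standard_normal((len(stages), z)) * noise
        hd -= 8.0 * (np.arange(1, z + 1)[None, :] <= stages[:, None])
        return matrix_from_groups(hc, hd)

    def _separated_matrix(self):
        return self._staged_matrix()

    def test_perfectly_separated_data_gives_permutation_matrix(self):
        matrix = self._separated_matrix()
        pvd = bootstrap_pvd(matrix, n_bootstrap=5, seed=0, n_restarts=3)
        assert set(np.unique(pvd.matrix)) <= {0.0, 1.0}
        assert np.allclose(pvd.matrix[np.arange(4), np.arange(4)], 1.0)

    def test_rows_and_columns_sum_to_one(self):
        rng = np.random.default_rng(4)
        hc = rng.standard_normal((30, 3))
        hd = rng.standard_normal((30, 3)) - rng.uniform(1, 3, 3)
        pvd = bootstrap_pvd(matrix_from_groups(hc, hd), n_bootstrap=6, seed=1,
                            n_restarts=2)
        assert np.allclose(pvd.matrix.sum(axis=0), 1.0, atol=1e-10)
        assert np.allclose(pvd.matrix.sum(axis=1), 1.0, atol=1e-10)

    def test_near_simultaneous_events_split_mass(self):
        """Two events with identical distributions: bootstrap mass splits
        across their two adjacent positions."""
        rng = np.random.default_rng(5)
        z = 3
        hc = rng.standard_normal((45, z)) * 0.3
        # patients at staggered stages, but stage-2 subjects have bm1 OR bm2
        # abnormal at random: the two events are interchangeable
        blocks = []
        for _ in range(15):
            blocks.append([-6.0, 0.0, 0.0])                  # stage 1
            second = rng.integers(1, 3)
            row = [-6.0, 0.0, 0.0]
            row[second] = -6.0
            blocks.append(row)                               # stage 2
            blocks.append([-6.0, -6.0, -6.0])                # stage 3
        hd = np.array(blocks) + rng.standard_normal((45, z)) * 0.3
        pvd = bootstrap_pvd(matrix_from_groups(hc, hd), n_bootstrap=20,
                            seed=2, n_restarts=3)
        assert pvd.matrix[0, 0] == pytest.approx(1.0)
        for i in (1, 2):
            assert 0.2 <= pvd.matrix[i, 1] <= 0.8
            assert pvd.matrix[i, 1] + pvd.matrix[i, 2] == pytest.approx(1.0)

    def test_requires_two_resamples(self):
        with pytest.raises(ValueError, match="n_bootstrap"):
            bootstrap_pvd(self._separated_matrix(), n_bootstrap=1)


class TestLongitudinalConsistency:
    def test_constant_stages_all_non_regressing(self):
        stages = [3, 5, 1] * 2
        visits = [0, 0, 0, 12, 12, 12]
        ids = ["a", "b", "c", "a", "b", "c"]
        rep = longitudinal_consistency(assignments_from(stages, visits, ids))
        assert rep["fraction_non_regressing"] == 1.0
        assert rep["mean_progression"] == 0.0
        assert rep["n_regressors"] == 0

    def test_monotone_progression_counts(self):
        ids = ["a", "b", "a", "b", "a", "b"]
        visits = [0, 0, 12, 12, 24, 24]
        stages = [2, 3, 4, 3, 6, 5]
        rep = longitudinal_consistency(assignments_from(stages, visits, ids))
        assert rep["fraction_non_regressing"] == 1.0
        assert rep["mean_progression"] == pytest.approx((4 + 2) / 2)
        assert rep["mean_stage_change"] == pytest.approx(3.0)

    def test_regressors_reported_separately(self):
        ids = ["a", "b", "a", "b"]
        visits = [0, 0, 12, 12]
        stages = [5, 2, 3, 4]
        rep = longitudinal_consistency(assignments_from(stages, visits, ids))
        assert rep["fraction_non_regressing"] == 0.5
        assert rep["mean_regression"] == pytest.approx(2.0)
        assert rep["n_regressors"] == 1

    def test_no_followups_rejected(self):
        with pytest.raises(ValueError, match="follow-up"):
            longitudinal_consistency(assignments_from([1, 2]))


class TestPredictConversion:
    def test_printed_operating_point_balanced_accuracy(self):
        """A staged cohort whose best threshold operates at 75% sensitivity
        and 55% specificity yields balanced accuracy 65% exactly."""
        stages = pd.Series([1, 8, 8, 8] + [2] * 11 + [8] * 9,
                           index=[f"s{j}" for j in range(24)])
        conv = pd.Series([True] * 4 + [False] * 20, index=stages.index)
        res = predict_conversion(stages, conv, n_stages=18)
        assert res.sensitivity == pytest.approx(0.75)
        assert res.specificity == pytest.approx(0.55)
        assert res.balanced_accuracy == pytest.approx(0.65)

    def test_perfect_separation(self):
        stages = pd.Series([1, 2, 3, 10, 11, 12],
                           index=[f"s{j}" for j in range(6)])
        conv = pd.Series([False] * 3 + [True] * 3, index=stages.index)
        res = predict_conversion(stages, conv, n_stages=12)
        assert res.balanced_accuracy == 1.0

    def test_balanced_accuracy_identity(self):
        rng = np.random.default_rng(6)
        stages = pd.Series(rng.integers(0, 10, 50),
                           index=[f"s{j}" for j in range(50)])
        conv = pd.Series(rng.random(50) < 0.3, index=stages.index)
        res = predict_conversion(stages, conv, n_stages=10)
        assert res.balanced_accuracy == (res.sensitivity + res.specificity) / 2

    def test_sweep_matches_direct_enumeration(self):
        rng = np.random.default_rng(7)
        stages = pd.Series(rng.integers(0, 8, 40),
                           index=[f"s{j}" for j in range(40)])
        conv = pd.Series(rng.random(40) < 0.4, index=stages.index)
        res = predict_conversion(stages, conv, n_stages=7)
        y, s = conv.to_numpy(), stages.to_numpy()
        best = max(
            (0.5 * (((s > t) & y).sum() / y.sum()
                    + ((~(s > t)) & ~y).sum() / (~y).sum()), -t)
            for t in range(8))
        assert res.balanced_accuracy == pytest.approx(best[0])
        assert res.threshold_stage == -best[1] or res.balanced_accuracy == best[0]

    def test_independent_stages_near_chance(self):
        """Stages carrying no information: optimized balanced accuracy stays
        within permutation-null range of 0.5."""
        rng = np.random.default_rng(8)
        n = 400
        stages = pd.Series(rng.integers(0, 19, n),
                           index=[f"s{j}" for j in range(n)])
        conv = pd.Series(rng.random(n) < 0.5, index=stages.index)
        res = predict_conversion(stages, conv, n_stages=18)
        null = []
        y = conv.to_numpy()
        s = stages.to_numpy()
        for _ in range(200):
            yp = rng.permutation(y)
            null.append(max(
                0.5 * (((s > t) & yp).sum() / yp.sum()
                       + ((~(s > t)) & ~yp).sum() / (~yp).sum())
                for t in range(19)))
        assert res.balanced_accuracy <= np.quantile(null, 0.995)

    def test_single_class_rejected(self):
        stages = pd.Series([1, 2], index=["a", "b"])
        with pytest.raises(ValueError, match="converter"):
            predict_conversion(stages, pd.Series([True, True],
                                                 index=["a", "b"]), 5)


class TestPhenotypeRegression:
    def test_identity_phenotype(self):
        stages = list(range(10))
        a = assignments_from(stages)
        pheno = pd.DataFrame({"TMS": np.array(stages, dtype=float)},
                             index=a.table["subject_id"])
        out = phenotype_regression(a, pheno)
        assert out.loc["TMS", "slope"] == pytest.approx(1.0)
        assert out.loc["TMS", "p_value"] < 1e-8

    def test_planted_slopes_recovered_within_2se(self):
        rng = np.random.default_rng(9)
        n = 238
        stages = rng.integers(0, 19, n)
        a = assignments_from(stages.tolist())
        planted = {"TMS": 0.98, "SDMT": -1.0, "Stroop": -1.4, "CAP": 0.014}
        noise = {"TMS": 5.0, "SDMT": 8.0, "Stroop": 12.0, "CAP": 0.1}
        pheno = pd.DataFrame(
            {k: planted[k] * stages + noise[k] * rng.standard_normal(n)
             for k in planted}, index=a.table["subject_id"])
        out = phenotype_regression(a, pheno)
        for k in planted:
            se = noise[k] / (stages.std() * np.sqrt(n))
            assert abs(out.loc[k, "slope"] - planted[k]) < 2.5 * se

    def test_shuffled_phenotype_rarely_significant(self):
        rng = np.random.default_rng(10)
        n = 80
        stages = rng.integers(0, 19, n)
        a = assignments_from(stages.tolist())
        n_sig = 0
        for _ in range(100):
            pheno = pd.DataFrame({"TMS": rng.permutation(stages).astype(float)
                                  + rng.standard_normal(n) * 5},
                                 index=a.table["subject_id"])
            n_sig += phenotype_regression(a, pheno).loc["TMS", "p_value"] < 0.05
        assert n_sig <= 10

    def test_zero_stage_variance_rejected(self):
        a = assignments_from([3, 3, 3])
        pheno = pd.DataFrame({"TMS": [1.0, 2.0, 3.0]},
                             index=a.table["subject_id"])
        with pytest.raises(ValueError, match="variance"):
            phenotype_regression(a, pheno)
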