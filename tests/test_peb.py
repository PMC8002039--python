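"""Hierarchical group model: design, estimation, contribution sums."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

import fesdcm as fd
from fesdcm.inversion import Posterior, PriorSpec
from fesdcm.peb import GroupEstimates, normalize_capacity

# printed pre/post capacity scores of the 8 patients (clinical table scale)
TABLE2_SCORES = [
    20.30, 21.32, 8.15, 8.17, 14.33, 18.15, 23.42, 23.82,
    21.26, 23.00, 24.50, 22.70, 17.31, 16.99, 18.50, 19.76,
]


def patient_records(n=4, scores=None):
    recs = []
    for i in range(n):
        ce = 1 if i < n // 2 else -1
        for tp in (1, -1):
            recs.append(
                fd.SubjectRecord(
                    subject_id=f"P{i:02d}", cohort="patient", carryover=ce,
                    timepoint=tp,
                    capacity_score=(scores[2 * i + (0 if tp == 1 else 1)]
                                    if scores else 15.0 + i),
                )
            )
    return recs


def toy_posteriors(n, k, truth_fn, prior, noise=0.05, subj_cov=0.08, seed=0):
    rng = np.random.default_rng(seed)
    names = [f"A:X{j}->Y{j}" for j in range(k)]
    posts = []
    for i in range(n):
        th = truth_fn(i) + rng.normal(0, subj_cov, k)
        m = th + rng.normal(0, noise, k)
        posts.append(Posterior(mean=m, cov=np.eye(k) * noise**2,
                               free_energy=0.0, names=names, prior=prior))
    return posts, names


class TestSubjectRecord:
    def test_controls_reject_patient_covariates(self):
        with pytest.raises(ValueError):
            fd.SubjectRecord("C1", "control", carryover=1)

    def test_patients_need_signed_labels(self):
        with pytest.raises(ValueError):
            fd.SubjectRecord("P1", "patient", carryover=0, timepoint=1)


class TestBuildDesign:
    def test_controls_mean_only(self):
        recs = [fd.SubjectRecord(f"C{i}", "control") for i in range(16)]
        d = fd.build_design(recs)
        assert d.matrix.shape == (16, 1)
        assert np.all(d.matrix == 1.0)

    def test_controls_refuse_extra_regressors(self):
        recs = [fd.SubjectRecord(f"C{i}", "control") for i in range(4)]
        with pytest.raises(ValueError, match="single mean"):
            fd.build_design(recs, regressors=("mean", "time"))

    def test_clinical_scores_normalized_into_unit_interval(self):
        col = normalize_capacity(TABLE2_SCORES)
        assert np.all(col >= -1.0) and np.all(col <= 1.0)
        assert col.mean() == pytest.approx(0.0, abs=1e-12)
        assert np.max(np.abs(col)) == pytest.approx(1.0)

    def test_degenerate_scores_map_to_zero(self):
        assert np.allclose(normalize_capacity([5.0, 5.0, 5.0]), 0.0)

    def test_signed_columns(self):
        d = fd.build_design(patient_records(4))
        ce = d.matrix[:, d.regressors.index("carryover")]
        tp = d.matrix[:, d.regressors.index("time")]
        assert set(ce) <= {-1.0, 1.0} and set(tp) <= {-1.0, 1.0}

    def test_rows_ordered_pre_before_post(self):
        d = fd.build_design(patient_records(3))
        for i in range(0, d.n, 2):
            assert d.rows[i][0] == d.rows[i + 1][0]
            assert d.rows[i][1] == 1 and d.rows[i + 1][1] == -1

    def test_missing_capacity_rejected(self):
        recs = patient_records(2)
        for r in recs:
            r.capacity_score = None
        with pytest.raises(ValueError, match="capacity"):
            fd.build_design(recs, regressors=("mean", "capacity"))


class TestFitPeb:
    def test_degenerate_hierarchy_returns_shared_mean(self):
        k = 3
        names = [f"A:X{j}->Y{j}" for j in range(k)]
        shared = np.array([0.4, -0.2, 0.1])
        prior = PriorSpec(np.zeros(k), np.eye(k) / 16, names)
        posts = [Posterior(mean=shared.copy(), cov=np.eye(k) * 1e-10,
                           free_energy=0.0, names=names, prior=prior)
                 for _ in range(8)]
        recs = [fd.SubjectRecord(f"C{i}", "control") for i in range(8)]
        d = fd.build_design(recs)
        flat = PriorSpec(np.zeros(k), np.eye(k) * 1e6)
        est = fd.fit_peb(posts, d, "A", beta_prior=flat)
        assert np.allclose(est.beta[0], shared, atol=1e-6)

    def test_recovers_planted_group_effects(self):
        k = 3
        prior = PriorSpec(np.zeros(k), np.eye(k) / 16)
        truth_mean = np.array([0.3, 0.0, -0.25])
        posts, _ = toy_posteriors(10, k, lambda i: truth_mean, prior, seed=1)
        recs = [fd.SubjectRecord(f"C{i}", "control") for i in range(10)]
        est = fd.fit_peb(posts, fd.build_design(recs), "A")
        for j in range(k):
            sd = est.coefficient_sd("mean", est.connections[j])
            assert abs(est.beta[0, j] - truth_mean[j]) < 2 * sd + 0.05

    def test_recovers_planted_carryover_coefficient(self):
        k = 2
        prior = PriorSpec(np.zeros(k), np.eye(k) / 16)
        ce_effect = np.array([0.5, 0.0])

        def truth(i):
            ce = 1 if i % 2 == 0 else -1
            return ce * ce_effect

        rng = np.random.default_rng(2)
        names = [f"B:X{j}->Y{j}" for j in range(k)]
        posts, recs = [], []
        for i in range(8):
            subj = rng.normal(0, 0.08, k)
            for tp in (1, -1):
                th = truth(i) + subj
                m = th + rng.normal(0, 0.05, k)
                posts.append(Posterior(mean=m, cov=np.eye(k) * 0.05**2,
                                       free_energy=0.0, names=names,
                                       prior=prior))
                recs.append(fd.SubjectRecord(
                    f"P{i:02d}", "patient",
                    carryover=1 if i % 2 == 0 else -1, timepoint=tp,
                    capacity_score=10.0 + i))
        est = fd.fit_peb(posts, fd.build_design(recs), "B")
        co = est.coefficient("carryover", names[0])
        sd = est.coefficient_sd("carryover", names[0])
        assert co > 0
        assert abs(co - 0.5) < 2 * sd + 0.05

    def test_row_permutation_invariance(self):
        k = 2
        prior = PriorSpec(np.zeros(k), np.eye(k) / 16)
        posts, _ = toy_posteriors(6, k, lambda i: np.array([0.2, -0.1]),
                                  prior, seed=3)
        recs = [fd.SubjectRecord(f"C{i}", "control") for i in range(6)]
        est1 = fd.fit_peb(posts, fd.build_design(recs), "A")
        order = [3, 1, 5, 0, 4, 2]
        est2 = fd.fit_peb([posts[i] for i in order],
                          fd.build_design([recs[i] for i in order]), "A")
        assert np.allclose(est1.beta, est2.beta, atol=1e-8)

    def test_rank_deficient_design_rejected(self):
        k = 1
        prior = PriorSpec(np.zeros(k), np.eye(k))
        posts, _ = toy_posteriors(4, k, lambda i: np.zeros(k), prior)
        recs = patient_records(2)
        for r in recs:
            r.capacity_score = 10.0 if r.carryover == 1 else 20.0
        with pytest.raises(ValueError, match="rank"):
            fd.fit_peb(posts, fd.build_design(recs), "A")

    def test_shrinkage_toward_design_prediction(self):
        # the empirical-Bayes update replaces each subject's shrinkage
        # prior with the group prediction, so the updated mean lies between
        # the subject's likelihood-only (de-shrunken) estimate and the
        # design-predicted group value, coordinate-wise (diagonal case)
        k = 2
        prior = PriorSpec(np.zeros(k), np.eye(k) / 16)
        posts, _ = toy_posteriors(8, k, lambda i: np.array([0.3, -0.2]),
                                  prior, noise=0.1, seed=4)
        recs = [fd.SubjectRecord(f"C{i}", "control") for i in range(8)]
        est = fd.fit_peb(posts, fd.build_design(recs), "A")
        group = est.beta[0]
        P0 = prior.precision
        for i, p in enumerate(posts):
            P = np.linalg.inv(p.cov)
            deshrunk = np.linalg.solve(P - P0, P @ p.mean - P0 @ prior.mean)
            updated = est.subject_means[i]
            for j in range(k):
                lo, hi = sorted([deshrunk[j], group[j]])
                assert lo - 1e-6 <= updated[j] <= hi + 1e-6


class TestCombineContributions:
    def _estimates(self, coeffs):
        regs = tuple(coeffs)
        k = 1
        beta = np.array([[coeffs[r]] for r in regs])
        d = fd.PEBDesign(np.ones((2, len(regs))) if "mean" not in regs else
                         np.ones((2, len(regs))), regs, (("a", 1), ("b", -1)))
        return GroupEstimates(
            connections=["B:SMA->M1"], regressors=regs, beta=beta,
            beta_cov=np.eye(len(regs)) * 1e-4, free_energy=0.0, gamma=0.0,
            gamma_var=1.0, design=d,
            beta_prior=PriorSpec(np.zeros(len(regs)), np.eye(len(regs))),
        )

    def test_ce_pre_worked_example(self):
        est = self._estimates({"mean": 0.0, "carryover": -0.39,
                               "time": 0.51, "capacity": 0.0})
        v = fd.combine_contributions(est, "B:SMA->M1", carryover=1,
                                     timepoint=1)
        assert v == pytest.approx(0.12)

    def test_ce_post_worked_example(self):
        est = self._estimates({"mean": 0.0, "carryover": -0.39,
                               "time": 0.51, "capacity": 0.0})
        v = fd.combine_contributions(est, "B:SMA->M1", carryover=1,
                                     timepoint=-1)
        assert v == pytest.approx(-0.90)

    def test_all_zero_coefficients(self):
        est = self._estimates({"mean": 0.0, "carryover": 0.0, "time": 0.0,
                               "capacity": 0.0})
        assert fd.combine_contributions(est, "B:SMA->M1", 1, -1, 0.5) == 0.0

    def test_absent_regressors_contribute_nothing(self):
        est = self._estimates({"mean": 0.2})
        assert fd.combine_contributions(
            est, "B:SMA->M1", carryover=1, timepoint=-1, capacity=0.7
        ) == pytest.approx(0.2)

    def test_unknown_connection_rejected(self):
        est = self._estimates({"mean": 0.0})
        with pytest.raises(KeyError):
            fd.combine_contributions(est, "B:AG->AG")

    @given(ce=st.floats(-1, 1), tp=st.floats(-1, 1), cs=st.floats(-1, 1))
    @hyp_settings(max_examples=30, deadline=None, derandomize=True)
    def test_linearity_in_each_regressor(self, ce, tp, cs):
        est = self._estimates({"mean": 0.1, "carryover": -0.4, "time": 0.5,
                               "capacity": 0.2})
        v = fd.combine_contributions(est, "B:SMA->M1", ce, tp, cs)
        expected = 0.1 + ce * -0.4 + tp * 0.5 + cs * 0.2
        assert v == pytest.approx(expected, abs=1e-12)


class TestPebSearch:
    def _toy_estimates(self, seed=0):
        k = 3
        prior = PriorSpec(np.zeros(k), np.eye(k) / 16)
        truth = np.array([0.35, 0.0, -0.3])
        posts, _ = toy_posteriors(10, k, lambda i: truth, prior, seed=seed)
        recs = [fd.SubjectRecord(f"C{i}", "control") for i in range(10)]
        return fd.fit_peb(posts, fd.build_design(recs), "A")

    def test_inclusion_separates_present_from_absent(self):
        est = self._toy_estimates()
        _, incl, _ = fd.peb_search(est)
        assert incl[est.connections[0]] > 0.9
        assert incl[est.connections[2]] > 0.9
        assert incl[est.connections[1]] < 0.5

    def test_no_switchable_reproduces_full_estimates(self):
        est = self._toy_estimates()
        bma, incl, cmp_ = fd.peb_search(est, switchable=[])
        assert len(cmp_.identifiers) == 1
        assert np.allclose(bma.beta, est.beta, atol=1e-10)

    def test_single_switchable_compares_two_models(self):
        est = self._toy_estimates()
        _, _, cmp_ = fd.peb_search(est, switchable=[est.connections[1]])
        assert len(cmp_.identifiers) == 2

    def test_joint_group_switching(self):
        est = self._toy_estimates()
        pair = (est.connections[0], est.connections[2])
        _, incl, cmp_ = fd.peb_search(est, switchable=[pair])
        assert len(cmp_.identifiers) == 2
        assert incl["|".join(pair)] > 0.9
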