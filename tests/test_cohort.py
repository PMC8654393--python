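"""Synthetic cohorts: structure, reproducibility, identifiability."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from microdcm.cohort import (CohortSpec, GROUP_SIZES, add_observation_noise,
                             draw_true_parameters, generate_cohort,
                             generate_subject_data, predict_paradigm)
from microdcm.cmc import ModelError

ASSR_FIT_GRID = np.arange(10.0, 50.0 + 1e-9, 1.0)


def small_spec(**kw):
    base = dict(paradigms=("assr",),
                group_sizes={"Con": 2, "PScz": 2, "Rel": 1}, seed=5)
    base.update(kw)
    return CohortSpec(**base)


class TestSpecAndDraws:
    def test_default_group_sizes_match_study(self):
        assert CohortSpec().group_sizes == GROUP_SIZES
        assert (GROUP_SIZES["Con"], GROUP_SIZES["PScz"],
                GROUP_SIZES["Rel"]) == (107, 108, 57)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ModelError):
            CohortSpec(group_sizes={"Con": 0})

    def test_degenerate_spec_gives_identical_parameters(self):
        spec = small_spec(between_sd=0.0,
                          effects={"assr": {"diagnosis": {}, "risk": {}}})
        rng = np.random.default_rng(0)
        t1 = draw_true_parameters(spec, "assr", "Con", rng)
        t2 = draw_true_parameters(spec, "assr", "PScz", rng)
        assert t1 == t2

    def test_diagnosis_delta_shifts_group_means(self):
        spec = small_spec(between_sd=0.05)
        rng = np.random.default_rng(1)
        pscz = [draw_true_parameters(spec, "assr", "PScz", rng)
                ["A1L.G.sp->sp"] for _ in range(200)]
        rel = [draw_true_parameters(spec, "assr", "Rel", rng)
               ["A1L.G.sp->sp"] for _ in range(200)]
        assert np.mean(pscz) - np.mean(rel) == pytest.approx(0.25, abs=0.02)

    def test_effect_on_unknown_parameter_rejected(self):
        spec = small_spec(effects={"assr": {"diagnosis":
                                            {"A1L.G.zz->zz": 0.1}}})
        with pytest.raises(ModelError, match="free parameter"):
            draw_true_parameters(spec, "assr", "PScz",
                                 np.random.default_rng(0))


class TestDataGeneration:
    def test_same_seed_reproduces_data_bitwise(self):
        spec = small_spec()
        theta = draw_true_parameters(spec, "assr", "Con",
                                     np.random.default_rng(2))
        d1 = generate_subject_data(spec, {"assr": theta}, seed=42,
                                   grid=ASSR_FIT_GRID)
        d2 = generate_subject_data(spec, {"assr": theta}, seed=42,
                                   grid=ASSR_FIT_GRID)
        assert np.array_equal(d1["assr"].values, d2["assr"].values)

    def test_zero_noise_returns_forward_prediction_exactly(self):
        spec = small_spec(noise_rest=0.0, assr_dof=0, paradigms=("rest",))
        theta = draw_true_parameters(spec, "rest", "Con",
                                     np.random.default_rng(3))
        data = generate_subject_data(spec, {"rest": theta}, seed=1)
        clean = predict_paradigm("rest", theta)
        np.testing.assert_allclose(data["rest"].values, clean.values,
                                   rtol=1e-12)

    def test_assr_noise_preserves_hermitian_psd(self):
        spec = small_spec()
        rng = np.random.default_rng(4)
        for k in range(100):
            theta = draw_true_parameters(spec, "assr", "Con", rng)
            clean = predict_paradigm("assr", theta, grid=ASSR_FIT_GRID)
            noisy = add_observation_noise("assr", clean, spec,
                                          np.random.default_rng(k))
            assert noisy.validate()

    def test_cohort_container_structure(self):
        spec = small_spec()
        subs = generate_cohort(spec, grid=ASSR_FIT_GRID)
        assert len(subs) == 5
        assert sorted({s.group for s in subs}) == ["Con", "PScz", "Rel"]
        s = subs[0]
        assert set(s.covariates) == {"age", "male", "smoker", "cpz"}
        assert set(s.symptoms) == {"positive", "negative"}
        assert "assr" in s.data and "assr" in s.true_params

    def test_cohort_deterministic_under_seed(self):
        s1 = generate_cohort(small_spec(), grid=ASSR_FIT_GRID)
        s2 = generate_cohort(small_spec(), grid=ASSR_FIT_GRID)
        for a, b in zip(s1, s2):
            assert a.true_params == b.true_params
            assert np.array_equal(a.data["assr"].values,
                                  b.data["assr"].values)

    def test_symptom_scores_respect_scales(self):
        spec = small_spec(group_sizes={"PScz": 30})
        subs = generate_cohort(spec, grid=ASSR_FIT_GRID)
        pos = [s.symptoms["positive"] for s in subs]
        neg = [s.symptoms["negative"] for s in subs]
        assert 0 <= min(pos) and max(pos) <= 49
        assert 0 <= min(neg) and max(neg) <= 28


class TestIdentifiability:
    @pytest.fixture(scope="class")
    def fitted(self):
        from microdcm.experiments import assr_fit_priors, fit_assr_subject
        from microdcm.inversion import FitSettings

        spec = small_spec(group_sizes={"Con": 20}, seed=9)
        subs = generate_cohort(spec, grid=ASSR_FIT_GRID)
        priors = assr_fit_priors()
        true, est = [], []
        for s in subs:
            fr = fit_assr_subject(s.data["assr"], priors=priors,
                                  settings=FitSettings(max_iter=20))
            for a in ("A1L", "A1R"):
                j = fr.posterior.names.index(f"{a}.G.sp->sp")
                true.append(s.true_params["assr"][f"{a}.G.sp->sp"])
                est.append(fr.posterior.mean[j])
        return np.asarray(true), np.asarray(est)

    def test_self_inhibition_rank_correlation(self, fitted):
        true, est = fitted
        assert spearmanr(true, est).statistic >= 0.6

    def test_recovery_error_shrinks_with_noise(self):
        from microdcm.experiments import assr_fit_priors, fit_assr_subject
        from microdcm.inversion import FitSettings

        from microdcm.cohort import generate_subject_data

        priors = assr_fit_priors()
        rng = np.random.default_rng(11)
        # subjects vary only in the fitted parameters, so the noiseless
        # limit is exactly recoverable
        thetas = []
        base_spec = small_spec(group_sizes={"Con": 6}, seed=11)
        for _ in range(6):
            th = draw_true_parameters(base_spec, "assr", "Con", rng)
            for a in ("A1L", "A1R"):
                th[f"{a}.G.ii->ii"] = 0.0
            thetas.append(th)
        errs = []
        for dof in (30, 150, 0):        # 0 = noiseless
            spec = small_spec(group_sizes={"Con": 6}, seed=11, assr_dof=dof)
            e = []
            for i, th in enumerate(thetas):
                data = generate_subject_data(spec, {"assr": th}, seed=50 + i,
                                             grid=ASSR_FIT_GRID)
                fr = fit_assr_subject(data["assr"], priors=priors,
                                      settings=FitSettings(max_iter=20))
                j = fr.posterior.names.index("A1L.G.sp->sp")
                e.append(abs(fr.posterior.mean[j] - th["A1L.G.sp->sp"]))
            errs.append(np.mean(e))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.02


class TestMmnCohort:
    def test_mmn_generation_and_pipeline_surface(self):
        """Three-source evoked cohorts generate, carry the deviant
        disinhibition, and the oddball pipeline runs end to end."""
        from microdcm import experiments as E
        from microdcm.inversion import FitSettings

        spec = CohortSpec(paradigms=("mmn",),
                          group_sizes={"Con": 2, "PScz": 2}, seed=21,
                          between_sd=0.05)
        subs = generate_cohort(spec, erp_kwargs=dict(dt=0.4,
                                                     t_start_ms=-50.0,
                                                     t_end_ms=300.0))
        assert len(subs) == 4
        erp = subs[0].data["mmn"]
        assert set(erp.traces) == {"standard", "deviant"}
        # deviant disinhibition generator present in the truth
        b = subs[0].true_params["mmn"]["B.deviant.A1.G.sp->sp"]
        assert b < 0
        # oddball pipeline surface on single-column subjects
        oddballs = E.oddball_cohort_erps(3, seed=22)
        res = E.run_paradigm_pipeline(
            "mmn", list(zip(["Con", "Con", "PScz"], oddballs)),
            scheme="case-control", models=["6G", "4Ga"],
            settings=FitSettings(max_iter=4), seed=22)
        assert res.report["winning_model"] in ("6G", "4Ga")
        assert res.log_evidence.shape == (3, 2)
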