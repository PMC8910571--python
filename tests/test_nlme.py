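"""Mixed-effects estimation: likelihood kernels, Laplace vs quadrature,
parameter recovery, RSEs, BICc and model selection."""

import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import aptapk as ap
from aptapk.datasets import PKDataset, Subject
from aptapk.nlme import ErrorModel, PopPKModel, PopPKResults, RandomEffectsSpec, bicc


def make_subject(times, dv, dose=40.0, bw=25.0, sid=1, blq=None):
    times = np.asarray(times, float)
    dv = np.asarray(dv, float)
    blq = np.zeros(times.size, bool) if blq is None else np.asarray(blq, bool)
    return Subject(
        subject_id=sid, dose=dose, bw=bw, times=times,
        dv=np.where(blq, np.nan, dv), blq=blq, mdv=blq.copy(),
        lloq=np.where(blq, 0.015, np.nan),
    )


class LinearToyModel(PopPKModel):
    """Structural model f = cl * exp(eta): the marginal likelihood is a
    closed-form log-normal, an analytic oracle for the Laplace machinery."""

    def _predict_rows(self, params, eta):
        return params["cl"] * np.exp(eta[self._obs_sidx]) * np.ones(self.n_obs)


class TestIndividualLoglik:
    def test_zero_residual(self, ref_ind):
        t = np.array([15.0, 60.0])
        pred = ap.concentration(ref_ind, 40.0, t)
        s = make_subject(t[:1], pred[:1])
        ll = ap.individual_loglik(s, ref_ind, ErrorModel(0.27))
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi * 0.27**2))

    def test_plus_minus_one_sd(self, ref_ind):
        t = np.array([15.0, 60.0])
        pred = ap.concentration(ref_ind, 40.0, t)
        dv = pred * np.exp([0.27, -0.27])
        s = make_subject(t, dv)
        ll = ap.individual_loglik(s, ref_ind, ErrorModel(0.27))
        assert ll == pytest.approx(2 * (-0.5 * math.log(2 * math.pi * 0.27**2)) - 1.0)

    def test_all_bloq_is_empty_likelihood(self, ref_ind):
        s = make_subject([15.0, 30.0], [0.01, 0.01], blq=[True, True])
        with pytest.raises(ValueError, match="no quantified"):
            ap.individual_loglik(s, ref_ind, ErrorModel(0.27))


class TestMarginalLoglik:
    def test_degenerate_random_effect(self, ref_pop, ref_ind, small_cohort):
        s = small_cohort.subjects[0]
        ll0 = ap.marginal_loglik(s, ref_pop, RandomEffectsSpec(0.0),
                                 ErrorModel(0.27))
        assert ll0 == pytest.approx(
            ap.individual_loglik(s, ref_ind, ErrorModel(0.27)), rel=1e-12)

    def test_laplace_agrees_with_quadrature(self, ref_pop):
        design = ap.StudyDesign(n_animals=1, loq=0.0,
                                sample_times=(0.0, 15.0, 60.0, 240.0, 1440.0))
        for seed in range(10):
            ds = ap.generate_pk_cohort(design, ref_pop, seed=300 + seed)
            s = ds.subjects[0]
            lap = ap.marginal_loglik(s, ref_pop, RandomEffectsSpec(0.2174),
                                     ErrorModel(0.27), method="laplace")
            agq = ap.marginal_loglik(s, ref_pop, RandomEffectsSpec(0.2174),
                                     ErrorModel(0.27), method="agq", n_nodes=64)
            assert abs(lap - agq) <= 0.01

    def test_linear_toy_matches_analytic_marginal(self):
        """f = c e^eta gives log y ~ MVN(log c, b^2 I + omega^2 J)."""
        rng = np.random.default_rng(21)
        c0, b, omega = 2.5, 0.3, 0.4
        subs = [make_subject([10.0, 20.0, 30.0],
                             c0 * np.exp(rng.normal(0, 0.4, 3)), sid=i + 1)
                for i in range(2)]
        model = LinearToyModel(PKDataset.from_subjects(subs),
                               structure="one_compartment")
        params = dict(cl=c0, v1=1.0, b=b, omega=omega)
        expected = 0.0
        for s in subs:
            logy = np.log(s.dv)
            cov = b**2 * np.eye(3) + omega**2 * np.ones((3, 3))
            expected += multivariate_normal.logpdf(logy, np.full(3, np.log(c0)),
                                                   cov)
        assert model.loglik(params) == pytest.approx(expected, abs=1e-6)
        assert model.loglik(params, method="agq") == pytest.approx(expected,
                                                                   abs=1e-6)


class TestFit:
    def test_noise_free_recovery(self, noise_free_cohort):
        model = PopPKModel(noise_free_cohort, "two_compartment")
        res = model.fit(fix={"b": 0.01, "omega": 0.0})
        assert res.converged
        assert res.params["cl"] == pytest.approx(3.29, rel=1e-3)
        assert res.params["v1"] == pytest.approx(81.77, rel=1e-3)
        assert res.params["q"] == pytest.approx(1.78, rel=1e-3)
        assert res.params["v2"] == pytest.approx(182.2, rel=1e-3)

    def test_single_subject_rejected(self, ref_pop):
        design = ap.StudyDesign(n_animals=1, loq=0.0)
        ds = ap.generate_pk_cohort(design, ref_pop, seed=1)
        with pytest.raises(ValueError, match=">=2 subjects"):
            PopPKModel(ds, "two_compartment")

    def test_deterministic(self, small_cohort):
        r1 = PopPKModel(small_cohort).fit()
        r2 = PopPKModel(small_cohort).fit()
        assert r1.params == r2.params
        assert r1.llf == r2.llf

    def test_scale_invariance(self, small_cohort):
        """Rescaling observations and dose together leaves estimates fixed
        (concentration-scale invariance of the exponential-error model)."""
        df = small_cohort.df.copy()
        df["DV"] *= 10.0
        df["AMT"] *= 10.0
        df["LLOQ"] *= 10.0
        m1 = PopPKModel(small_cohort)
        m2 = PopPKModel(PKDataset(df))
        # the marginal likelihood itself is exactly scale-invariant
        for params in (dict(cl=3.29, v1=81.77, q=1.78, v2=182.2, b=0.27,
                            omega=0.2174),
                       dict(cl=2.0, v1=60.0, q=1.0, v2=100.0, b=0.4,
                            omega=0.1)):
            assert m2.loglik(params) == pytest.approx(m1.loglik(params),
                                                      abs=1e-6)
        # estimates agree up to optimizer resolution on the flat directions
        r1, r2 = m1.fit(), m2.fit()
        for k in r1.params:
            assert r2.params[k] == pytest.approx(r1.params[k], rel=0.01)

    def test_summary_mentions_key_quantities(self, small_cohort):
        res = PopPKModel(small_cohort).fit()
        text = res.summary()
        for token in ("CL", "V1", "BICc", "half-lives", "BSV CV%"):
            assert token in text


class TestRSE:
    def test_analytic_fisher_toy(self):
        """Constant-prediction toy: RSE(c) = 100*b/sqrt(n) from the
        closed-form Fisher information of a log-normal mean."""
        rng = np.random.default_rng(8)
        c0, b, n = 5.0, 0.2, 100
        subs = []
        for i in range(2):
            t = np.arange(1.0, n // 2 + 1.0)
            dv = c0 * np.exp(b * rng.standard_normal(t.size))
            subs.append(make_subject(t, dv, sid=i + 1))
        model = LinearToyModel(PKDataset.from_subjects(subs),
                               structure="one_compartment")
        res = model.fit(init={"cl": c0, "b": b}, fix={"v1": 1.0, "omega": 0.0})
        b_hat = res.params["b"]
        expected = 100.0 * b_hat / math.sqrt(n)
        assert res.rse_percent["cl"] == pytest.approx(expected, rel=0.05)

    def test_duplication_shrinks_rse(self, small_cohort):
        import pandas as pd

        df = small_cohort.df
        df2 = df.copy()
        df2["ID"] = df2["ID"] + 100
        doubled = PKDataset(pd.concat([df, df2], ignore_index=True))
        r1 = PopPKModel(small_cohort).fit()
        r2 = PopPKModel(doubled).fit()
        for k in ("cl", "v1"):
            ratio = r2.rse_percent[k] / r1.rse_percent[k]
            assert ratio == pytest.approx(1 / math.sqrt(2), rel=0.2)

    def test_boundary_omega_reported_missing(self, ref_pop):
        """No-BSV data pushes omega to its bound; its RSE must be absent."""
        design = ap.StudyDesign(n_animals=8, loq=0.0)
        ds = ap.generate_pk_cohort(design, ref_pop, omega_cl=0.0, b=0.05,
                                   seed=4)
        res = PopPKModel(ds).fit()
        assert "omega" in res.boundary
        assert math.isnan(res.rse_percent["omega"])


class TestBICc:
    def test_hand_formula(self):
        val = bicc(-90.0, n_subjects=6, n_obs=40, n_fixed=4, n_random=1)
        assert val == pytest.approx(180.0 + 4 * math.log(40) + math.log(6))

    def test_penalty_variants(self):
        assert bicc(-90.0, 6, 40, 4, 1, penalty="n_obs") == pytest.approx(
            180.0 + 5 * math.log(40))
        assert bicc(-90.0, 6, 40, 4, 1, penalty="n_subjects") == pytest.approx(
            180.0 + 5 * math.log(6))
        with pytest.raises(ValueError):
            bicc(-90.0, 6, 40, 4, 1, penalty="aic")

    def test_monotone_in_loglik_and_parameters(self):
        assert bicc(-80.0, 6, 40, 4, 1) < bicc(-90.0, 6, 40, 4, 1)
        assert bicc(-90.0, 6, 40, 5, 1) > bicc(-90.0, 6, 40, 4, 1)


class TestSelectModel:
    def test_selects_lower_bicc(self, small_cohort):
        f1 = PopPKModel(small_cohort, "one_compartment").fit()
        f2 = PopPKModel(small_cohort, "two_compartment").fit()
        best = ap.select_model([f1, f2])
        assert best is min([f1, f2], key=lambda f: f.bicc)
        assert best.model.structure == "two_compartment"

    def test_tie_breaks_to_fewer_parameters(self, small_cohort):
        f2 = PopPKModel(small_cohort, "two_compartment").fit()

        def clone(free_names, bicc_value):
            return PopPKResults(
                model=f2.model, params=f2.params, free_names=free_names,
                fixed={}, llf=f2.llf, bicc=bicc_value, ebes=f2.ebes,
                converged=True, boundary=(), optimizer_message="", n_iter=0,
                method="laplace")

        small = clone(("cl", "v1", "b", "omega"), 100.0)
        large = clone(("cl", "v1", "q", "v2", "b", "omega"), 100.0)
        assert ap.select_model([large, small]) is small

    def test_rejects_different_datasets(self, small_cohort, ref_pop):
        other = ap.generate_pk_cohort(ap.StudyDesign(n_animals=6, loq=0.0),
                                      ref_pop, seed=99)
        f1 = PopPKModel(small_cohort).fit()
        f2 = PopPKModel(other).fit()
        with pytest.raises(ValueError, match="same dataset"):
            ap.select_model([f1, f2])


def test_cv_omega_mapping_is_exact_lognormal():
    omega = ap.cv_to_omega(22.0)
    assert omega == pytest.approx(0.2174, abs=2e-4)
    assert ap.omega_to_cv(omega) == pytest.approx(22.0, rel=1e-12)
    # the small-variance approximation cv ~ 100*omega is deliberately not used
    assert ap.omega_to_cv(0.5) != pytest.approx(50.0, rel=0.01)
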