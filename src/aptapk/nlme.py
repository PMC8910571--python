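"""Nonlinear mixed-effects estimation for the population PK model.

The model: per animal i with body weight BW_i,

    CL_i = CL_pop (BW_i/BW_ref)^0.75 e^{eta_i},   eta_i ~ N(0, omega^2)
    V1_i, V2_i = V_pop (BW_i/BW_ref)^1,  Q_i = Q_pop (BW_i/BW_ref)^0.75
    log y_ij = log C(t_ij; CL_i, V1_i, Q_i, V2_i) + b eps_ij,  eps ~ N(0,1)

i.e. a log-normal between-animal random effect on elimination clearance
and an exponential (multiplicative) residual-error model, analysed on the
log scale.  The marginal likelihood integrates eta out with a Laplace
approximation around the per-subject posterior mode; an adaptive
Gauss-Hermite quadrature route is provided as an independent check.
Estimation maximizes the total marginal log-likelihood over the
log-transformed parameters (guaranteeing positivity) with L-BFGS-B.

Model comparison uses a corrected BIC with the hybrid penalty common in
pharmacometric software: parameters tied to random effects are penalized
with ln(number of subjects), fixed-effect and residual parameters with
ln(number of observations).

The public surface is statsmodels-like: :class:`PopPKModel` is built from
a :class:`~aptapk.datasets.PKDataset` and ``fit()`` returns a
:class:`PopPKResults` carrying estimates, relative standard errors,
log-likelihood, BICc, empirical Bayes estimates and a ``summary()`` table.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr, logsumexp

from . import pk
from .datasets import PKDataset, Subject
from .pk import PopPKParams, _vectorized_biexponential

__all__ = [
    "ErrorModel",
    "RandomEffectsSpec",
    "PopPKModel",
    "PopPKResults",
    "fit_population",
    "select_model",
    "individual_loglik",
    "marginal_loglik",
    "compute_rse",
    "compute_bicc",
    "bicc",
    "omega_to_cv",
    "cv_to_omega",
]

_STRUCTURES = {
    "one_compartment": ("cl", "v1"),
    "two_compartment": ("cl", "v1", "q", "v2"),
}
_ALIASES = {"one_cpt": "one_compartment", "two_cpt": "two_compartment",
            "1cpt": "one_compartment", "2cpt": "two_compartment"}

_LOG_BOUNDS = {
    "cl": (-18.0, 18.0), "v1": (-18.0, 18.0), "q": (-18.0, 18.0),
    "v2": (-18.0, 18.0), "b": (math.log(1e-4), math.log(5.0)),
    "omega": (math.log(1e-3), math.log(2.5)),
}


def omega_to_cv(omega: float) -> float:
    """Exact log-normal SD -> coefficient of variability (%)."""
    return 100.0 * math.sqrt(math.expm1(omega * omega))


def cv_to_omega(cv_percent: float) -> float:
    """Exact coefficient of variability (%) -> log-normal SD."""
    return math.sqrt(math.log1p((cv_percent / 100.0) ** 2))


@dataclass(frozen=True)
class ErrorModel:
    """Exponential residual error: SD ``b`` of the log-observations."""

    b: float
    kind: str = "exponential"

    def __post_init__(self) -> None:
        if self.kind != "exponential":
            raise ValueError("only the exponential error model is supported")
        if self.b <= 0:
            raise ValueError("b must be strictly positive")


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Log-normal between-animal variability on elimination clearance."""

    omega_cl: float

    def __post_init__(self) -> None:
        if self.omega_cl < 0:
            raise ValueError("omega_cl must be non-negative")

    @property
    def cv_percent(self) -> float:
        return omega_to_cv(self.omega_cl)


# ---------------------------------------------------------------------------
# spec-level helpers on a single subject

def _subject_arrays(subject: Subject, bloq_policy: str):
    keep = subject.observed_mask
    t = subject.times[keep]
    y = subject.dv[keep]
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise ValueError(
            f"subject {subject.subject_id}: non-positive or missing observation "
            "retained; the exponential error model requires positive values"
        )
    if bloq_policy == "censored":
        cmask = subject.blq & ~np.isnan(subject.lloq)
        ct, clloq = subject.times[cmask], subject.lloq[cmask]
    else:
        ct = np.empty(0)
        clloq = np.empty(0)
    return t, y, ct, clloq


def individual_loglik(
    subject: Subject,
    ind_params: pk.IndividualParams,
    err: ErrorModel,
    bloq_policy: str = "discard",
) -> float:
    """Log-likelihood of one animal's data at fixed individual parameters.

    Gaussian log-density of log(observed) around log(predicted) with SD
    ``err.b``, summed over retained observations; under the censored
    ("M3") policy BLOQ records add a Phi(log LOQ) term.
    """
    t, y, ct, clloq = _subject_arrays(subject, bloq_policy)
    if t.size == 0:
        raise ValueError(
            f"subject {subject.subject_id}: no quantified observations "
            "retained under the current BLOQ policy"
        )
    f = pk.concentration(ind_params, subject.dose, t)
    resid = np.log(y) - np.log(np.maximum(f, 1e-300))
    b = err.b
    ll = float(np.sum(-0.5 * np.log(2 * np.pi * b * b) - resid**2 / (2 * b * b)))
    if ct.size:
        fc = pk.concentration(ind_params, subject.dose, ct)
        ll += float(np.sum(log_ndtr((np.log(clloq) - np.log(np.maximum(fc, 1e-300))) / b)))
    return ll


def marginal_loglik(
    subject: Subject,
    pop: PopPKParams,
    re: RandomEffectsSpec,
    err: ErrorModel,
    method: str = "laplace",
    n_nodes: int = 64,
    bloq_policy: str = "discard",
) -> float:
    """Marginal log-likelihood of one animal, integrating out the CL
    random effect (Laplace by default, adaptive Gauss-Hermite with
    ``method='agq'``)."""
    model = PopPKModel(
        PKDataset.from_subjects([subject]),
        structure="one_compartment" if pop.is_one_compartment else "two_compartment",
        bloq_policy=bloq_policy,
        ref_bw=pop.ref_bw, exp_cl=pop.exp_cl, exp_v=pop.exp_v,
        _allow_small=True,
    )
    params = dict(cl=pop.cl_ref, v1=pop.v1_ref, b=err.b, omega=re.omega_cl)
    if not pop.is_one_compartment:
        params.update(q=pop.q_ref, v2=pop.v2_ref)
    return model.loglik(params, method=method, n_nodes=n_nodes)


# ---------------------------------------------------------------------------


class PopPKModel:
    """Population PK mixed-effects model bound to a dataset.

    Parameters
    ----------
    dataset : PKDataset or DataFrame in the longitudinal CSV dialect.
    structure : ``"one_compartment"`` or ``"two_compartment"``.
    bloq_policy : ``"discard"`` (M1, default: BLOQ records dropped) or
        ``"censored"`` (M3: BLOQ records contribute Phi(log LOQ) terms).
    ref_bw, exp_cl, exp_v : allometric covariate model (reference body
        weight in g; exponents for clearances and volumes).
    bicc_penalty : ``"hybrid"`` (default), ``"n_subjects"`` or ``"n_obs"``.
    """

    def __init__(
        self,
        dataset,
        structure: str = "two_compartment",
        *,
        bloq_policy: str = "discard",
        ref_bw: float = 25.0,
        exp_cl: float = 0.75,
        exp_v: float = 1.0,
        bicc_penalty: str = "hybrid",
        _allow_small: bool = False,
    ):
        if isinstance(dataset, pd.DataFrame):
            dataset = PKDataset(dataset)
        if not isinstance(dataset, PKDataset):
            raise TypeError("dataset must be a PKDataset or DataFrame")
        structure = _ALIASES.get(structure, structure)
        if structure not in _STRUCTURES:
            raise ValueError(f"unknown model structure {structure!r}")
        if bloq_policy not in ("discard", "censored"):
            raise ValueError("bloq_policy must be 'discard' or 'censored'")
        self.dataset = dataset
        self.structure = structure
        self.bloq_policy = bloq_policy
        self.ref_bw = float(ref_bw)
        self.exp_cl = float(exp_cl)
        self.exp_v = float(exp_v)
        self.bicc_penalty = bicc_penalty

        subs = dataset.subjects
        obs_sidx, obs_t, obs_logy = [], [], []
        cens_sidx, cens_t, cens_loglloq = [], [], []
        doses, scl, sv, ids, n_per = [], [], [], [], []
        for i, s in enumerate(subs):
            t, y, ct, clloq = _subject_arrays(s, bloq_policy)
            obs_sidx.append(np.full(t.size, i))
            obs_t.append(t)
            obs_logy.append(np.log(y))
            cens_sidx.append(np.full(ct.size, i))
            cens_t.append(ct)
            cens_loglloq.append(np.log(clloq) if ct.size else clloq)
            doses.append(s.dose)
            scl.append((s.bw / self.ref_bw) ** self.exp_cl)
            sv.append((s.bw / self.ref_bw) ** self.exp_v)
            ids.append(s.subject_id)
            n_per.append(t.size)
        self.subject_ids = ids
        self.n_subjects = len(subs)
        self._n_per_subject = np.asarray(n_per)
        self._obs_sidx = np.concatenate(obs_sidx).astype(int)
        self._obs_t = np.concatenate(obs_t)
        self._obs_logy = np.concatenate(obs_logy)
        self._cens_sidx = np.concatenate(cens_sidx).astype(int)
        self._cens_t = np.concatenate(cens_t)
        self._cens_loglloq = np.concatenate(cens_loglloq)
        self._dose = np.asarray(doses, dtype=float)
        self._scl = np.asarray(scl, dtype=float)
        self._sv = np.asarray(sv, dtype=float)
        self.n_obs = int(self._obs_t.size)
        if not _allow_small:
            usable = self._n_per_subject >= 2
            if self.n_subjects < 2 or not usable.all():
                raise ValueError(
                    "population fitting requires >=2 subjects with >=2 "
                    "quantified observations each"
                )
        self._eta_warm = np.zeros(self.n_subjects)

    # -- parameter bookkeeping -------------------------------------------
    @property
    def param_names(self) -> tuple[str, ...]:
        return _STRUCTURES[self.structure] + ("b", "omega")

    def individual_params(self, params: dict, eta: float = 0.0, subject: int = 0):
        """Per-animal disposition parameters at the given random effect."""
        q = params.get("q", 0.0)
        v2 = params.get("v2", 0.0)
        return pk.IndividualParams(
            cl=params["cl"] * self._scl[subject] * math.exp(eta),
            v1=params["v1"] * self._sv[subject],
            q=q * self._scl[subject],
            v2=v2 * self._sv[subject],
        )

    # -- likelihood kernels ----------------------------------------------
    def _predict_rows(self, params: dict, eta: np.ndarray) -> np.ndarray:
        """Predicted concentration at every retained observation row."""
        cl = params["cl"] * self._scl * np.exp(eta)
        v1 = params["v1"] * self._sv
        q = np.full(self.n_subjects, params.get("q", 0.0)) * self._scl
        v2 = np.full(self.n_subjects, params.get("v2", 0.0)) * self._sv
        return _vectorized_biexponential(
            cl, v1, q, v2, self._dose, self._obs_t, self._obs_sidx
        )

    def _loglik_by_subject(self, params: dict, eta: np.ndarray) -> np.ndarray:
        b = params["b"]
        f = self._predict_rows(params, eta)
        resid = self._obs_logy - np.log(np.maximum(f, 1e-300))
        rows = -0.5 * math.log(2 * math.pi * b * b) - resid**2 / (2 * b * b)
        ll = np.bincount(self._obs_sidx, weights=rows, minlength=self.n_subjects)
        if self._cens_t.size:
            cl = params["cl"] * self._scl * np.exp(eta)
            v1 = params["v1"] * self._sv
            q = np.full(self.n_subjects, params.get("q", 0.0)) * self._scl
            v2 = np.full(self.n_subjects, params.get("v2", 0.0)) * self._sv
            fc = _vectorized_biexponential(
                cl, v1, q, v2, self._dose, self._cens_t, self._cens_sidx
            )
            z = (self._cens_loglloq - np.log(np.maximum(fc, 1e-300))) / b
            ll += np.bincount(self._cens_sidx, weights=log_ndtr(z),
                              minlength=self.n_subjects)
        return ll

    def _penalized(self, params: dict, eta: np.ndarray, omega: float) -> np.ndarray:
        return self._loglik_by_subject(params, eta) - eta**2 / (2.0 * omega * omega)

    def _inner_modes(self, params: dict, warm: np.ndarray | None = None):
        """Per-subject posterior modes of eta (damped Newton, vectorized)."""
        omega = params["omega"]
        d = 1e-4
        eta = np.zeros(self.n_subjects) if warm is None else warm.copy()
        g = lambda e: self._penalized(params, e, omega)
        g0 = g(eta)
        for _ in range(30):
            gp = g(eta + d)
            gm = g(eta - d)
            grad = (gp - gm) / (2 * d)
            curv = np.minimum((gp - 2 * g0 + gm) / (d * d), -1e-8)
            step = np.clip(-grad / curv, -2.0, 2.0)
            new = np.clip(eta + step, -12.0, 12.0)
            gn = g(new)
            for _ in range(25):
                worse = gn < g0 - 1e-10
                if not worse.any():
                    break
                step = np.where(worse, 0.5 * step, step)
                new = np.clip(eta + step, -12.0, 12.0)
                gn = g(new)
            moved = np.max(np.abs(new - eta))
            eta, g0 = new, gn
            if moved < 1e-9:
                break
        gp = g(eta + d)
        gm = g(eta - d)
        curv = np.minimum((gp - 2 * g0 + gm) / (d * d), -1e-10)
        return eta, g0, curv

    def _marginal_by_subject(self, params: dict, method: str = "laplace",
                             n_nodes: int = 64,
                             warm: np.ndarray | None = None):
        """Per-subject marginal log-likelihood and the eta modes."""
        omega = params["omega"]
        if omega < 1e-8:
            eta = np.zeros(self.n_subjects)
            return self._loglik_by_subject(params, eta), eta
        eta, g0, curv = self._inner_modes(params, warm)
        if method == "laplace":
            ll = g0 - math.log(omega) - 0.5 * np.log(-curv)
            return ll, eta
        if method == "agq":
            nodes, wts = np.polynomial.hermite.hermgauss(n_nodes)
            sigma = 1.0 / np.sqrt(-curv)
            # adaptive grid centered at the mode, scaled by the curvature
            terms = np.empty((n_nodes, self.n_subjects))
            for k, (x, w) in enumerate(zip(nodes, wts)):
                e_k = eta + math.sqrt(2.0) * sigma * x
                terms[k] = math.log(w) + x * x + self._penalized(params, e_k, omega)
            ll = (
                logsumexp(terms, axis=0)
                + np.log(math.sqrt(2.0) * sigma)
                - math.log(math.sqrt(2.0 * math.pi) * omega)
            )
            return ll, eta
        raise ValueError(f"unknown marginal method {method!r}")

    def loglik(self, params: dict, method: str = "laplace", n_nodes: int = 64) -> float:
        """Total marginal log-likelihood at the given parameter dict."""
        self._check_params(params)
        ll, _ = self._marginal_by_subject(params, method=method, n_nodes=n_nodes)
        return float(ll.sum())

    def _check_params(self, params: dict) -> None:
        for name in self.param_names:
            if name not in params:
                raise ValueError(f"missing parameter {name!r}")
            if name != "omega" and params[name] <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive")
        if params["omega"] < 0:
            raise ValueError("omega must be non-negative")

    # -- initialization ---------------------------------------------------
    def default_init(self) -> dict:
        """Naive two-stage starting values from per-subject log-linear fits.

        Per subject: V1 from the first-sample back-extrapolation, CL from
        dose/AUC (trapezoid plus log-linear tail), and for the
        two-compartment structure a curve-stripping estimate of the fast
        phase; medians across subjects, with heuristic fallbacks when a
        subject is too sparse or the stripping fails.
        """
        cls, v1s, qs, v2s = [], [], [], []
        for i in range(self.n_subjects):
            m = self._obs_sidx == i
            t = self._obs_t[m]
            logy = self._obs_logy[m]
            if t.size < 2:
                continue
            y = np.exp(logy)
            v1_i = self._dose[i] / y[0]
            n_tail = max(3, t.size // 2) if t.size >= 3 else 2
            tt, ty = t[-n_tail:], logy[-n_tail:]
            slope, inter = np.polyfit(tt, ty, 1)
            beta_hat = -slope
            auc = np.trapezoid(y, t)
            if beta_hat > 0:
                auc += y[-1] / beta_hat
            cl_i = self._dose[i] / auc if auc > 0 else np.nan
            if self.structure == "two_compartment":
                cl_i, v1_i, q_i, v2_i = self._strip_two_cpt(
                    t, y, beta_hat, inter, cl_i, v1_i, i)
                qs.append(q_i / self._scl[i])
                v2s.append(v2_i / self._sv[i])
            cls.append(cl_i / self._scl[i])
            v1s.append(v1_i / self._sv[i])
        init = dict(
            cl=float(np.nanmedian(cls)),
            v1=float(np.nanmedian(v1s)),
            b=0.3,
            omega=0.2,
        )
        if self.structure == "two_compartment":
            init["q"] = float(np.nanmedian(qs))
            init["v2"] = float(np.nanmedian(v2s))
        for k, v in init.items():
            lo, hi = np.exp(_LOG_BOUNDS[k])
            if not np.isfinite(v) or v <= 0:
                v = {"cl": 1.0, "v1": 10.0, "q": 0.5, "v2": 20.0,
                     "b": 0.3, "omega": 0.2}[k]
            init[k] = float(np.clip(v, lo * 10, hi / 10))
        # start the residual SD at the empirical misfit of the structural
        # init (a b far below the actual residual scale invites a
        # degenerate flat-curve optimum), and omega at the between-subject
        # spread of the per-subject clearance estimates
        with np.errstate(all="ignore"):
            f0 = self._predict_rows({**init, "q": init.get("q", 0.0),
                                     "v2": init.get("v2", 0.0)},
                                    np.zeros(self.n_subjects))
            resid = self._obs_logy - np.log(np.maximum(f0, 1e-300))
            if np.all(np.isfinite(resid)) and resid.size > 1:
                init["b"] = float(np.clip(np.std(resid, ddof=1), 0.05, 2.0))
            log_cls = np.log(np.asarray(cls, dtype=float))
            log_cls = log_cls[np.isfinite(log_cls)]
            if log_cls.size > 1:
                init["omega"] = float(np.clip(np.std(log_cls, ddof=1),
                                              0.02, 1.5))
        return init

    def _strip_two_cpt(self, t, y, beta_hat, log_b_inter, cl_i, v1_i, i):
        """Curve stripping of the fast phase; heuristic fallback.

        Returns (cl, v1, q, v2).  The stripped back-extrapolation
        dose/(A+B) corrects the central volume for fast-phase decay that
        the first post-dose sample has already undergone.
        """
        fallback = (cl_i, v1_i, 0.5 * cl_i, 2.0 * v1_i)
        try:
            if beta_hat <= 0:
                return fallback
            b_coef = math.exp(log_b_inter)
            early = t < np.median(t)
            resid = y[early] - b_coef * np.exp(-beta_hat * t[early])
            ok = resid > 0
            if ok.sum() < 2:
                return fallback
            slope_a, inter_a = np.polyfit(t[early][ok], np.log(resid[ok]), 1)
            alpha_hat = -slope_a
            a_coef = math.exp(inter_a)
            if alpha_hat <= beta_hat:
                return fallback
            mac = pk.MacroConstants(alpha=alpha_hat, beta=beta_hat,
                                    coef_a=a_coef, coef_b=b_coef)
            mic = pk.micro_from_macro(mac)
            v1_hat = self._dose[i] / (a_coef + b_coef)
            cl_hat = mic.k10 * v1_hat
            q_hat = mic.k12 * v1_hat
            v2_hat = q_hat / mic.k21 if mic.k21 > 0 else 2.0 * v1_i
            if min(cl_hat, v1_hat, q_hat, v2_hat) <= 0:
                return fallback
            return cl_hat, v1_hat, q_hat, v2_hat
        except (ValueError, OverflowError, FloatingPointError):
            return fallback

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        init: dict | None = None,
        fix: dict | None = None,
        method: str = "laplace",
        maxiter: int = 500,
        tol: float = 1e-8,
    ) -> "PopPKResults":
        """Maximize the total marginal log-likelihood.

        ``init`` overrides the naive two-stage starting values; ``fix``
        maps parameter names to frozen values (excluded from optimization,
        penalty counting and RSEs).  Deterministic given (dataset, init,
        fix, tolerances).
        """
        usable = self._n_per_subject >= 2
        if self.n_subjects < 2 or not usable.all():
            raise ValueError(
                "population fitting requires >=2 subjects with >=2 "
                "quantified observations each"
            )
        fix = dict(fix or {})
        start = self.default_init()
        start.update(init or {})
        for k in fix:
            if k not in self.param_names:
                raise ValueError(f"cannot fix unknown parameter {k!r}")
        free = [n for n in self.param_names if n not in fix]
        if not free:
            raise ValueError("no free parameters to optimize")
        x0 = np.array([math.log(max(start[n], 1e-12)) for n in free])
        bounds = [_LOG_BOUNDS[n] for n in free]
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        self._eta_warm = np.zeros(self.n_subjects)

        def assemble(x):
            p = {n: math.exp(v) for n, v in zip(free, x)}
            p.update(fix)
            return p

        def objective(x):
            p = assemble(x)
            if p.get("omega", 0.0) < 1e-8:
                ll = float(self._loglik_by_subject(p, np.zeros(self.n_subjects)).sum())
            else:
                ll_s, eta = self._marginal_by_subject(p, method=method,
                                                     warm=self._eta_warm)
                self._eta_warm = eta
                ll = float(ll_s.sum())
            if not np.isfinite(ll):
                return 1e12
            return -ll

        lo = np.array([b_[0] for b_ in bounds])
        hi = np.array([b_[1] for b_ in bounds])

        def boxed(x):
            if np.any(x < lo) or np.any(x > hi):
                return 1e12 + float(np.sum(np.maximum(lo - x, 0)
                                           + np.maximum(x - hi, 0)))
            return objective(x)

        def lbfgsb(x):
            return optimize.minimize(
                objective, np.clip(x, lo, hi), method="L-BFGS-B",
                bounds=bounds,
                options=dict(maxiter=maxiter, ftol=tol * 1e-4, gtol=1e-7,
                             eps=1e-6),
            )

        # second start at generic noise magnitudes guards against basins
        # where structural misfit is absorbed into the residual error
        starts = [x0]
        user_init = init or {}
        alt = dict(zip(free, x0))
        changed = False
        for n, v in (("b", 0.3), ("omega", 0.2)):
            if n in alt and n not in user_init and \
                    abs(alt[n] - math.log(v)) > 0.2:
                alt[n] = math.log(v)
                changed = True
        res = lbfgsb(x0)
        suspicious = (
            not res.success
            or float(np.max(np.abs(res.x - x0))) < 0.1  # barely moved
            or assemble(res.x).get("b", 0.0) > 0.8      # absurd residual SD
        )
        if changed and suspicious:
            res = min([res, lbfgsb(np.array([alt[n] for n in free]))],
                      key=lambda r: (r.fun, not r.success))
        if not res.success:
            # derivative-free polish plus restart for line-search failures
            # caused by the (slightly noisy) finite-difference gradient
            polish = optimize.minimize(
                boxed, res.x, method="Nelder-Mead",
                options=dict(maxfev=2500, xatol=1e-7, fatol=1e-9),
            )
            if polish.fun <= res.fun:
                res = polish
            if not res.success:
                retry = lbfgsb(res.x)
                if retry.success or retry.fun <= res.fun:
                    res = retry
        success = bool(res.success)
        if not success:
            # optimizer flags can be pessimistic (noisy finite-difference
            # line searches); accept a stationary point by checking the
            # projected gradient directly
            h = 1e-5
            grad = np.empty(len(res.x))
            for i in range(len(res.x)):
                e = np.zeros(len(res.x))
                e[i] = h
                grad[i] = (boxed(res.x + e) - boxed(res.x - e)) / (2 * h)
            at_lo = res.x - lo < 1e-6
            at_hi = hi - res.x < 1e-6
            proj = np.where(at_lo, np.minimum(grad, 0.0),
                            np.where(at_hi, np.maximum(grad, 0.0), grad))
            success = bool(np.max(np.abs(proj)) < 5e-2)
        params = assemble(res.x)
        boundary = [
            n for n, v, (lo, hi) in zip(free, res.x, bounds)
            if v - lo < 1e-4 or hi - v < 1e-4
        ]
        ll_s, eta = self._marginal_by_subject(params, method=method,
                                              warm=self._eta_warm)
        llf = float(ll_s.sum())
        converged = bool(success and np.isfinite(llf))
        if not converged:
            warnings.warn(
                f"optimizer did not report convergence: {res.message}",
                RuntimeWarning, stacklevel=2,
            )
        k_random = 0 if "omega" in fix else 1
        k_other = len(free) - k_random
        value_bicc = bicc(llf, self.n_subjects, self.n_obs + self._cens_t.size,
                          k_other, k_random, penalty=self.bicc_penalty)
        return PopPKResults(
            model=self, params=params, free_names=tuple(free),
            fixed=dict(fix), llf=llf, bicc=value_bicc, ebes=eta,
            converged=converged, boundary=tuple(boundary),
            optimizer_message=str(res.message), n_iter=int(res.nit),
            method=method,
        )

    def evaluate(self, params: dict, method: str = "laplace") -> "PopPKResults":
        """Build a results object at known parameter values (no fitting).

        Useful for diagnostics of externally supplied estimates and for
        reloading a saved fit.
        """
        self._check_params(params)
        ll_s, eta = self._marginal_by_subject(params, method=method)
        llf = float(ll_s.sum())
        free = tuple(self.param_names)
        value_bicc = bicc(llf, self.n_subjects, self.n_obs + self._cens_t.size,
                          len(free) - 1, 1, penalty=self.bicc_penalty)
        return PopPKResults(
            model=self, params=dict(params), free_names=free, fixed={},
            llf=llf, bicc=value_bicc, ebes=eta, converged=True, boundary=(),
            optimizer_message="evaluated at fixed parameters", n_iter=0,
            method=method,
        )


def bicc(loglik: float, n_subjects: int, n_obs: int, n_fixed: int,
         n_random: int, penalty: str = "hybrid") -> float:
    """Corrected BIC: -2 loglik plus a structure-aware sample-size penalty.

    ``hybrid`` penalizes random-effect parameters with ln(n_subjects) and
    fixed-effect/residual parameters with ln(n_obs); the alternatives use a
    single sample size for every parameter.
    """
    if penalty == "hybrid":
        pen = n_fixed * math.log(n_obs) + n_random * math.log(n_subjects)
    elif penalty == "n_subjects":
        pen = (n_fixed + n_random) * math.log(n_subjects)
    elif penalty == "n_obs":
        pen = (n_fixed + n_random) * math.log(n_obs)
    else:
        raise ValueError(f"unknown BICc penalty {penalty!r}")
    return -2.0 * loglik + pen


class PopPKResults:
    """Estimation results: estimates, uncertainties, diagnostics hooks.

    Attributes
    ----------
    params : dict of natural-scale estimates (cl, v1, [q, v2], b, omega).
    llf : maximized total marginal log-likelihood.
    bicc : corrected BIC of the fit.
    ebes : per-subject empirical Bayes estimates of the CL random effect.
    converged, boundary : convergence status and names of parameters at
        their bounds (boundary estimates flag unidentifiable structure).
    """

    def __init__(self, model, params, free_names, fixed, llf, bicc, ebes,
                 converged, boundary, optimizer_message, n_iter, method):
        self.model = model
        self.params = params
        self.free_names = free_names
        self.fixed = fixed
        self.llf = llf
        self.bicc = bicc
        self.ebes = np.asarray(ebes)
        self.converged = converged
        self.boundary = boundary
        self.optimizer_message = optimizer_message
        self.n_iter = n_iter
        self.method = method
        self._cov_log = None
        self._rse = None

    # -- domain views -----------------------------------------------------
    @property
    def pop_params(self) -> PopPKParams:
        m = self.model
        if m.structure == "one_compartment":
            return PopPKParams.one_compartment(
                self.params["cl"], self.params["v1"], ref_bw=m.ref_bw,
                exp_cl=m.exp_cl, exp_v=m.exp_v,
            )
        return PopPKParams(
            cl_ref=self.params["cl"], v1_ref=self.params["v1"],
            q_ref=self.params["q"], v2_ref=self.params["v2"],
            ref_bw=m.ref_bw, exp_cl=m.exp_cl, exp_v=m.exp_v,
        )

    @property
    def error_model(self) -> ErrorModel:
        return ErrorModel(b=self.params["b"])

    @property
    def random_effects(self) -> RandomEffectsSpec:
        return RandomEffectsSpec(omega_cl=self.params["omega"])

    @property
    def n_params(self) -> int:
        return len(self.free_names)

    def half_lives(self, bw: float | None = None) -> tuple[float, float]:
        """Disposition half-lives (min) of the typical animal."""
        ind = pk.apply_allometry(self.pop_params, bw or self.model.ref_bw)
        dose = float(np.median(self.model._dose))
        return pk.half_lives(pk.macro_constants(ind, dose))

    @property
    def ebes_by_subject(self) -> dict:
        return dict(zip(self.model.subject_ids, self.ebes.tolist()))

    # -- uncertainty ------------------------------------------------------
    def _numeric_hessian(self, h: float = 1e-4) -> np.ndarray:
        free = self.free_names
        x0 = np.array([math.log(self.params[n]) for n in free])

        def nll(x):
            p = {n: math.exp(v) for n, v in zip(free, x)}
            p.update(self.fixed)
            return -self.model.loglik(p, method=self.method)

        k = len(free)
        H = np.empty((k, k))
        f0 = nll(x0)
        for i in range(k):
            ei = np.zeros(k)
            ei[i] = h
            H[i, i] = (nll(x0 + ei) - 2 * f0 + nll(x0 - ei)) / (h * h)
            for j in range(i + 1, k):
                ej = np.zeros(k)
                ej[j] = h
                H[i, j] = H[j, i] = (
                    nll(x0 + ei + ej) - nll(x0 + ei - ej)
                    - nll(x0 - ei + ej) + nll(x0 - ei - ej)
                ) / (4 * h * h)
        return H

    @property
    def cov_log(self) -> np.ndarray:
        """Covariance of the log-scale estimates from the observed Fisher
        information (numerically differentiated at the optimum)."""
        if self._cov_log is None:
            H = self._numeric_hessian()
            try:
                cov = np.linalg.inv(H)
                if np.any(np.diag(cov) <= 0):
                    raise np.linalg.LinAlgError("non-positive variances")
            except np.linalg.LinAlgError:
                warnings.warn(
                    "observed information is not positive definite; "
                    "RSEs are reported only where defined",
                    RuntimeWarning, stacklevel=2,
                )
                cov = np.linalg.pinv(H)
                d = np.diag(cov).copy()
                d[d <= 0] = np.nan
                cov = cov.copy()
                np.fill_diagonal(cov, d)
            self._cov_log = cov
        return self._cov_log

    @property
    def rse_percent(self) -> dict:
        """Relative standard errors (%), delta method on the log scale.

        For log-normal parameters 100*SE(log estimate) is the relative SE
        of the natural-scale estimate.  Boundary estimates (e.g. omega
        collapsed to zero) are reported as missing.
        """
        if self._rse is None:
            d = np.sqrt(np.diag(self.cov_log))
            rse = {n: 100.0 * s for n, s in zip(self.free_names, d)}
            for n in self.boundary:
                rse[n] = float("nan")
            self._rse = rse
        return dict(self._rse)

    # -- reporting --------------------------------------------------------
    _LABELS = {
        "cl": ("CL", "mL/min", "elimination clearance"),
        "v1": ("V1", "mL", "central volume"),
        "q": ("Q", "mL/min", "distribution clearance"),
        "v2": ("V2", "mL", "peripheral volume"),
        "b": ("b", "", "residual SD (log scale)"),
        "omega": ("omega_CL", "", "BSV SD on log CL"),
    }

    def summary(self) -> str:
        m = self.model
        rse = self.rse_percent
        lines = [
            "Population PK mixed-effects fit (Laplace marginal likelihood)",
            "=" * 62,
            f"structure: {m.structure}   subjects: {m.n_subjects}   "
            f"observations: {m.n_obs}",
            f"BLOQ policy: {m.bloq_policy}   allometry: CL~BW^{m.exp_cl}, "
            f"V~BW^{m.exp_v} (ref {m.ref_bw} g)",
            f"log-likelihood: {self.llf:.3f}   BICc: {self.bicc:.2f}   "
            f"converged: {self.converged}",
            "-" * 62,
            f"{'parameter':<12}{'estimate':>12}{'RSE%':>9}  unit/meaning",
        ]
        for n in self.free_names:
            sym, unit, desc = self._LABELS[n]
            r = rse.get(n, float("nan"))
            rs = f"{r:9.1f}" if np.isfinite(r) else "      --"
            lines.append(f"{sym:<12}{self.params[n]:>12.4g}{rs}  {unit} {desc}")
        for n, v in self.fixed.items():
            sym, unit, desc = self._LABELS[n]
            lines.append(f"{sym:<12}{v:>12.4g}{'fixed':>9}  {unit} {desc}")
        if "omega" in self.free_names:
            lines.append(
                f"{'BSV CV%':<12}{self.random_effects.cv_percent:>12.4g}"
                f"{'':>9}  between-animal CV of CL"
            )
        if m.structure == "two_compartment" and "q" in self.params:
            th_a, th_b = self.half_lives()
            lines.append(f"disposition half-lives: {th_a:.4g} min (fast), "
                         f"{th_b:.4g} min (slow)")
        if self.boundary:
            lines.append(f"boundary estimates: {', '.join(self.boundary)}")
        lines.append("=" * 62)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return dict(
            structure=self.model.structure,
            estimates={k: float(v) for k, v in self.params.items()},
            fixed={k: float(v) for k, v in self.fixed.items()},
            rse_percent={k: (float(v) if np.isfinite(v) else None)
                         for k, v in self.rse_percent.items()},
            cv_percent=float(self.random_effects.cv_percent),
            loglik=float(self.llf),
            bicc=float(self.bicc),
            ebes={str(k): float(v) for k, v in self.ebes_by_subject.items()},
            converged=bool(self.converged),
            boundary=list(self.boundary),
            n_subjects=int(self.model.n_subjects),
            n_obs=int(self.model.n_obs),
            bloq_policy=self.model.bloq_policy,
        )

    def to_json(self, path=None, **extra) -> str:
        payload = {**self.to_dict(), **extra}
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    # -- simulation & diagnostics (delegates) -----------------------------
    def simulate(self, n_sim: int, seed: int = 0) -> np.ndarray:
        from .diagnostics import simulate_replicates

        return simulate_replicates(self, n_sim=n_sim, seed=seed)

    def vpc(self, n_sim: int = 500, seed: int = 0, **kw):
        from .diagnostics import run_vpc

        return run_vpc(self, n_sim=n_sim, seed=seed, **kw)

    def npde(self, n_sim: int = 1000, seed: int = 0, **kw):
        from .diagnostics import compute_npde

        return compute_npde(self, n_sim=n_sim, seed=seed, **kw)

    def gof_table(self) -> pd.DataFrame:
        from .diagnostics import gof_tables

        return gof_tables(self)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<PopPKResults {self.model.structure} llf={self.llf:.2f} "
                f"bicc={self.bicc:.1f} converged={self.converged}>")


# ---------------------------------------------------------------------------
# spec-surface wrappers

def fit_population(dataset, model_structure: str = "two_compartment",
                   init: dict | None = None, config: dict | None = None) -> PopPKResults:
    """Fit the population model on a dataset (thin wrapper over
    :class:`PopPKModel`)."""
    cfg = dict(config or {})
    model = PopPKModel(
        dataset, structure=model_structure,
        bloq_policy=cfg.pop("bloq_policy", "discard"),
        ref_bw=cfg.pop("ref_bw", 25.0),
        exp_cl=cfg.pop("exp_cl", 0.75),
        exp_v=cfg.pop("exp_v", 1.0),
        bicc_penalty=cfg.pop("bicc_penalty", "hybrid"),
    )
    return model.fit(init=init, **cfg)


def compute_rse(fit: PopPKResults) -> dict:
    """Relative standard errors (%) from the observed Fisher information."""
    if not fit.converged:
        raise ValueError("RSEs require a converged fit")
    return fit.rse_percent


def compute_bicc(fit: PopPKResults) -> float:
    if not fit.converged:
        raise ValueError("BICc requires a converged fit")
    return fit.bicc


def select_model(fits: list[PopPKResults]) -> PopPKResults:
    """Pick the fit with the lowest BICc; ties favor fewer parameters.

    All candidates must be fits of the same dataset.
    """
    if len(fits) < 2:
        raise ValueError("model selection requires at least two fits")
    if not all(f.converged for f in fits):
        raise ValueError("model selection requires converged fits")
    hashes = {f.model.dataset.content_hash() for f in fits}
    if len(hashes) > 1:
        raise ValueError("fits were not obtained on the same dataset")
    return min(fits, key=lambda f: (round(f.bicc, 10), f.n_params))
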