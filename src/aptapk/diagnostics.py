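"""Simulation-based model evaluation: VPC, NPDE and goodness-of-fit tables.

All diagnostics simulate replicate datasets from a fitted (or evaluated)
:class:`~aptapk.nlme.PopPKResults` under the original study design —
same animals, body weights, doses and retained sampling times — and are
bit-for-bit reproducible given (fit, dataset, seed, n_sim).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pk import _vectorized_biexponential

__all__ = [
    "simulate_replicates",
    "run_vpc",
    "compute_npde",
    "gof_tables",
    "VPCResult",
    "NPDEResult",
    "plot_vpc",
    "plot_npde",
]


def simulate_replicates(results, n_sim: int, seed: int = 0) -> np.ndarray:
    """Simulate concentrations at every retained observation row.

    Returns an (n_sim, n_obs) array.  Per replicate, fresh CL random
    effects and residual errors are drawn at the fitted estimates; rows
    follow the order of the model's retained observations.  Values are
    returned uncensored: under the discard BLOQ policy the retained design
    rows are by construction the quantified ones, and rank-based
    diagnostics need numeric values.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be positive")
    m = results.model
    p = results.params
    rng = np.random.default_rng(seed)
    omega = p.get("omega", 0.0)
    b = p["b"]
    n_subj, n_obs = m.n_subjects, m.n_obs
    eta = rng.normal(0.0, omega, size=(n_sim, n_subj)) if omega > 0 else \
        np.zeros((n_sim, n_subj))
    out = np.empty((n_sim, n_obs))
    q = np.full(n_subj, p.get("q", 0.0)) * m._scl
    v2 = np.full(n_subj, p.get("v2", 0.0)) * m._sv
    v1 = p["v1"] * m._sv
    for r in range(n_sim):
        cl = p["cl"] * m._scl * np.exp(eta[r])
        f = _vectorized_biexponential(cl, v1, q, v2, m._dose, m._obs_t, m._obs_sidx)
        eps = rng.standard_normal(n_obs) if b > 0 else np.zeros(n_obs)
        out[r] = f * np.exp(b * eps)
    return out


@dataclass
class VPCResult:
    """Visual predictive check: observed percentiles per time bin with
    simulated 90% confidence bands for each percentile."""

    bin_times: np.ndarray            # representative time per bin (min)
    bin_counts: np.ndarray
    percentiles: tuple               # e.g. (5, 50, 95)
    obs_percentiles: np.ndarray      # (n_bins, n_pct)
    sim_band_lo: np.ndarray          # (n_bins, n_pct) lower 90% band edge
    sim_band_hi: np.ndarray          # (n_bins, n_pct) upper 90% band edge
    n_sim: int
    seed: int

    def median_coverage(self) -> float:
        """Fraction of bins whose observed median lies inside the
        simulated band for the median."""
        j = list(self.percentiles).index(50)
        med = self.obs_percentiles[:, j]
        inside = (med >= self.sim_band_lo[:, j]) & (med <= self.sim_band_hi[:, j])
        return float(inside.mean())

    def band_width(self) -> float:
        """Mean log-scale width of the median band (spread diagnostic)."""
        j = list(self.percentiles).index(50)
        return float(np.mean(np.log(self.sim_band_hi[:, j])
                             - np.log(np.maximum(self.sim_band_lo[:, j], 1e-300))))

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        rows["time"] = self.bin_times
        rows["n_obs"] = self.bin_counts
        for j, q in enumerate(self.percentiles):
            rows[f"obs_p{q}"] = self.obs_percentiles[:, j]
            rows[f"sim_p{q}_lo"] = self.sim_band_lo[:, j]
            rows[f"sim_p{q}_hi"] = self.sim_band_hi[:, j]
        return pd.DataFrame(rows)


def _bin_assignments(times: np.ndarray, bin_edges=None, min_count: int = 1):
    """Bin observation times: nominal unique-time bins by default, or
    user edges with empty bins merged into their neighbor."""
    if bin_edges is None:
        uniq = np.unique(times)
        idx = np.searchsorted(uniq, times)
        return idx, uniq
    edges = np.asarray(bin_edges, dtype=float)
    idx = np.clip(np.digitize(times, edges) - 1, 0, len(edges) - 2)
    keep = []
    for k in range(len(edges) - 1):
        if np.sum(idx == k) >= min_count:
            keep.append(k)
        else:
            warnings.warn(f"empty time bin [{edges[k]}, {edges[k + 1]}) merged "
                          "with neighbor", UserWarning, stacklevel=3)
    if not keep:
        raise ValueError("no non-empty time bins")
    keep = np.asarray(keep)
    remap = np.searchsorted(keep, np.clip(idx, keep.min(), keep.max()))
    remap = np.clip(remap, 0, len(keep) - 1)
    centers = np.array([times[remap == k].mean() for k in range(len(keep))])
    return remap, centers


def run_vpc(results, n_sim: int = 500, seed: int = 0, bin_edges=None,
            percentiles=(5, 50, 95)) -> VPCResult:
    """Visual predictive check of a fitted model.

    Simulates ``n_sim`` replicate cohorts under the fitted model and the
    original design, then compares observed percentiles per time bin with
    the simulated 90% confidence band of each percentile.  Default
    binning groups observations by their nominal sampling times.
    """
    if n_sim < 100:
        raise ValueError("VPC requires n_sim >= 100")
    if 50 not in percentiles:
        raise ValueError("percentiles must include the median (50)")
    m = results.model
    obs = np.exp(m._obs_logy)
    idx, centers = _bin_assignments(m._obs_t, bin_edges)
    n_bins = len(centers)
    sims = simulate_replicates(results, n_sim=n_sim, seed=seed)
    pct = np.asarray(percentiles, dtype=float)
    obs_p = np.empty((n_bins, pct.size))
    sim_p = np.empty((n_sim, n_bins, pct.size))
    counts = np.empty(n_bins, dtype=int)
    for k in range(n_bins):
        mask = idx == k
        counts[k] = mask.sum()
        obs_p[k] = np.percentile(obs[mask], pct)
        sim_p[:, k, :] = np.percentile(sims[:, mask], pct, axis=1).T
    lo = np.percentile(sim_p, 5, axis=0)
    hi = np.percentile(sim_p, 95, axis=0)
    return VPCResult(
        bin_times=centers, bin_counts=counts, percentiles=tuple(percentiles),
        obs_percentiles=obs_p, sim_band_lo=lo, sim_band_hi=hi,
        n_sim=n_sim, seed=seed,
    )


@dataclass
class NPDEResult:
    """Normalized prediction distribution errors per retained observation."""

    npde: np.ndarray
    subject_ids: np.ndarray
    times: np.ndarray
    n_sim: int
    seed: int
    summary: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(ID=self.subject_ids, TIME=self.times,
                                 NPDE=self.npde))


def compute_npde(results, n_sim: int = 1000, seed: int = 0,
                 ridge: float = 1e-8) -> NPDEResult:
    """Normalized prediction distribution errors.

    Per subject, observed and simulated log-concentration vectors are
    decorrelated with the inverse Cholesky factor of the empirical
    simulated covariance; the observed decorrelated value is ranked within
    the simulated ones and the midpoint rank fraction (k+0.5)/(K+1) is
    mapped through the standard-normal quantile.  Under a correct model
    the NPDE are approximately iid N(0,1).
    """
    if n_sim < 500:
        raise ValueError("NPDE requires n_sim >= 500")
    m = results.model
    sims_log = np.log(np.maximum(simulate_replicates(results, n_sim, seed), 1e-300))
    obs_log = m._obs_logy
    npde = np.empty(m.n_obs)
    for i in range(m.n_subjects):
        mask = m._obs_sidx == i
        y = obs_log[mask]
        S = sims_log[:, mask]
        mu = S.mean(axis=0)
        cov = np.cov(S, rowvar=False)
        cov = np.atleast_2d(cov)
        scale = max(np.trace(cov) / cov.shape[0], 1e-12)
        for attempt in range(6):
            try:
                L = np.linalg.cholesky(cov + np.eye(cov.shape[0])
                                       * ridge * scale * 10**attempt)
                break
            except np.linalg.LinAlgError:
                if attempt == 0:
                    warnings.warn(
                        f"singular simulated covariance for subject "
                        f"{m.subject_ids[i]}; ridge-regularized",
                        RuntimeWarning, stacklevel=2,
                    )
        else:  # pragma: no cover
            raise np.linalg.LinAlgError("covariance regularization failed")
        y_dec = np.linalg.solve(L, y - mu)
        s_dec = np.linalg.solve(L, (S - mu).T)  # (n_i, n_sim)
        ranks = (s_dec < y_dec[:, None]).sum(axis=1)
        pde = (ranks + 0.5) / (n_sim + 1.0)
        npde[mask] = stats.norm.ppf(pde)
    summary = dict(mean=float(npde.mean()), variance=float(npde.var(ddof=1)))
    if npde.size >= 20:
        stat, pval = stats.normaltest(npde)
        summary.update(normality_stat=float(stat), normality_pvalue=float(pval))
    return NPDEResult(
        npde=npde,
        subject_ids=np.asarray(m.subject_ids, dtype=object)[m._obs_sidx],
        times=m._obs_t.copy(),
        n_sim=n_sim, seed=seed, summary=summary,
    )


def gof_tables(results) -> pd.DataFrame:
    """Per-observation goodness-of-fit table.

    Columns: observed value, population prediction (random effect at
    zero), individual prediction (at the empirical Bayes estimate), and
    the corresponding weighted residuals on the log scale,
    (log y - log f)/b.
    """
    m = results.model
    p = results.params
    b = p["b"]
    f_pop = m._predict_rows(p, np.zeros(m.n_subjects))
    f_ind = m._predict_rows(p, results.ebes)
    logy = m._obs_logy
    return pd.DataFrame(
        dict(
            ID=np.asarray(m.subject_ids, dtype=object)[m._obs_sidx],
            TIME=m._obs_t,
            DV=np.exp(logy),
            PRED=f_pop,
            IPRED=f_ind,
            PWRES=(logy - np.log(np.maximum(f_pop, 1e-300))) / b,
            IWRES=(logy - np.log(np.maximum(f_ind, 1e-300))) / b,
        )
    )


# ---------------------------------------------------------------------------
# optional plotting


def plot_vpc(vpc: VPCResult, ax=None):
    """Observed percentiles over simulated bands, log-log axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for j, q in enumerate(vpc.percentiles):
        ax.fill_between(vpc.bin_times, vpc.sim_band_lo[:, j],
                        vpc.sim_band_hi[:, j], alpha=0.25,
                        label=f"simulated 90% band, p{q}")
        ax.plot(vpc.bin_times, vpc.obs_percentiles[:, j], "o-",
                label=f"observed p{q}")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("concentration (µg/mL)")
    ax.legend(fontsize=7)
    return ax


def plot_npde(npde: NPDEResult, axes=None):
    """Histogram and normal QQ plot of the NPDE."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    axes[0].hist(npde.npde, bins=30, density=True, alpha=0.7)
    grid = np.linspace(-4, 4, 200)
    axes[0].plot(grid, stats.norm.pdf(grid), "k--")
    axes[0].set_xlabel("NPDE")
    stats.probplot(npde.npde, dist="norm", plot=axes[1])
    return axes
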