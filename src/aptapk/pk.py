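"""Closed-form compartmental kinetics for an IV-bolus probe.

One- and two-compartment disposition with first-order rate constants,
parameterized by clearances and volumes (the pharmacometric convention:
all parameters strictly positive, log-transformable).  The two-compartment
solution after an intravenous bolus is the biexponential

    C(t) = A e^(-alpha t) + B e^(-beta t),

where (alpha, beta) are the fast/slow disposition rates obtained from the
micro rate constants k10 = CL/V1, k12 = Q/V1, k21 = Q/V2 as the roots of
x^2 - (k10+k12+k21) x + k10 k21 = 0.  Disposition half-lives are
ln2/alpha and ln2/beta.

Covariate scaling is allometric on body weight: clearances scale with
(BW/BW_ref)^0.75 and volumes with (BW/BW_ref)^1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PopPKParams",
    "IndividualParams",
    "MicroConstants",
    "MacroConstants",
    "TumorDims",
    "apply_allometry",
    "micro_from_primary",
    "macro_from_micro",
    "micro_from_macro",
    "half_lives",
    "concentration",
    "amounts",
    "tumor_volume",
]

#: Population estimates for a 25 g mouse: elimination clearance (mL/min),
#: central volume (mL), distribution clearance (mL/min), peripheral volume
#: (mL).  Used as defaults throughout the package and by the synthetic
#: cohort generator.
REFERENCE_ESTIMATES = dict(cl_ref=3.29, v1_ref=81.77, q_ref=1.78, v2_ref=182.2)


@dataclass(frozen=True)
class PopPKParams:
    """Population (typical-animal) disposition parameters with allometry.

    Parameters are referenced to an animal of body weight ``ref_bw`` grams.
    ``exp_cl`` applies to both clearances, ``exp_v`` to both volumes.
    """

    cl_ref: float
    v1_ref: float
    q_ref: float
    v2_ref: float
    ref_bw: float = 25.0
    exp_cl: float = 0.75
    exp_v: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cl_ref", "v1_ref", "ref_bw"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.q_ref < 0 or self.v2_ref < 0:
            raise ValueError("q_ref and v2_ref must be non-negative")
        if (self.q_ref == 0) != (self.v2_ref == 0):
            # one-compartment reduction requires both to vanish together;
            # a positive v2 with q=0 is inert but tolerated
            if self.q_ref > 0 and self.v2_ref == 0:
                raise ValueError("q_ref > 0 requires v2_ref > 0")

    @property
    def is_one_compartment(self) -> bool:
        return self.q_ref == 0.0

    @classmethod
    def reference(cls, **overrides) -> "PopPKParams":
        """The package's default mouse estimates (25 g reference weight)."""
        return cls(**{**REFERENCE_ESTIMATES, **overrides})

    @classmethod
    def one_compartment(cls, cl_ref: float, v1_ref: float, **overrides) -> "PopPKParams":
        return cls(cl_ref=cl_ref, v1_ref=v1_ref, q_ref=0.0, v2_ref=0.0, **overrides)


@dataclass(frozen=True)
class IndividualParams:
    """Per-animal disposition parameters after covariate scaling and
    random effects.  Units as :class:`PopPKParams`."""

    cl: float
    v1: float
    q: float
    v2: float

    def __post_init__(self) -> None:
        if self.cl <= 0 or self.v1 <= 0:
            raise ValueError("cl and v1 must be strictly positive")
        if self.q < 0 or self.v2 < 0:
            raise ValueError("q and v2 must be non-negative")
        if self.q > 0 and self.v2 <= 0:
            raise ValueError("q > 0 requires v2 > 0")


@dataclass(frozen=True)
class MicroConstants:
    """First-order micro rate constants (1/min)."""

    k10: float
    k12: float
    k21: float

    def __post_init__(self) -> None:
        if self.k10 <= 0:
            raise ValueError("k10 must be strictly positive")
        if self.k12 < 0 or self.k21 < 0:
            raise ValueError("k12 and k21 must be non-negative")
        if (self.k12 == 0) != (self.k21 == 0):
            raise ValueError("k12 and k21 must vanish together")


@dataclass(frozen=True)
class MacroConstants:
    """Biexponential macro constants: rates (1/min) and intercepts (µg/mL).

    In the one-compartment reduction ``beta == alpha`` and ``coef_b == 0``
    by convention.
    """

    alpha: float
    beta: float
    coef_a: float
    coef_b: float

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.alpha < self.beta:
            raise ValueError("require alpha >= beta > 0")
        if self.coef_a < 0 or self.coef_b < 0:
            raise ValueError("intercepts must be non-negative")

    @property
    def is_one_compartment(self) -> bool:
        return self.coef_b == 0.0


@dataclass(frozen=True)
class TumorDims:
    """Caliper measurements: W the shorter and L the longer dimension (mm)."""

    width_w: float
    length_l: float

    def __post_init__(self) -> None:
        if self.width_w < 0:
            raise ValueError("width must be non-negative")
        if self.width_w > self.length_l:
            raise ValueError("caliper convention requires W <= L")


def apply_allometry(pop: PopPKParams, bw: float) -> IndividualParams:
    """Scale population parameters to an animal of body weight ``bw`` (g).

    Clearances scale with (bw/ref_bw)**exp_cl, volumes with
    (bw/ref_bw)**exp_v.  At the reference weight this is the identity.
    """
    if bw <= 0:
        raise ValueError("body weight must be strictly positive")
    f_cl = (bw / pop.ref_bw) ** pop.exp_cl
    f_v = (bw / pop.ref_bw) ** pop.exp_v
    return IndividualParams(
        cl=pop.cl_ref * f_cl,
        v1=pop.v1_ref * f_v,
        q=pop.q_ref * f_cl,
        v2=pop.v2_ref * f_v,
    )


def micro_from_primary(ind: IndividualParams) -> MicroConstants:
    """Convert (CL, V1, Q, V2) to micro rate constants."""
    k12 = ind.q / ind.v1
    k21 = ind.q / ind.v2 if ind.v2 > 0 else 0.0
    return MicroConstants(k10=ind.cl / ind.v1, k12=k12, k21=k21)


def macro_from_micro(micro: MicroConstants, dose: float, v1: float) -> MacroConstants:
    """Solve the characteristic quadratic for (alpha, beta) and form the
    bolus intercepts.

    alpha + beta = k10 + k12 + k21 and alpha * beta = k10 * k21; the
    intercepts satisfy coef_a + coef_b = dose / v1 (all drug in the central
    compartment at t=0).  A repeated root collapses to the one-compartment
    convention with a warning.
    """
    if dose <= 0:
        raise ValueError("dose must be strictly positive")
    if v1 <= 0:
        raise ValueError("v1 must be strictly positive")
    k10, k12, k21 = micro.k10, micro.k12, micro.k21
    if k12 == 0.0 and k21 == 0.0:
        return MacroConstants(alpha=k10, beta=k10, coef_a=dose / v1, coef_b=0.0)
    s = k10 + k12 + k21
    disc = s * s - 4.0 * k10 * k21
    if disc <= 0:
        # repeated (or numerically indistinct) root: probability-zero region
        warnings.warn(
            "repeated disposition root; falling back to one-compartment convention",
            RuntimeWarning,
            stacklevel=2,
        )
        rate = 0.5 * s
        return MacroConstants(alpha=rate, beta=rate, coef_a=dose / v1, coef_b=0.0)
    root = math.sqrt(disc)
    alpha = 0.5 * (s + root)
    beta = 0.5 * (s - root)
    coef_a = dose * (alpha - k21) / (v1 * (alpha - beta))
    coef_b = dose * (k21 - beta) / (v1 * (alpha - beta))
    return MacroConstants(alpha=alpha, beta=beta, coef_a=coef_a, coef_b=coef_b)


def micro_from_macro(macro: MacroConstants) -> MicroConstants:
    """Invert :func:`macro_from_micro` (intercept-weighted rate identities)."""
    if macro.is_one_compartment:
        return MicroConstants(k10=macro.alpha, k12=0.0, k21=0.0)
    total = macro.coef_a + macro.coef_b
    k21 = (macro.coef_a * macro.beta + macro.coef_b * macro.alpha) / total
    k10 = macro.alpha * macro.beta / k21
    k12 = macro.alpha + macro.beta - k10 - k21
    return MicroConstants(k10=k10, k12=max(k12, 0.0), k21=k21)


def half_lives(macro: MacroConstants) -> tuple[float, float]:
    """Fast and slow disposition half-lives (min): (ln2/alpha, ln2/beta)."""
    return math.log(2.0) / macro.alpha, math.log(2.0) / macro.beta


def macro_constants(ind: IndividualParams, dose: float) -> MacroConstants:
    """Convenience chain: individual parameters -> macro constants."""
    return macro_from_micro(micro_from_primary(ind), dose, ind.v1)


def concentration(ind: IndividualParams, dose: float, t) -> np.ndarray | float:
    """Central-compartment concentration (µg/mL) after an IV bolus at t=0.

    Accepts scalar or array times (min); negative times are a domain error.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    mac = macro_constants(ind, dose)
    out = mac.coef_a * np.exp(-mac.alpha * t_arr) + mac.coef_b * np.exp(-mac.beta * t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def amounts(ind: IndividualParams, dose: float, t) -> tuple:
    """Drug amounts (µg) in (central, peripheral, eliminated) at time t.

    Mass balance: the three components sum to the dose at all times.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    mac = macro_constants(ind, dose)
    central = ind.v1 * (
        mac.coef_a * np.exp(-mac.alpha * t_arr) + mac.coef_b * np.exp(-mac.beta * t_arr)
    )
    micro = micro_from_primary(ind)
    if micro.k12 == 0.0 or mac.alpha == mac.beta:
        peripheral = np.zeros_like(t_arr)
    else:
        peripheral = (
            dose
            * micro.k12
            / (mac.alpha - mac.beta)
            * (np.exp(-mac.beta * t_arr) - np.exp(-mac.alpha * t_arr))
        )
    eliminated = dose - central - peripheral
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(central), float(peripheral), float(eliminated)
    return central, peripheral, eliminated


def tumor_volume(dims: TumorDims) -> float:
    """Caliper tumor volume (mm³): V = ½ · W² · L."""
    return 0.5 * dims.width_w**2 * dims.length_l


def _vectorized_biexponential(cl, v1, q, v2, dose, t, subject_index=None):
    """Biexponential concentration for arrays of per-subject parameters.

    ``cl, v1, q, v2, dose`` are arrays of length n_subjects; ``t`` is an
    array of observation times.  If ``subject_index`` maps each element of
    ``t`` to its subject, a flat vector of predictions is returned;
    otherwise parameters and times must broadcast directly.

    Internal fast path used by the estimation engine and simulator; the
    scalar API above is the reference implementation.
    """
    cl = np.asarray(cl, dtype=float)
    v1 = np.asarray(v1, dtype=float)
    q = np.asarray(q, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    dose = np.asarray(dose, dtype=float)
    k10 = cl / v1
    with np.errstate(divide="ignore", invalid="ignore"):
        k12 = np.where(v1 > 0, q / v1, 0.0)
        k21 = np.where(v2 > 0, q / v2, 0.0)
    s = k10 + k12 + k21
    disc = np.maximum(s * s - 4.0 * k10 * k21, 0.0)
    root = np.sqrt(disc)
    alpha = 0.5 * (s + root)
    beta = 0.5 * (s - root)
    one_cpt = (k12 == 0.0) | (root <= 0.0)
    denom = np.where(one_cpt, 1.0, alpha - beta)
    coef_a = np.where(one_cpt, dose / v1, dose * (alpha - k21) / (v1 * denom))
    coef_b = np.where(one_cpt, 0.0, dose * (k21 - beta) / (v1 * denom))
    beta = np.where(one_cpt, alpha, beta)
    if subject_index is not None:
        alpha = alpha[subject_index]
        beta = beta[subject_index]
        coef_a = coef_a[subject_index]
        coef_b = coef_b[subject_index]
    return coef_a * np.exp(-alpha * t) + coef_b * np.exp(-beta * t)
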