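"""Ex-vivo biodistribution summaries and the competition-blocking index.

Works on tidy organ-fluorescence tables (columns ``animal_id``, ``group``,
``organ``, ``intensity`` in counts/pixel).  Sacrifice groups are the
post-injection timepoints (``2h``, ``24h``, ``48h``), the ``competition``
blocking arm, and PBS ``control`` animals, which are used only for
background reporting and never pooled into treated-group statistics.

Because fluorescence units are arbitrary, all group comparisons are done
on the log scale (scale-invariant); each animal is sacrificed at a single
timepoint, so the between-timepoint model is a one-way fixed-effects
linear model with Holm-adjusted pairwise contrasts against the 2 h group.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "TBRRecord",
    "CompetitionResult",
    "validate_measurements",
    "summarize_organs",
    "tumor_to_muscle",
    "tbr_table",
    "compare_timepoints",
    "competition_index",
    "permutation_pvalue",
    "AUTOFLUORESCENT_ORGANS",
    "TREATED_GROUPS",
]

TREATED_GROUPS = ("2h", "24h", "48h")
#: Excluded by default: high autofluorescence swamps probe signal.
AUTOFLUORESCENT_ORGANS = ("stomach", "intestine", "gallbladder")

REQUIRED_COLUMNS = ["animal_id", "group", "organ", "intensity"]


@dataclass(frozen=True)
class TBRRecord:
    """Tumor-to-background ratio of one animal (tumor/muscle intensity)."""

    animal_id: object
    ratio: float


@dataclass(frozen=True)
class CompetitionResult:
    """Blocking-assay index: blocked/unblocked tumor signal."""

    ratio: float
    percent_reduction: float


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    if (pd.to_numeric(df["intensity"], errors="coerce") < 0).any():
        raise ValueError("intensities must be non-negative")
    dup = df.duplicated(subset=["animal_id", "group", "organ"])
    if dup.any():
        raise ValueError(
            f"duplicate (animal, group, organ) record at row {df.index[dup][0]}"
        )
    return df


def summarize_organs(
    df: pd.DataFrame,
    group: str,
    organs: list[str] | None = None,
    include_autofluorescent: bool = False,
) -> pd.DataFrame:
    """Arithmetic mean and SD of intensity per organ within one group.

    A requested organ with no measurements yields an explicit NaN row
    (absent marker), never zero; an SD for a single animal is NaN.
    """
    df = validate_measurements(df)
    sub = df[df["group"] == group]
    if not include_autofluorescent:
        sub = sub[~sub["organ"].isin(AUTOFLUORESCENT_ORGANS)]
    if sub.empty:
        raise ValueError(f"no measurements for group {group!r}")
    wanted = organs if organs is not None else sorted(sub["organ"].unique())
    rows = []
    for organ in wanted:
        vals = sub.loc[sub["organ"] == organ, "intensity"].to_numpy(float)
        if vals.size == 0:
            rows.append(dict(organ=organ, group=group, n=0,
                             mean=np.nan, sd=np.nan))
        else:
            rows.append(dict(
                organ=organ, group=group, n=int(vals.size),
                mean=float(vals.mean()),
                sd=float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
            ))
    return pd.DataFrame(rows)


def tumor_to_muscle(df: pd.DataFrame, animal_id) -> TBRRecord:
    """Tumor-to-background ratio for one animal: tumor/muscle intensity."""
    df = validate_measurements(df)
    sub = df[df["animal_id"] == animal_id]
    tumor = sub.loc[sub["organ"] == "tumor", "intensity"]
    muscle = sub.loc[sub["organ"] == "muscle", "intensity"]
    if tumor.empty or muscle.empty:
        raise ValueError(
            f"animal {animal_id!r} needs both tumor and muscle records"
        )
    muscle_v = float(muscle.iloc[0])
    if muscle_v <= 0:
        raise ZeroDivisionError(
            f"animal {animal_id!r}: muscle intensity is zero; TBR undefined"
        )
    return TBRRecord(animal_id=animal_id, ratio=float(tumor.iloc[0]) / muscle_v)


def tbr_table(df: pd.DataFrame, groups=TREATED_GROUPS) -> pd.DataFrame:
    """TBR per animal for the requested groups."""
    df = validate_measurements(df)
    rows = []
    for group in groups:
        for animal in df.loc[df["group"] == group, "animal_id"].unique():
            rec = tumor_to_muscle(df, animal)
            rows.append(dict(animal_id=animal, group=group, tbr=rec.ratio))
    return pd.DataFrame(rows)


def permutation_pvalue(a: np.ndarray, b: np.ndarray, n_perm: int = 20000,
                       seed: int = 0) -> float:
    """Two-sided permutation test of a mean difference (log-scale inputs).

    Exact enumeration when the group sizes allow fewer than ``n_perm``
    distinct relabelings, Monte-Carlo otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n_a = a.size
    observed = abs(a.mean() - b.mean())
    from math import comb

    if comb(pooled.size, n_a) <= n_perm:
        count = total = 0
        for pick in combinations(range(pooled.size), n_a):
            mask = np.zeros(pooled.size, bool)
            mask[list(pick)] = True
            diff = abs(pooled[mask].mean() - pooled[~mask].mean())
            count += diff >= observed - 1e-12
            total += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = 1  # include the observed labeling
    for _ in range(n_perm):
        rng.shuffle(pooled)
        diff = abs(pooled[:n_a].mean() - pooled[n_a:].mean())
        count += diff >= observed - 1e-12
    return count / (n_perm + 1)


def compare_timepoints(
    df: pd.DataFrame,
    organ: str,
    reference: str = "2h",
    others: tuple = ("24h", "48h"),
    n_perm: int = 20000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise timepoint contrasts for one organ, Holm-adjusted.

    Fits a one-way fixed-effects linear model to log intensity across the
    sacrifice groups and tests each ``reference`` vs ``other`` contrast;
    degenerate (near-zero) residual variance falls back to a permutation
    test, and identical data give p = 1.  Returns a frame with raw and
    Holm-adjusted p-values, deterministic for fixed inputs.
    """
    import statsmodels.api as sm
    from statsmodels.stats.multitest import multipletests

    df = validate_measurements(df)
    sub = df[(df["organ"] == organ) & df["group"].isin((reference,) + tuple(others))]
    counts = sub.groupby("group")["animal_id"].nunique()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need >=2 groups with >=2 animals each")
    if (sub["intensity"] <= 0).any():
        raise ValueError("log-scale model requires positive intensities")
    logy = np.log(sub["intensity"].to_numpy(float))
    groups = sub["group"].to_numpy()
    levels = [reference] + [g for g in others if g in counts.index]
    X = np.column_stack([np.ones(logy.size)]
                        + [(groups == g).astype(float) for g in levels[1:]])
    fit = sm.OLS(logy, X).fit()
    resid_var = float(fit.mse_resid) if fit.df_resid > 0 else 0.0
    rows = []
    for j, g in enumerate(levels[1:], start=1):
        ref_vals = logy[groups == reference]
        oth_vals = logy[groups == g]
        if resid_var < 1e-12:
            if np.allclose(ref_vals.mean(), oth_vals.mean()):
                pval = 1.0
            else:
                pval = permutation_pvalue(ref_vals, oth_vals,
                                          n_perm=n_perm, seed=seed)
            estimate = float(oth_vals.mean() - ref_vals.mean())
        else:
            contrast = np.zeros(X.shape[1])
            contrast[j] = 1.0
            tt = fit.t_test(contrast)
            pval = float(tt.pvalue)
            estimate = float(tt.effect[0])
        rows.append(dict(
            organ=organ, contrast=f"{reference} vs {g}",
            log_fold_change=estimate,
            fold_change=float(np.exp(estimate)),
            p_value=pval,
        ))
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p_value"], method="holm")[1]
    return out


def competition_index(unblocked_mean: float, blocked_mean: float) -> CompetitionResult:
    """Blocking index of the competition assay.

    ``ratio`` is blocked/unblocked mean tumor signal; ``percent_reduction``
    is 100·(1 - ratio).  Pre-dosing excess unlabeled ligand should reduce
    labeled-probe uptake if binding is target-specific.
    """
    if unblocked_mean <= 0 or blocked_mean < 0:
        raise ValueError("means must be positive (blocked may be zero)")
    if blocked_mean == 0:
        return CompetitionResult(ratio=0.0, percent_reduction=100.0)
    ratio = blocked_mean / unblocked_mean
    return CompetitionResult(ratio=ratio, percent_reduction=100.0 * (1.0 - ratio))
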