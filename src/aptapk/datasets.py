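"""Longitudinal PK dataset container and CSV dialect.

The on-disk format follows the NONMEM-style longitudinal convention:

======  ==========================================================
column  meaning
======  ==========================================================
ID      subject (animal) identifier
TIME    sampling time, minutes (an optional TIME_UNIT column with
        value ``h`` marks hour-scaled files; converted on read)
DV      observed concentration (µg/mL); empty when MDV=1
AMT     dose amount (µg) on the dosing row, empty elsewhere
BW      body weight (g)
MDV     1 when DV is missing (dosing rows, pre-dose and BLOQ rows)
BLQ     1 when the sample was below the limit of quantification
LLOQ    the quantification limit (µg/mL), required when BLQ=1
======  ==========================================================

Invariants enforced on read: exactly one AMT row per subject at TIME=0;
DV empty iff MDV=1; BLQ=1 implies DV empty and LLOQ present; TIME
non-decreasing within subject.  Missing values are empty fields, never
sentinel numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Subject", "PKDataset", "read_pk_dataset", "write_pk_dataset", "SchemaError"]

COLUMNS = ["ID", "TIME", "DV", "AMT", "BW", "MDV", "BLQ", "LLOQ"]


class SchemaError(ValueError):
    """A dataset file violates the longitudinal-table schema."""


@dataclass
class Subject:
    """Per-animal view of the dataset used by the estimation engine."""

    subject_id: object
    dose: float
    bw: float
    times: np.ndarray          # post-dose sampling times with any record
    dv: np.ndarray             # observed values (nan where missing/BLOQ)
    blq: np.ndarray            # bool, below-LOQ flag per record
    mdv: np.ndarray            # bool, missing-DV flag per record
    lloq: np.ndarray           # LOQ per record (nan where absent)

    @property
    def observed_mask(self) -> np.ndarray:
        """Quantified observations (MDV=0, not BLOQ)."""
        return (~self.mdv) & (~self.blq)

    @property
    def n_observed(self) -> int:
        return int(self.observed_mask.sum())


class PKDataset:
    """Validated longitudinal concentration-time table.

    Wraps a :class:`pandas.DataFrame` in the column dialect above and
    exposes typed per-subject views.  Construct from a frame (validated),
    from :func:`read_pk_dataset`, or from the synthetic cohort generator.
    """

    def __init__(self, df: pd.DataFrame):
        self.df = _validate(df)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_subjects(cls, subjects: list[Subject]) -> "PKDataset":
        rows = []
        for s in subjects:
            rows.append(
                dict(ID=s.subject_id, TIME=0.0, DV=np.nan, AMT=s.dose, BW=s.bw,
                     MDV=1, BLQ=0, LLOQ=np.nan)
            )
            for t, dv, blq, mdv, lloq in zip(s.times, s.dv, s.blq, s.mdv, s.lloq):
                rows.append(
                    dict(ID=s.subject_id, TIME=float(t),
                         DV=(np.nan if mdv else float(dv)),
                         AMT=np.nan, BW=s.bw, MDV=int(mdv), BLQ=int(blq),
                         LLOQ=(float(lloq) if np.isfinite(lloq) else np.nan))
                )
        return cls(pd.DataFrame(rows, columns=COLUMNS))

    # -- views ------------------------------------------------------------
    @property
    def subjects(self) -> list[Subject]:
        out = []
        for sid, grp in self.df.groupby("ID", sort=False):
            dose_rows = grp[grp["AMT"].notna()]
            obs = grp[grp["AMT"].isna()]
            out.append(
                Subject(
                    subject_id=sid,
                    dose=float(dose_rows["AMT"].iloc[0]),
                    bw=float(grp["BW"].iloc[0]),
                    times=obs["TIME"].to_numpy(float),
                    dv=obs["DV"].to_numpy(float),
                    blq=obs["BLQ"].to_numpy(int).astype(bool),
                    mdv=obs["MDV"].to_numpy(int).astype(bool),
                    lloq=obs["LLOQ"].to_numpy(float),
                )
            )
        return out

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    @property
    def n_observations(self) -> int:
        """Quantified (retained under the discard policy) observations."""
        m = (self.df["MDV"] == 0) & (self.df["BLQ"] == 0) & self.df["AMT"].isna()
        return int(m.sum())

    def content_hash(self) -> str:
        import hashlib

        csv = self.df.to_csv(index=False, float_format="%.12g")
        return hashlib.sha256(csv.encode()).hexdigest()[:12]

    def write_csv(self, path) -> None:
        write_pk_dataset(self, path)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"PKDataset(n_subjects={self.n_subjects}, "
                f"n_observations={self.n_observations})")


def _fail(msg: str) -> None:
    raise SchemaError(msg)


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        _fail(f"missing required columns: {missing}")
    df = df.copy()
    if "TIME_UNIT" in df.columns:
        unit = df["TIME_UNIT"].astype(str).str.strip().str.lower()
        bad = ~unit.isin(["min", "h", ""])
        if bad.any():
            _fail(f"row {df.index[bad][0]}: unknown TIME_UNIT value")
        df.loc[unit == "h", "TIME"] = df.loc[unit == "h", "TIME"] * 60.0
        df = df.drop(columns=["TIME_UNIT"])
    for col in ("TIME", "DV", "AMT", "BW", "LLOQ"):
        df[col] = pd.to_numeric(df[col], errors="coerce") if df[col].dtype == object \
            else df[col].astype(float)
    for col in ("MDV", "BLQ"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not vals.isin([0, 1]).all():
            row = df.index[~vals.isin([0, 1])][0]
            _fail(f"row {row}, column {col}: must be 0 or 1")
        df[col] = vals.astype(int)
    if df["TIME"].isna().any():
        _fail(f"row {df.index[df['TIME'].isna()][0]}, column TIME: missing")
    if (df["TIME"] < 0).any():
        _fail(f"row {df.index[df['TIME'] < 0][0]}, column TIME: negative")
    if df["BW"].isna().any() or (df["BW"] <= 0).any():
        bad = df["BW"].isna() | (df["BW"] <= 0)
        _fail(f"row {df.index[bad][0]}, column BW: must be positive")
    # DV empty iff MDV=1
    dv_present = df["DV"].notna()
    bad = dv_present == (df["MDV"] == 1)
    if bad.any():
        _fail(f"row {df.index[bad][0]}: DV must be present exactly when MDV=0")
    if ((df["DV"] <= 0) & dv_present).any():
        row = df.index[(df["DV"] <= 0) & dv_present][0]
        _fail(f"row {row}, column DV: non-positive observation "
              "(exponential error model requires positive concentrations)")
    # BLQ=1 implies DV empty and LLOQ present
    blq = df["BLQ"] == 1
    if (blq & dv_present).any():
        _fail(f"row {df.index[blq & dv_present][0]}: BLQ=1 requires empty DV")
    if (blq & df["LLOQ"].isna()).any():
        _fail(f"row {df.index[blq & df['LLOQ'].isna()][0]}: BLQ=1 requires LLOQ")
    for sid, grp in df.groupby("ID", sort=False):
        times = grp["TIME"].to_numpy(float)
        if np.any(np.diff(times) < 0):
            _fail(f"subject {sid}: TIME must be non-decreasing")
        dose_rows = grp[grp["AMT"].notna()]
        if len(dose_rows) != 1:
            _fail(f"subject {sid}: exactly one AMT (dosing) row required, "
                  f"found {len(dose_rows)}")
        if float(dose_rows["TIME"].iloc[0]) != 0.0:
            _fail(f"subject {sid}: dosing row must be at TIME=0")
        if float(dose_rows["AMT"].iloc[0]) <= 0:
            _fail(f"subject {sid}: dose must be strictly positive")
        if int(dose_rows["MDV"].iloc[0]) != 1:
            _fail(f"subject {sid}: dosing row must have MDV=1")
        if grp["BW"].nunique() != 1:
            _fail(f"subject {sid}: BW must be constant within subject")
    return df.reset_index(drop=True)[COLUMNS]


def read_pk_dataset(path) -> PKDataset:
    """Read and validate a longitudinal PK dataset CSV.

    Schema violations raise :class:`SchemaError` naming the offending row
    and column; row order is preserved.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SchemaError(f"cannot read {path}: {exc}") from exc
    return PKDataset(df)


def write_pk_dataset(dataset: PKDataset, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        dataset.df.to_csv(fh, index=False, float_format="%.10g")
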