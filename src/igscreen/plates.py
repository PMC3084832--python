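"""Plate data model, I/O, QC, and control-based normalization for cell-based ELISA.

A screening run is held as a long-format :class:`pandas.DataFrame` with one row
per well.  Required columns:

``plate_id``
    plate identifier (string).
``well``
    96-well coordinate, ``A1``..``H12``.
``role``
    one of ``sample``, ``pos_ctrl``, ``neg_ctrl``.
``od``
    optical density at 492 nm (reference 650 nm), already blank-referenced by
    the reader; dimensionless, >= 0.

Sample wells may carry any additional annotation columns (``patient_id``,
``stage``, ``culture_id``...); they are preserved by every operation here.

Normalization is strictly per plate: each plate carries its own triplicate
positive control (Trastuzumab-like antibody) and negative control
(non-specific human IgG), and every sample OD on that plate is expressed as

* *fold increase*   = OD_sample / mean(negative-control ODs on that plate)
* *relative absorbance* = OD_sample / mean(positive-control ODs on that plate)

so the mean positive control on each plate has relative absorbance exactly 1.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

ROLES = ("sample", "pos_ctrl", "neg_ctrl")
REQUIRED_COLUMNS = ("plate_id", "well", "role", "od")

_WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")


class PlateError(ValueError):
    """Malformed plate table (missing columns, bad coordinates, duplicates)."""


class MissingControlError(PlateError):
    """A plate lacks wells of a required control role."""


class DegenerateControlError(PlateError):
    """Control mean is zero or negative; normalization is undefined."""


def validate_plate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format plate table, returning it unchanged.

    Raises :class:`PlateError` naming the offending column or row.
    """
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise PlateError(f"plate table is missing required column {col!r}")
    bad_role = ~df["role"].isin(ROLES)
    if bad_role.any():
        row = df.index[bad_role][0]
        raise PlateError(
            f"row {row}: invalid role {df.loc[row, 'role']!r} "
            f"(expected one of {ROLES})"
        )
    bad_well = ~df["well"].astype(str).str.match(_WELL_RE)
    if bad_well.any():
        row = df.index[bad_well][0]
        raise PlateError(f"row {row}: invalid 96-well coordinate {df.loc[row, 'well']!r}")
    if (df["od"] < 0).any():
        row = df.index[df["od"] < 0][0]
        raise PlateError(f"row {row}: negative OD {df.loc[row, 'od']}")
    dup = df.duplicated(subset=["plate_id", "well"])
    if dup.any():
        row = df.index[dup][0]
        raise PlateError(
            f"row {row}: duplicate well {df.loc[row, 'well']!r} "
            f"on plate {df.loc[row, 'plate_id']!r}"
        )
    return df


def read_plate_table(path) -> pd.DataFrame:
    """Read and validate a plate CSV (see module docstring for the schema)."""
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "role": str})
    return validate_plate_table(df)


def write_plate_table(df: pd.DataFrame, path) -> None:
    """Write a validated plate table to CSV (lossless round-trip)."""
    validate_plate_table(df)
    df.to_csv(path, index=False)


def control_mean(plate: pd.DataFrame, role: str) -> float:
    """Arithmetic mean OD of a plate's control wells of the given role.

    Raises :class:`MissingControlError` when the plate has no well of the role.
    """
    if role not in ROLES:
        raise PlateError(f"unknown role {role!r}")
    ods = plate.loc[plate["role"] == role, "od"]
    if len(ods) == 0:
        raise MissingControlError(f"plate has no {role!r} wells")
    return float(ods.mean())


def fold_increase(od_sample, neg_mean: float):
    """Sample OD over the plate's mean negative-control OD.

    This is the reactivity measure used for all cohort comparisons: a well at
    fold 1.0 is indistinguishable from the non-specific IgG background.
    """
    if neg_mean <= 0:
        raise DegenerateControlError(f"negative-control mean must be > 0, got {neg_mean}")
    return np.asarray(od_sample, dtype=float) / neg_mean if np.ndim(od_sample) else float(od_sample) / neg_mean


def relative_absorbance(od_sample, pos_mean: float):
    """Sample OD over the plate's mean positive-control OD.

    The plate's mean positive control is assigned relative absorbance 1, so
    this expresses each culture on a per-plate scale where the reactive-well
    threshold (0.75 by default) is comparable across plates.
    """
    if pos_mean <= 0:
        raise DegenerateControlError(f"positive-control mean must be > 0, got {pos_mean}")
    return np.asarray(od_sample, dtype=float) / pos_mean if np.ndim(od_sample) else float(od_sample) / pos_mean


def mfi_above_isotype(mfi_sample: float, mfi_isotype: float) -> float:
    """Flow-cytometry surface binding: sample MFI minus isotype-control MFI.

    Floored at 0: signal below the isotype control is noise, not negative
    binding.
    """
    if mfi_sample < 0 or mfi_isotype < 0:
        raise ValueError("MFI values must be non-negative")
    return max(0.0, float(mfi_sample) - float(mfi_isotype))


@dataclass
class QCReport:
    """Per-plate control quality summary.

    A plate passes when both control sets have at least ``min_control_wells``
    wells, both control CVs are at or below ``cv_ceiling``, and the positive
    mean is at least ``min_pos_over_neg`` times the negative mean.
    """

    plate_id: str
    pos_mean: float
    neg_mean: float
    pos_cv: float
    neg_cv: float
    n_pos: int
    n_neg: int
    passed: bool
    reasons: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def qc_plate(
    plate: pd.DataFrame,
    plate_id: str | None = None,
    cv_ceiling: float = 0.20,
    min_pos_over_neg: float = 2.0,
    min_control_wells: int = 3,
) -> QCReport:
    """Check one plate's controls against inclusion criteria.

    Defaults: triplicate controls required, control CV <= 20 %, positive mean
    at least twice the negative mean.
    """
    if plate_id is None:
        ids = plate["plate_id"].unique()
        if len(ids) != 1:
            raise PlateError("qc_plate expects a single plate; pass plate_id to select")
        plate_id = str(ids[0])
    reasons: list[str] = []
    stats = {}
    for role in ("pos_ctrl", "neg_ctrl"):
        ods = plate.loc[plate["role"] == role, "od"].to_numpy(float)
        n = len(ods)
        mean = float(ods.mean()) if n else float("nan")
        cv = float(ods.std(ddof=1) / mean) if n >= 2 and mean > 0 else float("nan")
        stats[role] = (n, mean, cv)
        if n < min_control_wells:
            reasons.append(f"{role}: {n} wells < required {min_control_wells}")
        elif not np.isfinite(cv) or cv > cv_ceiling:
            reasons.append(f"{role}: CV {cv:.3f} exceeds ceiling {cv_ceiling}")
    n_pos, pos_mean, pos_cv = stats["pos_ctrl"]
    n_neg, neg_mean, neg_cv = stats["neg_ctrl"]
    if np.isfinite(pos_mean) and np.isfinite(neg_mean) and pos_mean < min_pos_over_neg * neg_mean:
        reasons.append(
            f"positive mean {pos_mean:.3f} below {min_pos_over_neg} x negative mean {neg_mean:.3f}"
        )
    report = QCReport(
        plate_id=plate_id, pos_mean=pos_mean, neg_mean=neg_mean,
        pos_cv=pos_cv, neg_cv=neg_cv, n_pos=n_pos, n_neg=n_neg,
        passed=not reasons, reasons=reasons,
    )
    if not report.passed:
        logger.warning("plate %s failed QC: %s", plate_id, "; ".join(reasons))
    return report


def qc_report_json(reports) -> str:
    return json.dumps([r.to_dict() for r in reports], indent=2)


class PlateNormalizer(BaseEstimator, TransformerMixin):
    """Per-plate control normalization as a scikit-learn transformer.

    ``fit`` learns each plate's control means (and QC status); ``transform``
    appends ``fold_increase`` and ``relative_absorbance`` columns to the sample
    rows.  Plates failing QC are dropped from the output when ``qc`` is true
    (with a warning), mirroring the inclusion criteria a screening run applies.

    Parameters
    ----------
    qc : bool
        Apply control-based plate inclusion criteria.
    cv_ceiling, min_pos_over_neg, min_control_wells :
        QC limits; see :func:`qc_plate`.

    Attributes
    ----------
    control_means_ : dict
        ``plate_id -> (pos_mean, neg_mean)``.
    qc_reports_ : list of QCReport
    """

    def __init__(self, qc: bool = True, cv_ceiling: float = 0.20,
                 min_pos_over_neg: float = 2.0, min_control_wells: int = 3):
        self.qc = qc
        self.cv_ceiling = cv_ceiling
        self.min_pos_over_neg = min_pos_over_neg
        self.min_control_wells = min_control_wells

    def fit(self, X: pd.DataFrame, y=None):
        validate_plate_table(X)
        self.control_means_ = {}
        self.qc_reports_ = []
        self.failed_plates_ = []
        for plate_id, plate in X.groupby("plate_id", sort=True):
            report = qc_plate(
                plate, str(plate_id), cv_ceiling=self.cv_ceiling,
                min_pos_over_neg=self.min_pos_over_neg,
                min_control_wells=self.min_control_wells,
            )
            self.qc_reports_.append(report)
            if self.qc and not report.passed:
                self.failed_plates_.append(str(plate_id))
                continue
            self.control_means_[str(plate_id)] = (
                control_mean(plate, "pos_ctrl"),
                control_mean(plate, "neg_ctrl"),
            )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "control_means_"):
            raise RuntimeError("PlateNormalizer must be fit before transform")
        validate_plate_table(X)
        keep = X["plate_id"].astype(str).isin(self.control_means_)
        if not keep.all():
            dropped = sorted(X.loc[~keep, "plate_id"].astype(str).unique())
            warnings.warn(f"dropping wells on plates without usable controls: {dropped}")
        out = X.loc[keep].copy()
        pos = out["plate_id"].astype(str).map(lambda p: self.control_means_[p][0])
        neg = out["plate_id"].astype(str).map(lambda p: self.control_means_[p][1])
        out["fold_increase"] = out["od"] / neg
        out["relative_absorbance"] = out["od"] / pos
        return out


def normalize_plates(df: pd.DataFrame, qc: bool = True, **qc_limits) -> pd.DataFrame:
    """Fit-and-transform convenience wrapper over :class:`PlateNormalizer`."""
    return PlateNormalizer(qc=qc, **qc_limits).fit_transform(df)
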