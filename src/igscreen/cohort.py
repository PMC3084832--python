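"""Cohort statistics: per-patient summaries, stage-group aggregates, tests.

Each patient contributes 60-120 antibody-secreting B-cell cultures; the
per-culture reactivity measure is the fold increase over the plate's
non-specific IgG negative control.  Patient summaries report the mean fold
increase with a t-based 95 % CI, the maximum fold increase, and the percent
of cultures called reactive (relative absorbance above the positive-control
threshold).  Group aggregates are unweighted means of patient-level values,
which is what reproduces published per-stage summary rows exactly; an
alternative "pooled" mode averages over cultures directly (patients with more
cultures weigh more) and generally gives higher stage means.

Comparative tests follow the study design: pooled two-sided Student t for
two-group contrasts (patients vs healthy volunteers; localized vs metastatic)
and one-way ANOVA with Tukey's HSD across disease stages II-IV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

STAGE_ORDER = ("I", "II", "III", "IV")
LOCALIZED_STAGES = ("I", "II")

__all__ = [
    "PatientSummary", "GroupSummary", "ComparisonResult",
    "summarize_patient", "summarize_group", "summarize_cohort",
    "ttest_two_sided", "anova_tukey", "load_published_cohort",
    "round_half_up", "metastatic_label",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.5 -> 1), as in the reported tables."""
    factor = 10.0 ** ndigits
    return float(np.floor(abs(x) * factor + 0.5) / factor * np.sign(x)) if x else 0.0


def metastatic_label(stage: str) -> str:
    """Map a disease stage to localized (I-II) vs metastatic (III-IV)."""
    if stage not in STAGE_ORDER:
        raise ValueError(f"unknown stage {stage!r}")
    return "localized" if stage in LOCALIZED_STAGES else "metastatic"


@dataclass
class PatientSummary:
    patient_id: str
    stage: str
    n_cultures: int
    mean_fold: float
    ci_low: float
    ci_high: float
    max_fold: float
    pct_reactive: float          # rounded to integer, reporting convention

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id, "stage": self.stage,
            "n_cultures": self.n_cultures, "mean_fold": self.mean_fold,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "max_fold": self.max_fold, "pct_reactive": self.pct_reactive,
        }


@dataclass
class GroupSummary:
    label: str
    n_patients: int
    mean_fold: float             # unweighted mean of patient means
    ci_low: float                # mean of patient CI bounds (report mode)
    ci_high: float
    mean_max_fold: float
    mean_pct_reactive: float

    def rounded(self) -> dict:
        """Reporting precision: fold values to 1 decimal, percent to integer."""
        return {
            "label": self.label,
            "n_patients": self.n_patients,
            "mean_fold": round_half_up(self.mean_fold, 1),
            "ci_low": round_half_up(self.ci_low, 1),
            "ci_high": round_half_up(self.ci_high, 1),
            "mean_max_fold": round_half_up(self.mean_max_fold, 1),
            "mean_pct_reactive": round_half_up(self.mean_pct_reactive, 0),
        }


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    df: float
    p_value: float
    group_means: dict = field(default_factory=dict)
    pairwise_p: dict = field(default_factory=dict)   # populated for ANOVA only
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "test": self.test, "statistic": self.statistic, "df": self.df,
            "p_value": self.p_value, "group_means": self.group_means,
            "pairwise_p": {f"{a} vs {b}": p for (a, b), p in self.pairwise_p.items()},
            "note": self.note,
        }


def summarize_patient(folds, reactive_calls, patient_id: str = "",
                      stage: str = "", ci_level: float = 0.95) -> PatientSummary:
    """Per-patient culture summary: mean fold, t-interval, max, % reactive.

    With fewer than two cultures the CI is undefined (NaN) and a warning is
    issued; degenerate (zero-variance) folds give a zero-width interval.
    """
    folds = np.asarray(folds, dtype=float)
    calls = np.asarray(reactive_calls, dtype=bool)
    if folds.size == 0:
        raise ValueError("summarize_patient needs at least one culture")
    if folds.size != calls.size:
        raise ValueError("folds and reactive_calls must align")
    mean = float(folds.mean())
    if folds.size >= 2:
        se = float(folds.std(ddof=1) / np.sqrt(folds.size))
        tcrit = float(stats.t.ppf(0.5 + ci_level / 2.0, df=folds.size - 1))
        lo, hi = mean - tcrit * se, mean + tcrit * se
    else:
        warnings.warn(f"patient {patient_id or '?'}: <2 cultures, CI undefined")
        lo = hi = float("nan")
    pct = round_half_up(100.0 * calls.mean())
    return PatientSummary(
        patient_id=str(patient_id), stage=stage, n_cultures=int(folds.size),
        mean_fold=mean, ci_low=lo, ci_high=hi, max_fold=float(folds.max()),
        pct_reactive=pct,
    )


def summarize_group(patients, label: str = "") -> GroupSummary:
    """Stage-group aggregate as the unweighted mean of patient-level values.

    ``patients`` is a sequence of :class:`PatientSummary` (or a DataFrame with
    the same columns).  Every column — mean fold, CI bounds, maximum, percent
    reactive — is averaged across patients with equal weight, which is how
    the published per-stage rows are formed from the patient rows.
    """
    if isinstance(patients, pd.DataFrame):
        df = patients
    else:
        patients = list(patients)
        if not patients:
            raise ValueError(f"empty group {label!r}")
        df = pd.DataFrame([p.to_dict() for p in patients])
    if df.empty:
        raise ValueError(f"empty group {label!r}")
    return GroupSummary(
        label=label,
        n_patients=len(df),
        mean_fold=float(df["mean_fold"].mean()),
        ci_low=float(df["ci_low"].mean()),
        ci_high=float(df["ci_high"].mean()),
        mean_max_fold=float(df["max_fold"].mean()),
        mean_pct_reactive=float(df["pct_reactive"].mean()),
    )


def summarize_cohort(culture_df: pd.DataFrame, by: str = "stage") -> pd.DataFrame:
    """Patient summaries plus group rows from a normalized, called culture table.

    Expects columns ``patient_id``, ``stage``, ``fold_increase``, ``reactive``.
    ``by`` groups by ``"stage"`` or ``"metastatic"`` (localized vs metastatic).
    Returns patient rows with group rows appended (``row_type`` column).
    """
    required = {"patient_id", "stage", "fold_increase", "reactive"}
    missing = required - set(culture_df.columns)
    if missing:
        raise ValueError(f"culture table missing columns: {sorted(missing)}")
    summaries = []
    for (pid, stage), sub in culture_df.groupby(["patient_id", "stage"], sort=True):
        summaries.append(
            summarize_patient(sub["fold_increase"], sub["reactive"],
                              patient_id=str(pid), stage=str(stage))
        )
    pat = pd.DataFrame([s.to_dict() for s in summaries])
    pat["row_type"] = "patient"
    if by == "metastatic":
        pat["group"] = pat["stage"].map(metastatic_label)
    else:
        pat["group"] = pat["stage"]
    rows = [pat]
    for grp, sub in pat.groupby("group", sort=True):
        g = summarize_group(sub, label=str(grp)).rounded()
        rows.append(pd.DataFrame([{
            "patient_id": "", "stage": str(grp), "n_cultures": int(sub["n_cultures"].sum()),
            "mean_fold": g["mean_fold"], "ci_low": g["ci_low"], "ci_high": g["ci_high"],
            "max_fold": g["mean_max_fold"], "pct_reactive": g["mean_pct_reactive"],
            "row_type": "group", "group": str(grp),
        }]))
    return pd.concat(rows, ignore_index=True)


def ttest_two_sided(group_a, group_b) -> ComparisonResult:
    """Pooled-variance two-sided Student t-test on per-culture fold values.

    df = n_a + n_b - 2.  When every value in both groups is identical the
    statistic is 0 and p = 1 (degenerate-variance flag in ``note``).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    df = a.size + b.size - 2
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return ComparisonResult(test="student_t", statistic=0.0, df=df, p_value=1.0,
                                group_means={"a": float(a.mean()), "b": float(b.mean())},
                                note="degenerate: all values identical")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return ComparisonResult(test="student_t", statistic=float(t), df=float(df),
                            p_value=float(p),
                            group_means={"a": float(a.mean()), "b": float(b.mean())})


def anova_tukey(groups: dict, alpha: float = 0.05) -> ComparisonResult:
    """One-way ANOVA across stage groups with Tukey HSD post-hoc pairs.

    ``groups`` maps group label -> per-culture fold values.  Requires at least
    two groups with at least two values each.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        pairs = {(labels[i], labels[j]): 1.0
                 for i in range(len(labels)) for j in range(i + 1, len(labels))}
        return ComparisonResult(test="anova_tukey", statistic=0.0,
                                df=float(len(labels) - 1), p_value=1.0,
                                group_means={g: float(np.mean(groups[g])) for g in labels},
                                pairwise_p=pairs, note="degenerate: all values identical")
    f_stat, p = stats.f_oneway(*arrays)
    values = np.concatenate(arrays)
    codes = np.concatenate([[g] * a.size for g, a in zip(labels, arrays)])
    tk = pairwise_tukeyhsd(values, codes, alpha=alpha)
    uniq = list(tk.groupsunique)  # pairindices are codes into sorted unique groups
    pairwise = {
        (str(uniq[i]), str(uniq[j])): float(p)
        for i, j, p in zip(tk._multicomp.pairindices[0],
                           tk._multicomp.pairindices[1], tk.pvalues)
    }
    return ComparisonResult(
        test="anova_tukey", statistic=float(f_stat), df=float(len(labels) - 1),
        p_value=float(p),
        group_means={g: float(np.mean(groups[g])) for g in labels},
        pairwise_p=pairwise,
    )


def load_published_cohort() -> pd.DataFrame:
    """The packaged 21-patient melanoma cohort summary table.

    Per-patient rows (stage, id, demographics, mean fold increase over the
    negative control with 95 % CI at printed precision, maximum fold increase,
    percent reactive cultures) used by the reproduction tests and the report
    command.
    """
    with resources.files("igscreen.data").joinpath("published_cohort.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"patient_id": str, "stage": str})
    return df
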