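"""ADCC quantification from tabular live-imaging exports.

The assay: calcein-labeled tumor cells are co-cultured for two hours with
Fc-receptor-bearing monocytic effector cells pre-incubated with antibody,
in medium containing ethidium homodimer-1.  Images every 5 minutes yield two
tables per run:

state table
    one row per (tumor cell, time): calcein intensity (live-cell dye,
    arbitrary units) and an ethidium-positive flag (dead-cell DNA stain).
    Death is absorbing: once ethidium-positive, always positive.

track table
    one row per (effector cell, time): x/y position in micrometers and a
    contact flag (touching a tumor cell at that frame).

From these, the module computes endpoint tumor viability (percent ethidium-
negative), live-cell fluorescence relative to baseline, and per-effector
total path length, comparing effectors in sustained tumor contact with free
effectors by a pooled two-sided t-test.  Viability is defined by ethidium
negativity rather than calcein level so photobleaching does not count as
killing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

FRAME_INTERVAL_MIN = 5.0
DURATION_MIN = 120.0

STATE_COLUMNS = ("cell_id", "t_min", "calcein", "ethidium_pos")
TRACK_COLUMNS = ("cell_id", "t_min", "x_um", "y_um", "contact")

__all__ = [
    "AdccResult", "validate_state_table", "validate_track_table",
    "viability_percent", "relative_live_intensity", "path_length",
    "net_displacement", "classify_contact", "compare_contact_motility",
]


@dataclass
class AdccResult:
    """Endpoint summary of one ADCC run."""

    viability_pct: float
    relative_intensity_pct: float
    contact_mean_path: float
    contact_ci: tuple
    free_mean_path: float
    free_ci: tuple
    motility_p: float
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "viability_pct": self.viability_pct,
            "relative_intensity_pct": self.relative_intensity_pct,
            "contact_mean_path_um": self.contact_mean_path,
            "contact_ci_um": list(self.contact_ci),
            "free_mean_path_um": self.free_mean_path,
            "free_ci_um": list(self.free_ci),
            "motility_p": self.motility_p,
            **self.extra,
        }


def validate_state_table(df: pd.DataFrame) -> pd.DataFrame:
    for col in STATE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"state table is missing column {col!r}")
    if (df["calcein"] < 0).any():
        raise ValueError("calcein intensity must be non-negative")
    # absorbing death: ethidium flag never reverts within a cell
    flags = df.sort_values("t_min").groupby("cell_id")["ethidium_pos"]
    if (flags.apply(lambda s: bool((s.astype(int).diff() < 0).any()))).any():
        raise ValueError("ethidium_pos must be monotone per cell (death is absorbing)")
    return df


def validate_track_table(df: pd.DataFrame) -> pd.DataFrame:
    for col in TRACK_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"track table is missing column {col!r}")
    if not np.isfinite(df[["x_um", "y_um"]].to_numpy(float)).all():
        raise ValueError("track coordinates must be finite")
    dup = df.duplicated(subset=["cell_id", "t_min"])
    if dup.any():
        raise ValueError("duplicate (cell_id, t_min) in track table")
    return df


def _snap_time(df: pd.DataFrame, t: float) -> float:
    grid = np.sort(df["t_min"].unique())
    if t in grid:
        return float(t)
    nearest = float(grid[np.argmin(np.abs(grid - t))])
    warnings.warn(f"time {t} min is off the acquisition grid; using {nearest} min")
    return nearest


def viability_percent(state: pd.DataFrame, t: float = DURATION_MIN) -> float:
    """Percent of tumor cells not ethidium-positive at time t.

    Off-grid times snap to the nearest frame with a warning.
    """
    t = _snap_time(state, t)
    frame = state.loc[state["t_min"] == t]
    if frame.empty:
        raise ValueError(f"no state rows at t = {t} min")
    alive = (~frame["ethidium_pos"].astype(bool)).sum()
    return 100.0 * alive / len(frame)


def relative_live_intensity(state: pd.DataFrame, t0: float = 0.0,
                            t: float = DURATION_MIN) -> float:
    """Mean calcein intensity at t as a percent of the mean at t0.

    The published endpoint quantity: live-cell fluorescence remaining after
    two hours, relative to the start of the assay.
    """
    t0 = _snap_time(state, t0)
    t = _snap_time(state, t)
    base = state.loc[state["t_min"] == t0, "calcein"].mean()
    if not np.isfinite(base) or base <= 0:
        raise ValueError("degenerate baseline: mean calcein at t0 is zero")
    now = state.loc[state["t_min"] == t, "calcein"].mean()
    return 100.0 * float(now) / float(base)


def _as_xy(track: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(track, pd.DataFrame):
        track = track.sort_values("t_min")[["x_um", "y_um"]].to_numpy(float)
    return np.asarray(track, dtype=float)


def path_length(track) -> float:
    """Total path length (sum of per-frame Euclidean displacements), in um."""
    xy = _as_xy(track)
    if len(xy) < 2:
        warnings.warn("track has a single time point; path length is 0")
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1)))


def net_displacement(track) -> float:
    """Straight-line distance from first to last position, in um (<= path)."""
    xy = _as_xy(track)
    if len(xy) < 2:
        return 0.0
    return float(np.linalg.norm(xy[-1] - xy[0]))


def classify_contact(track_df: pd.DataFrame, min_fraction: float = 0.5) -> pd.Series:
    """Per-effector contact class: True when the contact flag is set for at
    least ``min_fraction`` of frames (default half).

    The imaging software exports a per-frame touching flag; a single grazing
    frame should not make a cell a "contact" effector, hence the sustained-
    fraction rule.
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    return track_df.groupby("cell_id")["contact"].mean() >= min_fraction


def _mean_ci(values: np.ndarray, level: float = 0.95) -> tuple:
    mean = float(values.mean())
    if values.size < 2:
        return (float("nan"), float("nan"))
    se = values.std(ddof=1) / np.sqrt(values.size)
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=values.size - 1)
    return (mean - float(tcrit * se), mean + float(tcrit * se))


def compare_contact_motility(track_df: pd.DataFrame, min_fraction: float = 0.5,
                             ci_level: float = 0.95) -> AdccResult | None:
    """Compare total path length of contact vs non-contact effector cells.

    Returns per-class mean path lengths with t-based CIs and the pooled
    two-sided Student t-test p-value; ``None`` (not applicable) when either
    class has no cells.  Net displacement means are reported alongside in
    ``extra`` since tracking software conventions differ on which "movement"
    measure is exported.
    """
    validate_track_table(track_df)
    if "cell_type" in track_df.columns:
        track_df = track_df.loc[track_df["cell_type"] == "effector"]
    contact_class = classify_contact(track_df, min_fraction)
    lengths = track_df.groupby("cell_id").apply(path_length, include_groups=False)
    nets = track_df.groupby("cell_id").apply(net_displacement, include_groups=False)
    contact = lengths[contact_class.reindex(lengths.index)].to_numpy(float)
    free = lengths[~contact_class.reindex(lengths.index)].to_numpy(float)
    if contact.size == 0 or free.size == 0:
        warnings.warn("one contact class is empty; motility comparison not applicable")
        return None
    if contact.size < 2 or free.size < 2:
        raise ValueError("each contact class needs at least two tracks for the t-test")
    t, p = stats.ttest_ind(contact, free, equal_var=True)
    return AdccResult(
        viability_pct=float("nan"), relative_intensity_pct=float("nan"),
        contact_mean_path=float(contact.mean()), contact_ci=_mean_ci(contact, ci_level),
        free_mean_path=float(free.mean()), free_ci=_mean_ci(free, ci_level),
        motility_p=float(p),
        extra={
            "t_statistic": float(t),
            "n_contact": int(contact.size), "n_free": int(free.size),
            "contact_mean_net_um": float(nets[contact_class.reindex(nets.index)].mean()),
            "free_mean_net_um": float(nets[~contact_class.reindex(nets.index)].mean()),
        },
    )


def summarize_adcc(state_df: pd.DataFrame, track_df: pd.DataFrame,
                   t0: float = 0.0, t_end: float = DURATION_MIN) -> AdccResult:
    """Full endpoint summary: viability, relative intensity, motility contrast."""
    validate_state_table(state_df)
    motility = compare_contact_motility(track_df)
    via = viability_percent(state_df, t_end)
    rel = relative_live_intensity(state_df, t0, t_end)
    if motility is None:
        return AdccResult(viability_pct=via, relative_intensity_pct=rel,
                          contact_mean_path=float("nan"), contact_ci=(float("nan"),) * 2,
                          free_mean_path=float("nan"), free_ci=(float("nan"),) * 2,
                          motility_p=float("nan"))
    motility.viability_pct = via
    motility.relative_intensity_pct = rel
    return motility
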