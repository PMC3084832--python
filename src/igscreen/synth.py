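"""Synthetic cohorts, ELISA plates, dilution series and ADCC tables.

The generator emulates the statistical structure the analysis assumes, so
every downstream stage can be exercised end to end with known ground truth:

* Each patient has a latent per-cell frequency ``f`` of B cells secreting a
  tumor-reactive antibody, decreasing with disease stage.  A culture well
  seeded with ``n`` cells receives Binomial(n, f) reactive clones; a well is
  latently reactive when it has at least one clone, so the fraction of
  reactive wells follows 1 - (1-f)^n ~ 1 - exp(-f*n) (the single-hit model).
* Optical densities are multiplicative log-normal noise around a mean that
  depends only on the well's latent class (background vs reactive) and the
  control role.  Reactive-well OD does not scale with clone count — a
  deliberate simplification; the assay gives presence/absence, not titer.
* Plates carry triplicate positive (Trastuzumab-like) and negative
  (non-specific IgG) control wells with their own noise.
* Limiting-dilution series draw non-reactive well counts directly from
  Binomial(wells, exp(-f*n)) at each plating density (125-2,500 cells/well).
* ADCC runs emulate a 2-hour co-culture imaged every 5 minutes at a 3:1
  effector:tumor ratio: effector cells do 2-D Gaussian random walks with a
  smaller step SD while in tumor contact; tumor cells die (become ethidium-
  positive, absorbing) with a scenario-dependent 2-hour kill probability and
  their calcein signal decays after death, while live-cell calcein bleaches
  slowly.

One global seed fans out to independent per-table child streams
(:func:`child_rng`), so generating an extra table never perturbs earlier ones
and a fixed seed reproduces every table exactly.
"""

from __future__ import annotations

import hashlib
import string
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .lda import DilutionSeries

__all__ = [
    "CohortSpec", "PlateLayout", "AdccSpec",
    "DEFAULT_STAGE_REACTIVE_PCT", "default_stage_frequencies",
    "default_cohort_spec", "child_rng",
    "gen_cohort", "gen_plates", "gen_dilution_series", "gen_adcc",
]

# Target per-stage reactive-culture percentages used to calibrate the default
# latent frequencies (stage-group column means of the published cohort table).
DEFAULT_STAGE_REACTIVE_PCT = {"I": 2.0, "II": 33.0, "III": 30.0, "IV": 24.0}

DEFAULT_DOSES = (125, 250, 500, 1000, 2500)


def default_stage_frequencies(cells_per_culture: int = 500) -> dict:
    """Latent per-cell frequencies solved from 1 - exp(-f*n) = target fraction.

    Inverts the single-hit model at the default plating density so the
    expected percent of reactive cultures per stage matches
    :data:`DEFAULT_STAGE_REACTIVE_PCT`.
    """
    return {
        stage: float(-np.log(1.0 - pct / 100.0) / cells_per_culture)
        for stage, pct in DEFAULT_STAGE_REACTIVE_PCT.items()
    }


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent named child stream of one global seed.

    The stream name is hashed stably (not with Python's randomized ``hash``)
    so tables are reproducible across processes.
    """
    key = int.from_bytes(hashlib.sha256(stream.encode()).digest()[:4], "little")
    ss = np.random.SeedSequence(seed, spawn_key=(key,))
    return np.random.default_rng(ss)


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size) -> np.ndarray:
    """Multiplicative noise: log-normal with the given arithmetic mean and CV."""
    if cv == 0:
        return np.full(size, mean, dtype=float)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


class CohortSpec(BaseModel):
    """Study-design parameters for a synthetic screening cohort.

    Defaults mirror the screened melanoma cohort: 500 B cells seeded per
    culture well, 60-120 cultures per patient (90 by default), triplicate
    plate controls, and stage-dependent latent frequencies calibrated so the
    expected reactive-culture percentages match the published per-stage means.
    """

    n_patients_per_stage: dict[str, int] = Field(
        default_factory=lambda: {"I": 1, "II": 8, "III": 6, "IV": 6})
    freq_per_stage: dict[str, float] = Field(default_factory=default_stage_frequencies)
    cells_per_culture: int = 500
    cultures_per_patient: int = 90          # study range 60-120
    od_neg_mean: float = 0.30               # OD units, non-specific IgG background
    od_neg_cv: float = 0.10
    od_pos_mean: float = 1.00               # positive-control antibody OD
    od_pos_cv: float = 0.10
    od_reactive_mean: float = 1.10          # latently reactive culture OD
    od_reactive_cv: float = 0.15
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        for stage, f in self.freq_per_stage.items():
            if not 0 <= f < 1:
                raise ValueError(f"freq_per_stage[{stage!r}] must be in [0, 1), got {f}")
        for stage, n in self.n_patients_per_stage.items():
            if n < 1:
                raise ValueError(f"n_patients_per_stage[{stage!r}] must be >= 1, got {n}")
            if stage not in self.freq_per_stage:
                raise ValueError(f"no frequency given for stage {stage!r}")
        if self.cells_per_culture < 1 or self.cultures_per_patient < 1:
            raise ValueError("cells_per_culture and cultures_per_patient must be >= 1")
        for name in ("od_neg_cv", "od_pos_cv", "od_reactive_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("od_neg_mean", "od_pos_mean", "od_reactive_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.od_pos_mean <= self.od_neg_mean:
            raise ValueError("od_pos_mean must exceed od_neg_mean")
        return self


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The study-condition cohort spec with an explicit seed."""
    return CohortSpec(seed=seed, **overrides)


def gen_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate culture wells for a cohort; returns (culture table, truth table).

    Culture table: one row per culture with ``culture_id``, ``patient_id``,
    ``stage`` and raw ``od``.  Truth table adds the latent ``true_frequency``
    and the per-well ``n_reactive_clones`` (0 for wells whose OD came from the
    background model), sufficient for every parameter-recovery test.
    """
    rng = child_rng(spec.seed, "cohort")
    cultures, truths = [], []
    pid = 0
    for stage in sorted(spec.n_patients_per_stage):
        f = spec.freq_per_stage[stage]
        for _ in range(spec.n_patients_per_stage[stage]):
            pid += 1
            patient_id = f"P{pid:03d}"
            clones = rng.binomial(spec.cells_per_culture, f,
                                  size=spec.cultures_per_patient)
            reactive = clones > 0
            od = np.where(
                reactive,
                _lognormal(rng, spec.od_reactive_mean, spec.od_reactive_cv,
                           spec.cultures_per_patient),
                _lognormal(rng, spec.od_neg_mean, spec.od_neg_cv,
                           spec.cultures_per_patient),
            )
            for j in range(spec.cultures_per_patient):
                cid = f"{patient_id}_c{j:03d}"
                cultures.append((cid, patient_id, stage, float(od[j])))
                truths.append((cid, patient_id, stage, f, int(clones[j])))
    culture_df = pd.DataFrame(
        cultures, columns=["culture_id", "patient_id", "stage", "od"])
    truth_df = pd.DataFrame(
        truths, columns=["culture_id", "patient_id", "stage",
                         "true_frequency", "n_reactive_clones"])
    return culture_df, truth_df


class PlateLayout(BaseModel):
    """96-well plate layout: which coordinates hold the control triplicates."""

    pos_wells: tuple[str, ...] = ("A1", "B1", "C1")
    neg_wells: tuple[str, ...] = ("D1", "E1", "F1")
    max_plates: Optional[int] = None

    @model_validator(mode="after")
    def _check(self):
        if len(self.pos_wells) < 3 or len(self.neg_wells) < 3:
            raise ValueError("layout needs at least 3 wells per control role")
        if set(self.pos_wells) & set(self.neg_wells):
            raise ValueError("control roles share a well")
        return self

    @property
    def sample_wells(self) -> list[str]:
        all_wells = [f"{r}{c}" for r in string.ascii_uppercase[:8]
                     for c in range(1, 13)]
        taken = set(self.pos_wells) | set(self.neg_wells)
        return [w for w in all_wells if w not in taken]


class PlateCapacityError(ValueError):
    """More cultures than the allowed plates can hold."""


def gen_plates(culture_df: pd.DataFrame, spec: CohortSpec,
               layout: PlateLayout | None = None) -> pd.DataFrame:
    """Arrange cultures onto 96-well plates and inject noisy control wells.

    Cultures fill plates in order; each plate carries the layout's positive
    and negative control triplicates with ODs drawn from the spec's control
    noise models.  Returns a long-format plate table (see
    :mod:`igscreen.plates`) preserving the culture annotations.
    """
    layout = layout or PlateLayout()
    rng = child_rng(spec.seed, "plates")
    per_plate = len(layout.sample_wells)
    n_plates = -(-len(culture_df) // per_plate)  # ceiling
    if layout.max_plates is not None and n_plates > layout.max_plates:
        raise PlateCapacityError(
            f"{len(culture_df)} cultures need {n_plates} plates "
            f"(capacity {per_plate}/plate) but max_plates={layout.max_plates}"
        )
    rows = []
    for p in range(n_plates):
        plate_id = f"plate{p + 1:03d}"
        for w in layout.pos_wells:
            rows.append({"plate_id": plate_id, "well": w, "role": "pos_ctrl",
                         "od": float(_lognormal(rng, spec.od_pos_mean,
                                                spec.od_pos_cv, ())),
                         "culture_id": "", "patient_id": "", "stage": ""})
        for w in layout.neg_wells:
            rows.append({"plate_id": plate_id, "well": w, "role": "neg_ctrl",
                         "od": float(_lognormal(rng, spec.od_neg_mean,
                                                spec.od_neg_cv, ())),
                         "culture_id": "", "patient_id": "", "stage": ""})
        chunk = culture_df.iloc[p * per_plate:(p + 1) * per_plate]
        for well, (_, c) in zip(layout.sample_wells, chunk.iterrows()):
            rows.append({"plate_id": plate_id, "well": well, "role": "sample",
                         "od": float(c["od"]), "culture_id": c["culture_id"],
                         "patient_id": c["patient_id"], "stage": c["stage"]})
    return pd.DataFrame(rows)


def gen_dilution_series(
    true_frequency: float,
    doses=DEFAULT_DOSES,
    wells_per_dose: int = 24,
    seed: int = 0,
) -> tuple[DilutionSeries, dict]:
    """Simulate a limiting-dilution experiment under the single-hit model.

    At each plating density ``n`` the non-reactive well count is drawn
    Binomial(wells_per_dose, exp(-f*n)).  Returns the series and a truth dict
    recording the generating frequency.
    """
    if not 0 < true_frequency < 1:
        raise ValueError(f"true_frequency must be in (0, 1), got {true_frequency}")
    doses = np.asarray(doses, dtype=int)
    if (doses <= 0).any():
        raise ValueError("doses must be positive cell counts")
    if wells_per_dose < 1:
        raise ValueError("wells_per_dose must be >= 1")
    rng = child_rng(seed, "dilution")
    p0 = np.exp(-true_frequency * doses)
    nonreactive = rng.binomial(wells_per_dose, p0)
    series = DilutionSeries.from_arrays(
        doses, np.full(len(doses), wells_per_dose), nonreactive)
    return series, {"true_frequency": float(true_frequency),
                    "wells_per_dose": int(wells_per_dose)}


class AdccSpec(BaseModel):
    """Parameters of a synthetic 2-hour effector/tumor co-culture.

    The kill probabilities are 2-hour endpoint probabilities of a tumor cell
    becoming ethidium-positive; step SDs are per-frame Gaussian displacement
    SDs (um) for effectors in and out of tumor contact.  Defaults give
    endpoint quantities in the range seen for a tumor-specific antibody
    (``scenario="specific"``) or a non-binding control (``scenario="control"``).
    """

    n_tumor: int = 30
    n_effector: int = 90                    # 3:1 effector:tumor ratio
    scenario: str = "specific"              # "specific" | "control"
    kill_prob_specific: float = 0.82        # fraction killed / 2 h
    kill_prob_control: float = 0.05
    step_sd_contact: float = 0.43           # um per 5-min frame
    step_sd_free: float = 0.85
    contact_fraction: float = 0.5           # effectors seeded at tumor contact
    contact_radius_um: float = 10.0
    frame_interval: float = 5.0             # minutes
    duration: float = 120.0                 # minutes
    calcein_mean: float = 1000.0            # AU at t=0
    calcein_cv: float = 0.15
    live_bleach_endpoint: float = 0.67      # live-cell calcein remaining at 2 h
    dead_decay_halftime_min: float = 20.0
    dead_residual: float = 0.05             # floor fraction of initial signal
    field_um: float = 400.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.scenario not in ("specific", "control"):
            raise ValueError(f"scenario must be 'specific' or 'control', got {self.scenario!r}")
        for name in ("kill_prob_specific", "kill_prob_control",
                     "contact_fraction", "live_bleach_endpoint", "dead_residual"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.step_sd_contact < 0 or self.step_sd_free < 0:
            raise ValueError("step SDs must be >= 0")
        if self.n_tumor < 1 or self.n_effector < 1:
            raise ValueError("cell counts must be >= 1")
        n_frames = self.duration / self.frame_interval
        if abs(n_frames - round(n_frames)) > 1e-9:
            raise ValueError("duration must be a multiple of frame_interval")
        return self

    @property
    def kill_prob(self) -> float:
        return self.kill_prob_specific if self.scenario == "specific" else self.kill_prob_control

    @property
    def times(self) -> np.ndarray:
        return np.arange(0, self.duration + self.frame_interval / 2,
                         self.frame_interval)


def gen_adcc(spec: AdccSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one co-culture run; returns (track table, state table).

    Track table: per-frame effector (and static tumor) positions with a
    contact flag (within ``contact_radius_um`` of a tumor cell).  State table:
    per-frame tumor calcein intensity and the absorbing ethidium flag.
    """
    rng = child_rng(spec.seed, f"adcc-{spec.scenario}")
    times = spec.times
    n_frames = len(times)
    n_steps = n_frames - 1

    tumor_xy = rng.uniform(0, spec.field_um, size=(spec.n_tumor, 2))

    # --- tumor death process -------------------------------------------------
    # per-frame hazard chosen so the endpoint death probability is kill_prob
    if spec.kill_prob >= 1.0:
        hazard = 1.0
    else:
        hazard = 1.0 - (1.0 - spec.kill_prob) ** (1.0 / n_steps)
    death_frame = np.full(spec.n_tumor, np.inf)
    if hazard > 0:
        draws = rng.random((spec.n_tumor, n_steps)) < hazard
        for i in range(spec.n_tumor):
            hits = np.nonzero(draws[i])[0]
            if hits.size:
                death_frame[i] = hits[0] + 1  # death observed at end of the step

    c0 = _lognormal(rng, spec.calcein_mean, spec.calcein_cv, spec.n_tumor)
    bleach = spec.live_bleach_endpoint ** (1.0 / n_steps)
    state_rows = []
    for i in range(spec.n_tumor):
        for fidx, t in enumerate(times):
            dead = fidx >= death_frame[i]
            live_level = c0[i] * bleach ** fidx
            if dead:
                dt = (fidx - death_frame[i]) * spec.frame_interval
                decayed = live_level * 0.5 ** (dt / spec.dead_decay_halftime_min)
                cal = max(spec.dead_residual * c0[i], decayed)
            else:
                cal = live_level
            state_rows.append((f"T{i:03d}", float(t), float(cal), bool(dead)))
    state_df = pd.DataFrame(state_rows,
                            columns=["cell_id", "t_min", "calcein", "ethidium_pos"])

    # --- effector random walks ----------------------------------------------
    n_contact_seed = int(round(spec.contact_fraction * spec.n_effector))
    start = np.empty((spec.n_effector, 2))
    for e in range(spec.n_effector):
        if e < n_contact_seed:
            # adjacent to a random tumor cell, well inside the contact radius
            anchor = tumor_xy[rng.integers(spec.n_tumor)]
            angle = rng.uniform(0, 2 * np.pi)
            start[e] = anchor + 0.4 * spec.contact_radius_um * np.array(
                [np.cos(angle), np.sin(angle)])
        else:
            # rejection-sample a free starting position
            while True:
                cand = rng.uniform(0, spec.field_um, size=2)
                d = np.min(np.linalg.norm(tumor_xy - cand, axis=1))
                if d > 3 * spec.contact_radius_um:
                    start[e] = cand
                    break
    track_rows = []
    for e in range(spec.n_effector):
        xy = start[e].copy()
        for fidx, t in enumerate(times):
            d = np.min(np.linalg.norm(tumor_xy - xy, axis=1))
            in_contact = d < spec.contact_radius_um
            track_rows.append((f"E{e:03d}", "effector", float(t),
                               float(xy[0]), float(xy[1]), bool(in_contact)))
            if fidx < n_steps:
                sd = spec.step_sd_contact if in_contact else spec.step_sd_free
                xy = xy + rng.normal(0.0, sd, size=2)
    for i in range(spec.n_tumor):
        for t in times:
            track_rows.append((f"T{i:03d}", "tumor", float(t),
                               float(tumor_xy[i, 0]), float(tumor_xy[i, 1]), False))
    track_df = pd.DataFrame(track_rows, columns=["cell_id", "cell_type", "t_min",
                                                 "x_um", "y_um", "contact"])
    return track_df, state_df
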