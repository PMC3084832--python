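"""Generator contracts: determinism, single-hit statistics, plate capacity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from igscreen.lda import nonreactive_fractions
from igscreen.synth import (
    AdccSpec,
    CohortSpec,
    PlateCapacityError,
    PlateLayout,
    default_cohort_spec,
    gen_adcc,
    gen_cohort,
    gen_dilution_series,
    gen_plates,
)


class TestGenCohort:
    def test_same_seed_reproduces_tables_exactly(self):
        spec = default_cohort_spec(seed=42, n_patients_per_stage={"II": 2},
                                   cultures_per_patient=30)
        c1, t1 = gen_cohort(spec)
        c2, t2 = gen_cohort(spec)
        assert c1.to_csv() == c2.to_csv()
        assert t1.to_csv() == t2.to_csv()

    def test_zero_frequency_gives_only_background_wells(self):
        spec = CohortSpec(n_patients_per_stage={"II": 2},
                          freq_per_stage={"II": 0.0},
                          cultures_per_patient=50, seed=0)
        cultures, truth = gen_cohort(spec)
        assert (truth["n_reactive_clones"] == 0).all()
        # background ODs sit far below the reactive mean
        assert cultures["od"].max() < spec.od_reactive_mean / 2

    def test_reactive_well_fraction_matches_single_hit_expectation(self):
        f, cells = 1 / 2000, 500
        spec = CohortSpec(n_patients_per_stage={"II": 1},
                          freq_per_stage={"II": f},
                          cells_per_culture=cells,
                          cultures_per_patient=10_000, seed=7)
        _, truth = gen_cohort(spec)
        p = 1.0 - (1.0 - f) ** cells  # ~ 1 - exp(-0.25) ~ 0.221
        lo, hi = stats.binom.ppf([0.005, 0.995], 10_000, p) / 10_000
        frac = (truth["n_reactive_clones"] > 0).mean()
        assert lo <= frac <= hi

    def test_truth_rows_align_with_culture_rows(self):
        spec = default_cohort_spec(seed=3, n_patients_per_stage={"III": 2},
                                   cultures_per_patient=40)
        cultures, truth = gen_cohort(spec)
        assert len(truth) == len(cultures)
        assert (truth["culture_id"] == cultures["culture_id"]).all()

    def test_invalid_spec_names_field(self):
        with pytest.raises(ValueError, match="od_pos_mean"):
            CohortSpec(od_pos_mean=0.2, od_neg_mean=0.3)
        with pytest.raises(ValueError, match="freq_per_stage"):
            CohortSpec(freq_per_stage={"II": 1.5},
                       n_patients_per_stage={"II": 1})


class TestGenPlates:
    def _cultures(self, n):
        return pd.DataFrame({
            "culture_id": [f"c{i}" for i in range(n)],
            "patient_id": "P1", "stage": "II", "od": 0.3,
        })

    def test_exact_fit_uses_one_plate(self):
        spec = default_cohort_spec()
        plates = gen_plates(self._cultures(90), spec)
        assert plates["plate_id"].nunique() == 1
        assert (plates["role"] == "sample").sum() == 90

    def test_one_extra_culture_opens_second_plate(self):
        spec = default_cohort_spec()
        plates = gen_plates(self._cultures(91), spec)
        assert plates["plate_id"].nunique() == 2

    def test_capacity_error_when_plates_capped(self):
        spec = default_cohort_spec()
        layout = PlateLayout(max_plates=1)
        with pytest.raises(PlateCapacityError):
            gen_plates(self._cultures(91), spec, layout)

    def test_no_well_used_twice(self):
        spec = default_cohort_spec()
        plates = gen_plates(self._cultures(150), spec)
        assert not plates.duplicated(subset=["plate_id", "well"]).any()

    def test_control_od_means_match_noise_model(self):
        # 1,000 single-culture plates: control means within 3 SE of the spec
        spec = default_cohort_spec()
        pos, neg = [], []
        for seed in range(1000):
            s = spec.model_copy(update={"seed": seed})
            plates = gen_plates(self._cultures(1), s)
            pos.extend(plates.loc[plates["role"] == "pos_ctrl", "od"])
            neg.extend(plates.loc[plates["role"] == "neg_ctrl", "od"])
        for values, mean, cv in [(pos, spec.od_pos_mean, spec.od_pos_cv),
                                 (neg, spec.od_neg_mean, spec.od_neg_cv)]:
            se = cv * mean / np.sqrt(len(values))
            assert abs(np.mean(values) - mean) < 3 * se


class TestGenDilutionSeries:
    def test_vanishing_frequency_leaves_all_wells_nonreactive(self):
        series, _ = gen_dilution_series(1e-9, wells_per_dose=50, seed=0)
        assert (series.nonreactive == series.tested).all()

    def test_fraction_at_reciprocal_dose_approaches_e_minus_1(self):
        series, _ = gen_dilution_series(1 / 1000, doses=[1000],
                                        wells_per_dose=200_000, seed=5)
        frac = nonreactive_fractions(series)[0]
        assert frac == pytest.approx(np.exp(-1), abs=0.005)

    def test_expected_fraction_at_patient_design_point(self):
        # f = 1/1790, dose 500: model predicts exp(-500/1790) ~ 0.756
        series, truth = gen_dilution_series(1 / 1790, doses=[500],
                                            wells_per_dose=100_000, seed=2)
        assert truth["true_frequency"] == pytest.approx(1 / 1790)
        assert nonreactive_fractions(series)[0] == pytest.approx(
            np.exp(-500 / 1790), abs=0.01)

    def test_rejects_invalid_frequency(self):
        with pytest.raises(ValueError, match="true_frequency"):
            gen_dilution_series(0.0)
        with pytest.raises(ValueError, match="true_frequency"):
            gen_dilution_series(1.5)


class TestGenAdcc:
    def test_zero_kill_probability_leaves_all_cells_ethidium_negative(self):
        spec = AdccSpec(scenario="control", kill_prob_control=0.0,
                        n_tumor=20, n_effector=10, seed=0)
        _, state = gen_adcc(spec)
        assert not state["ethidium_pos"].any()

    def test_every_track_has_one_point_per_frame(self):
        spec = AdccSpec(n_tumor=5, n_effector=8, seed=1)
        tracks, state = gen_adcc(spec)
        counts = tracks.groupby("cell_id")["t_min"].count()
        assert (counts == 25).all()                      # 120 min / 5 min + 1
        assert (state.groupby("cell_id")["t_min"].count() == 25).all()

    def test_equal_step_sds_give_equal_mean_paths(self):
        # null Monte-Carlo: with identical contact and free step SDs, the two
        # classes' mean path lengths differ by less than 2 SE over 500 cells
        from igscreen.adcc import classify_contact, path_length
        spec = AdccSpec(step_sd_contact=0.85, step_sd_free=0.85,
                        n_tumor=30, n_effector=500, seed=9)
        tracks, _ = gen_adcc(spec)
        eff = tracks[tracks["cell_type"] == "effector"]
        contact = classify_contact(eff)
        lengths = eff.groupby("cell_id").apply(path_length, include_groups=False)
        a = lengths[contact.reindex(lengths.index)]
        b = lengths[~contact.reindex(lengths.index)]
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert abs(a.mean() - b.mean()) < 2 * se

    def test_duration_must_be_multiple_of_frame_interval(self):
        with pytest.raises(ValueError, match="frame_interval"):
            AdccSpec(duration=118)

    def test_seed_reproduces_adcc_tables(self):
        spec = AdccSpec(n_tumor=5, n_effector=8, seed=4)
        t1, s1 = gen_adcc(spec)
        t2, s2 = gen_adcc(spec)
        assert t1.to_csv() == t2.to_csv()
        assert s1.to_csv() == s2.to_csv()
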