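import numpy as np
import pytest

from igscreen.lda import DilutionSeries
from igscreen.synth import default_cohort_spec, gen_cohort, gen_plates

DOSES = (125, 250, 500, 1000, 2500)


def noise_free_series(frequency, doses=DOSES, wells=10**6):
    """Dilution series with non-reactive counts at their exact expectation
    (rounded to integers at large well counts), for analytic-recovery tests."""
    doses = np.asarray(doses)
    nonreactive = np.round(np.exp(-frequency * doses) * wells).astype(int)
    return DilutionSeries.from_arrays(doses, np.full(len(doses), wells), nonreactive)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact simulated cohort (2 patients/stage, 60 cultures each) with
    its plate table, shared across tests that only read it."""
    spec = default_cohort_spec(
        seed=11,
        n_patients_per_stage={"II": 2, "III": 2, "IV": 2},
        cultures_per_patient=60,
    )
    cultures, truth = gen_cohort(spec)
    plate_df = gen_plates(cultures, spec)
    return spec, cultures, truth, plate_df
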