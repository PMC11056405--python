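import logging

import pandas as pd
import pytest

from fbt import synth

logging.getLogger("fbt").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort() -> synth.SyntheticCohort:
    """A 40-patient cohort with the default conditions (kernels on)."""
    return synth.generate_cohort(synth.CohortConfig(n_patients=40, seed=1234))


@pytest.fixture(scope="session")
def confounded_cohort() -> synth.SyntheticCohort:
    """A 150-patient cohort with confounding by indication, no kernels."""
    return synth.generate_cohort(
        synth.CohortConfig(
            n_patients=150, seed=77, effect_kernels=(), confounding_strength=1.0
        )
    )


def records_frame(records, patient_id="P0000", substance="ringer_lactate",
                  t0="2019-01-01 00:00:00"):
    """Build an infusion DataFrame from (start_min, end_min, volume) tuples."""
    base = pd.Timestamp(t0)
    rows = []
    for s, e, v in records:
        rows.append(
            {
                "patient_id": patient_id,
                "substance": substance,
                "start_ts": base + pd.Timedelta(minutes=s),
                "end_ts": base + pd.Timedelta(minutes=e),
                "volume_ml": v,
                "rate_ml_h": v / (e - s) * 60.0,
            }
        )
    return pd.DataFrame(rows)
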