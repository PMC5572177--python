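import numpy as np
import pandas as pd
import pytest

from oncoscreen_cea.synthetic_trial import (CostModel, HazardSpec, TrialDesign,
                                            default_costs, default_design,
                                            default_hazard, generate_trial,
                                            PatientRecord, records_to_frame)

# fixed seeds chosen once for reproducibility of the suite
TRIAL_SEED = 2017


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def hazard(design):
    return default_hazard(design)


@pytest.fixture(scope="session")
def costs():
    return default_costs()


@pytest.fixture(scope="session")
def full_trial(design, hazard, costs):
    """Full-scale synthetic trial (~202k women) shared across tests."""
    return generate_trial(design, hazard, costs, seed=TRIAL_SEED)


@pytest.fixture(scope="session")
def small_design():
    """Scaled-down design for fast structural tests."""
    return TrialDesign(n_control=2000, n_mms=1000, n_uss=1000)


@pytest.fixture(scope="session")
def strong_hazard():
    """Common-event hazard giving tests statistical power at small n."""
    return HazardSpec(baseline_oc_hazard=0.01, lead_time=3.0,
                      reduction_mms=0.4, reduction_uss=0.3)


def make_records(rows, n_years=None):
    """rows: iterable of (t, event) or (t, event, yearly_costs)."""
    recs = []
    for i, row in enumerate(rows):
        t, d, *rest = row
        ycosts = rest[0] if rest else ()
        recs.append(PatientRecord(id=i, arm="x", followup_time=float(t),
                                  event=int(d), yearly_costs=tuple(ycosts)))
    return records_to_frame(recs, n_years=n_years)
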