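import numpy as np
import pandas as pd
import pytest

import teletmle as t


@pytest.fixture(scope="session")
def demo_study():
    """One fixed demo study shared across tests: tables plus built cohort."""
    cfg = t.demo_config(seed=123)
    tables = t.generate_study(cfg)
    cohort = t.build_cohort(tables, window_start=cfg.window_start, window_end=cfg.window_end)
    return {"config": cfg, "tables": tables, "cohort": cohort,
            "episodes": cohort.episodes}


def make_consultations(day_modes, patient_id="PT000001", start="2021-06-01",
                       role="general_medical_practitioner", codes="URTI"):
    """Build a small consultation frame from (day_offset, mode_marker) pairs."""
    cols = ["consultation_id", "patient_id", "date", "clinician_role",
            "mode_marker", "diagnosis_codes"]
    rows = []
    for i, (day, marker) in enumerate(day_modes):
        rows.append(
            {
                "consultation_id": f"C{i:04d}",
                "patient_id": patient_id,
                "date": pd.Timestamp(start) + pd.Timedelta(days=day),
                "clinician_role": role,
                "mode_marker": marker,
                "diagnosis_codes": codes,
            }
        )
    out = pd.DataFrame(rows, columns=cols)
    out["date"] = pd.to_datetime(out["date"])
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(7)
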