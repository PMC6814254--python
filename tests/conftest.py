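import numpy as np
import pandas as pd
import pytest

from coprescribenet.centrality import centrality_table
from coprescribenet.network import filter_opioid_claims
from coprescribenet.outcomes import assemble_panel
from coprescribenet.synth import SynthConfig, generate_study


def make_rx(rows):
    """Build a prescription table from (patient, prescriber, quarter, ...) tuples.

    Each row: (patient_id, prescriber_id, quarter[, daily_dose_mg, mme_factor,
    fill_day, days_supply, is_mat]).
    """
    recs = []
    for r in rows:
        rec = {
            "patient_id": r[0], "prescriber_id": r[1], "quarter": r[2],
            "drug_code": "hydrocodone", "daily_dose_mg": 10.0, "mme_factor": 1.0,
            "fill_day": 0, "days_supply": 30, "is_mat": 0,
        }
        keys = ["daily_dose_mg", "mme_factor", "fill_day", "days_supply", "is_mat"]
        for k, v in zip(keys, r[3:]):
            rec[k] = v
        recs.append(rec)
    return pd.DataFrame(recs)


def random_bipartite_rx(rng, n_patients=40, n_prescribers=10, n_records=300, n_quarters=3):
    """Random prescription table over a grid of patients/prescribers."""
    return make_rx(
        [
            (
                f"P{rng.integers(n_patients)}",
                f"D{rng.integers(n_prescribers)}",
                int(rng.integers(n_quarters)),
            )
            for _ in range(n_records)
        ]
    )


@pytest.fixture(scope="session")
def small_study():
    """A small end-to-end synthetic study shared across tests."""
    cfg = SynthConfig(n_patients=300, n_prescribers=60, seed=11)
    return generate_study(cfg)


@pytest.fixture(scope="session")
def small_panel(small_study):
    cfg = small_study["config"]
    rx_f = filter_opioid_claims(small_study["rx"])
    cent = centrality_table(
        rx_f, cfg.panel_quarters, max_quarter=cfg.n_quarters - 1
    )
    return assemble_panel(
        small_study["patients"], small_study["rx"], small_study["dx"],
        cent, cfg.panel_quarters,
    )
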