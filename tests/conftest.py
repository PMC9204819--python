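from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from notchbench import (
    ChannelSet,
    NotchRegion,
    PSMTable,
    SimParams,
    build_mix_design,
    simulate_experiment,
)

#: reference seed used by all seeded simulation fixtures
REFERENCE_SEED = 11

#: scaled-down generator settings for fast unit tests
SMALL = dict(n_yeast_proteins=60, n_human_proteins=180, psm_per_protein=(4.0, 0.5))


@pytest.fixture(scope="session")
def channels() -> ChannelSet:
    return ChannelSet()


@pytest.fixture(scope="session")
def design():
    return build_mix_design()


@pytest.fixture(scope="session")
def notch() -> NotchRegion:
    return NotchRegion()


@pytest.fixture
def make_table(channels):
    """Factory building a small PSMTable from per-row dicts.

    Unspecified metadata defaults to pass-all quality metrics; intensities
    are given as a list aligned with the channel labels (None -> missing).
    """

    def _make(rows: list[dict]) -> PSMTable:
        records = []
        for i, row in enumerate(rows):
            rec = {
                "psm_id": row.get("psm_id", f"psm{i}"),
                "sequence": row.get("sequence", f"PEPTIDE{i}"),
                "master_proteins": row.get("master_proteins", f"P{i}"),
                "species": row.get("species", "human"),
                "delta_cn": row.get("delta_cn", 1.0),
                "coisolation_pct": row.get("coisolation_pct", 0.0),
                "avg_sn": row.get("avg_sn", np.inf),
            }
            intensities = row.get("intensities", [100.0] * len(channels))
            for label, value in zip(channels.labels, intensities):
                rec[label] = np.nan if value is None else float(value)
            records.append(rec)
        return PSMTable(data=pd.DataFrame(records), channels=channels)

    return _make


@pytest.fixture(scope="session")
def sim_small(design):
    """Seeded small simulation with the notch artifact enabled."""
    params = SimParams(seed=REFERENCE_SEED, **SMALL)
    return simulate_experiment(design, params)


@pytest.fixture(scope="session")
def sim_small_nonotch(design):
    """Seeded small simulation without the notch artifact."""
    params = SimParams(seed=REFERENCE_SEED, notch=None, **SMALL)
    return simulate_experiment(design, params)
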