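from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from icage.events import EventDataset
from icage.schedule import build_default_protocol
from icage.simulate import (
    GenotypeParams,
    SimConfig,
    scenario_paper_like,
    simulate_cohort,
)


def make_roster(spec: dict[str, int]) -> pd.DataFrame:
    rows = [
        (f"{g}{i + 1:02d}", g, "C1", "active", np.nan)
        for g in sorted(spec)
        for i in range(spec[g])
    ]
    return pd.DataFrame(rows, columns=["animal_id", "genotype", "cage_id", "status", "removal_day"])


def make_dataset(visits, pokes=None, licks=None, roster=None, t0=0.0) -> EventDataset:
    """Assemble a small validated dataset from plain tuples.

    visits: (visit_id, animal_id, corner, t_start, t_end)
    pokes:  (visit_id, side, t);  licks: (visit_id, t, n_licks)
    """
    vdf = pd.DataFrame(visits, columns=["visit_id", "animal_id", "corner", "t_start", "t_end"])
    pdf = pd.DataFrame(pokes or [], columns=["visit_id", "side", "t"])
    ldf = pd.DataFrame(licks or [], columns=["visit_id", "t", "n_licks"])
    if roster is None:
        ids = sorted(vdf["animal_id"].unique())
        roster = pd.DataFrame(
            [(a, "NonTg", "C1", "active", np.nan) for a in ids],
            columns=["animal_id", "genotype", "cage_id", "status", "removal_day"],
        )
    return EventDataset(animals=roster, visits=vdf, pokes=pdf, licks=ldf, t0=t0).validate()


@pytest.fixture(scope="session")
def protocol():
    return build_default_protocol()


@pytest.fixture(scope="session")
def tiny_sim():
    """A small but full-calendar simulation shared across tests."""
    cfg = SimConfig(
        n_per_genotype={"NonTg": 3, "TG": 3},
        params={
            "NonTg": GenotypeParams(visit_rate_dark=1.2, visit_rate_light=0.3),
            "TG": GenotypeParams(visit_rate_dark=1.5, visit_rate_light=0.4,
                                 premature_hazard=0.15, cue_response_rate=0.5),
        },
        protocol=build_default_protocol(),
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def paper_like_sim():
    return simulate_cohort(scenario_paper_like(7))
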