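"""Shared fixtures: synthetic samples reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import cedad


def make_event_table(
    ctv=None, ag=None, pi=None, n=None, rng=None
) -> cedad.EventTable:
    """Build a minimal EventTable with plausible scatter columns."""
    if n is None:
        n = len(next(a for a in (ctv, ag, pi) if a is not None))
    rng = rng or np.random.default_rng(0)
    fsc = 10.0 ** rng.normal(5.0, 0.06, n)
    data = pd.DataFrame(
        {
            "CTV_A": np.ones(n) if ctv is None else np.asarray(ctv, float),
            "AG_A": np.ones(n) if ag is None else np.asarray(ag, float),
            "PI_A": np.ones(n) if pi is None else np.asarray(pi, float),
            "FSC_A": fsc,
            "FSC_H": fsc * rng.normal(0.95, 0.015, n),
            "SSC_A": 10.0 ** (np.log10(fsc) - 0.5 + rng.normal(0, 0.08, n)),
        }
    )
    return cedad.EventTable(data)


@pytest.fixture(scope="session")
def standard_sample():
    """Fast-growth control sample at the standard study conditions."""
    cfg = cedad.SimulationConfig(
        n_initial=20_000,
        n_events_recorded=20_000,
        dye_cv_log2=0.25,
        marker_separation_log10=1.5,
        seed=1,
    )
    return cedad.simulate_population(cfg)


@pytest.fixture(scope="session")
def treated_sample():
    """Slowed-division, elevated-death sample (drug-treated condition)."""
    cfg = cedad.SimulationConfig(
        n_initial=10_000,
        n_events_recorded=10_000,
        division_time_mean_days=1.6,
        death_hazard_per_day=0.15,
        seed=2,
    )
    return cedad.simulate_population(cfg)
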