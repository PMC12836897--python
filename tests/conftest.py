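import datetime as dt

import pandas as pd
import pytest

from medswitch import SimulationConfig, generate_claims


def make_rx(fills, member="M1", drug="sertraline", supply=30):
    """Pharmacy-claims frame from (date, [drug], [supply]) tuples or dates."""
    rows = []
    for f in fills:
        if isinstance(f, tuple):
            date, *rest = f
            d = rest[0] if rest else drug
            s = rest[1] if len(rest) > 1 else supply
        else:
            date, d, s = f, drug, supply
        rows.append((member, pd.Timestamp(date), d, s))
    return pd.DataFrame(rows, columns=["member_id", "fill_date", "drug_name", "days_supply"])


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(n_members=400, seed=7)


@pytest.fixture(scope="session")
def default_bundle(default_config):
    return generate_claims(default_config)


@pytest.fixture(scope="session")
def big_bundle():
    """5000-member bundle at default study conditions."""
    return generate_claims(SimulationConfig(n_members=5000, seed=11))
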