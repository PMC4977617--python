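import io

import pytest
from hypothesis import HealthCheck, settings

import phenodiv as pv

settings.register_profile(
    "suite", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


TOY_CATALOG = """\
trait_key\ttrait_name\tvariable_code\tvariable_label
COL\tColour\t1\tRed
COL\tColour\t2\tGreen
COL\tColour\t3\tBlue
SHP\tShape\t4\tRound
SHP\tShape\t5\tOval
SIZ\tSize\t6\tSmall
SIZ\tSize\t7\tLarge
"""


@pytest.fixture(scope="session")
def catalog():
    return pv.odisha_asg_catalog()


@pytest.fixture()
def toy_catalog():
    return pv.load_catalog(io.StringIO(TOY_CATALOG))


@pytest.fixture(scope="session")
def odisha_panel(catalog):
    """Deterministic odisha-like panel: N=126, exact per-trait counts."""
    return pv.simulate_panel(pv.odisha_like_spec(seed=42, catalog=catalog))


@pytest.fixture(scope="session")
def odisha_bm(odisha_panel):
    return pv.encode_binary(odisha_panel)


def make_records(catalog, state_rows, prefix="G", groups=None):
    """Build a TraitMatrix from rows of {trait_key: label} mappings."""
    records = []
    for i, states in enumerate(state_rows):
        records.append(
            pv.GenotypeRecord(
                accession_id=f"{prefix}{i + 1}",
                name=f"geno-{i + 1}",
                group=None if groups is None else groups[i],
                states=dict(states),
            )
        )
    return pv.TraitMatrix(catalog, records)
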