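"""Shared fixtures: synthetic references, registry, look-up tables, datasets."""

import numpy as np
import pytest

from prevharm import build_lookup_table, default_registry, stack_records
from prevharm.synthetic import (
    default_refs,
    paper_shaped_design,
    paper_shaped_pairs,
    worked_example_fixture,
    zshift_setup,
)


@pytest.fixture(scope="session")
def refs():
    return default_refs()


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def all_pairs():
    pp = paper_shaped_pairs()
    return sorted(set(pp["survey"] + pp["cohort"]))


@pytest.fixture(scope="session")
def lookup_table(refs, registry, all_pairs):
    return build_lookup_table(refs, registry, all_pairs)


@pytest.fixture(scope="session")
def paper_shaped(refs, registry):
    return paper_shaped_design(seed=20260927, refs=refs, registry=registry)


@pytest.fixture(scope="session")
def stacked_records(paper_shaped, lookup_table, registry):
    return stack_records(paper_shaped, lookup_table, registry=registry)


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_fixture()


@pytest.fixture(scope="session")
def zshift_bench():
    """Exact z-shift reference pair plus a standard 300-group design."""
    refs, registry, pairs = zshift_setup()
    groups = [
        ("male" if i % 2 else "female", 6.0 + (i % 21) * 0.5, 1300)
        for i in range(300)
    ]
    table = build_lookup_table(refs, registry, pairs,
                               ages=np.arange(4, 37) * 0.5)
    return {"refs": refs, "registry": registry, "pairs": pairs,
            "groups": groups, "table": table}
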