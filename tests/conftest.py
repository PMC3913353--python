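"""Shared fixtures: a scaled-down synthetic group database.

The scaled fixture keeps the structure of the full-size study conditions
(multiple genus-like groups, planted curation pathologies, 2% within-group
and 20% between-group divergence) at a third of the sequence length so the
whole suite runs quickly; curation length bounds are scaled with it.
"""

from __future__ import annotations

import pytest

from probegrid.curation import CurationCriteria
from probegrid.fixtures import FixtureSpec, generate_fixture
from probegrid.seq_core import DesignParameters


SMALL_SPEC = FixtureSpec(
    n_groups=3, sequences_per_group=6, template_length=600, seed=1
)
SMALL_CRITERIA = CurationCriteria(
    min_length=400, max_length_prokaryote=800, max_length_fungi=900
)


@pytest.fixture(scope="session")
def small_fixture():
    return generate_fixture(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_criteria():
    return SMALL_CRITERIA


@pytest.fixture(scope="session")
def design_params():
    return DesignParameters()
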