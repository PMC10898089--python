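"""Shared fixtures: synthetic reference worlds and prebuilt databases.

Everything is generated programmatically at fixed seeds; screens that
several tests inspect are run once per session.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from contamscreen.config import ScreenConfig
from contamscreen.hmer_index import build_database
from contamscreen.report_io import run_screen
from contamscreen.simulate import SimSpec, generate_query_set, generate_reference_set

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def refset():
    """The default synthetic world (nine divisions, eight kingdoms touched)."""
    return generate_reference_set(seed=1)


@pytest.fixture(scope="session")
def db(refset):
    return build_database(refset.records, refset.taxonomy)


@pytest.fixture(scope="session")
def fungal_world():
    """Two divisions in one kingdom, no planted repeat/conserved elements."""
    spec = SimSpec(
        divisions=(
            ("fung:ascomycetes", ("Fungi", 1)),
            ("fung:basidiomycetes", ("Fungi", 1)),
        ),
        conserved_elements=0,
        repeat_copies=0,
    )
    refset = generate_reference_set(spec, seed=1)
    return refset, build_database(refset.records, refset.taxonomy)


@pytest.fixture(scope="session")
def prok_host_taxid(refset):
    return refset.taxids_for_division("prok:g-proteobacteria")[0]


@pytest.fixture(scope="session")
def euk_host_taxid(refset):
    return refset.taxids_for_division("anml:primates")[0]


@pytest.fixture(scope="session")
def prok_fragments(refset, prok_host_taxid):
    """10-kbp fragments of a diverged strain of the prokaryote host."""
    return generate_query_set(
        refset, "fragments", seed=2, host_taxid=prok_host_taxid, fragment_size=10_000
    )


@pytest.fixture(scope="session")
def clean_prok_screen(refset, db, prok_host_taxid, prok_fragments):
    """Specificity run: fragments screened with the correct taxid."""
    return run_screen(prok_fragments.records, prok_host_taxid, db)


@pytest.fixture(scope="session")
def mock_host_screen(refset, db, euk_host_taxid, prok_fragments):
    """Sensitivity run: prokaryote fragments declared as a eukaryote."""
    cfg = ScreenConfig(repeat_masking=False)
    return run_screen(prok_fragments.records, euk_host_taxid, db, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
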