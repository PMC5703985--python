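import numpy as np
import pytest

from metalsites.geometry import load_template_library
from metalsites.pdb_io import parse_structure
from metalsites.synthetic import (
    CorpusRequest,
    ProteinLigand,
    SiteSpec,
    generate_corpus,
    generate_structure,
)


@pytest.fixture(scope="session")
def template_library():
    return load_template_library()


ZN_CCHH = SiteSpec(
    "ZN",
    (
        ProteinLigand("CYS", ("SG",)),
        ProteinLigand("CYS", ("SG",)),
        ProteinLigand("HIS", ("NE2",)),
        ProteinLigand("HIS", ("ND1",)),
    ),
    "tet",
    noise_sigma=0.0,
    resolution=1.8,
    ph=7.5,
)


@pytest.fixture(scope="session")
def zn_cchh_spec():
    return ZN_CCHH


@pytest.fixture(scope="session")
def zn_cchh_model():
    text, _ = generate_structure(ZN_CCHH, seed=3, pdb_id="ZTET")
    return parse_structure(text, "ZTET")


@pytest.fixture(scope="session")
def small_corpus():
    """A mixed-fate corpus exercising every cascade stage."""
    request = CorpusRequest(
        n_survivors=20,
        n_resolution_fail=10,
        n_coligand_fail=10,
        n_protein_min_fail=5,
        n_redundancy_families=5,
        copies_per_family=3,
        n_symmetric_dup=4,
    )
    files, manifest = generate_corpus(request, seed=42)
    models = {pid: parse_structure(text, pid) for pid, text in files.items()}
    return files, models, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
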