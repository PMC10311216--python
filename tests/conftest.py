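"""Shared fixtures: toy catalogues, hosts, and the heavyweight default
three-regime cohort analyses reused by the cohort-level acceptance tests."""

import numpy as np
import pytest

from glycometa.pipeline import run_default_cohort
from glycometa.refdb import ReferenceEntry
from glycometa.synthetic import generate_catalogue, generate_host

#: Seeds of the five default cohorts scored in the cluster-recovery check.
COHORT_SEEDS = (101, 102, 103, 104, 105)


@pytest.fixture(scope="session")
def toy_catalogue():
    """Small deterministic catalogue: 5 families x 4 entries (no AA)."""
    return generate_catalogue(5, 4, seed=11)


@pytest.fixture(scope="session")
def toy_host():
    return generate_host(10_000, seed=3)


@pytest.fixture(scope="session")
def cohort_runs():
    """Full pipeline runs of the default 3-regime x 10-sample x 20k-read
    cohort under five cohort seeds (the study conditions).  Session-scoped:
    several acceptance tests read from the same runs."""
    return [run_default_cohort(seed=s) for s in COHORT_SEEDS]


def make_entry(ref_id, aa_seq, family="GH10", cazy_class="GH",
               functions=None, substrates=None, taxon=None):
    return ReferenceEntry(
        ref_id=ref_id, aa_seq=aa_seq, family=family, cazy_class=cazy_class,
        functions=[("3.2.1.1", 1.0)] if functions is None else functions,
        substrates=[("Plant", 1.0)] if substrates is None else substrates,
        taxon=taxon or {"phylum": "Bacteroidota", "family": "Bacteroidaceae",
                        "genus": "Bacteroides", "species": "Bacteroides sp1"},
    )


def random_protein(rng, length):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
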