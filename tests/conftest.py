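import random
import re

import pytest
from hypothesis import settings

from mriokit.knowledge_base import (
    AnalysisSpec,
    KnowledgeBase,
    TermRecord,
    build_default_kb,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

# BIDS filename grammar for the entities/suffixes this toolkit emits.
BIDS_PATH_RE = re.compile(
    r"^sub-(?P<sub>[a-zA-Z0-9]+)"
    r"(/ses-(?P<ses>[a-zA-Z0-9]+))?"
    r"/(?P<dt>anat|func|dwi)"
    r"/sub-(?P=sub)"
    r"(_ses-(?P=ses))?"
    r"(_run-[0-9]+)?"
    r"_(T1w|T2w|FLAIR|PDw|bold|dwi)\.nii\.gz$"
)


@pytest.fixture(scope="session")
def kb():
    return build_default_kb()


@pytest.fixture(scope="session")
def bids_path_re():
    return BIDS_PATH_RE


def make_random_kb(rng: random.Random, n_types: int = 10, n_analyses: int = 5):
    """A small random type tree plus random DNF analyses, for property
    tests of the assignment machinery."""
    types = [
        TermRecord("MRIOKIT:ty-0", "type 0", namespace="PROVISIONAL")
    ]
    for i in range(1, n_types):
        parent = types[rng.randrange(len(types))].iri
        types.append(
            TermRecord(
                f"MRIOKIT:ty-{i}",
                f"type {i}",
                parent_iri=parent,
                namespace="PROVISIONAL",
            )
        )
    type_iris = [t.iri for t in types]
    analyses = []
    for j in range(n_analyses):
        dnf = tuple(
            tuple(rng.sample(type_iris, rng.randint(1, 3)))
            for _ in range(rng.randint(1, 3))
        )
        analyses.append(
            AnalysisSpec(
                f"MRIOKIT:an-{j}",
                f"analysis {j}",
                input_dnf=dnf,
                provenance="DEFAULT",
            )
        )
    terms = types + [
        TermRecord(a.iri, a.label, namespace="PROVISIONAL") for a in analyses
    ]
    return KnowledgeBase(terms=tuple(terms), analyses=tuple(analyses)), type_iris
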