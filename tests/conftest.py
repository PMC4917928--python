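"""Shared fixtures: tiny hand-traceable ontologies and corpora.

The toy corpus is the 4-protein example worked throughout the tests:
ontology r <- a <- {a1, a2}, r <- b; proteins P1:{a1}, P2:{a1}, P3:{a2},
P4:{b}.  Extended sets and information contents are computed by hand in
the tests that use them.
"""

import io

import pytest

from funcoh import parse_obo, parse_tsv

TOY_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: r
namespace: molecular_function

[Term]
id: GO:0000002
name: a
namespace: molecular_function
is_a: GO:0000001 ! r

[Term]
id: GO:0000003
name: b
namespace: molecular_function
is_a: GO:0000001 ! r

[Term]
id: GO:0000004
name: a1
namespace: molecular_function
is_a: GO:0000002 ! a

[Term]
id: GO:0000005
name: a2
namespace: molecular_function
is_a: GO:0000002 ! a
"""

R, A, B, A1, A2 = (f"GO:000000{i}" for i in range(1, 6))

TOY_TSV = """\
P1\tGO:0000004
P2\tGO:0000004
P3\tGO:0000005
P4\tGO:0000003
"""


@pytest.fixture(scope="session")
def toy_ontology():
    return parse_obo(io.StringIO(TOY_OBO))


@pytest.fixture()
def toy_corpus(toy_ontology):
    return parse_tsv(io.StringIO(TOY_TSV), toy_ontology)
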