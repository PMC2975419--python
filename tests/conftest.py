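import textwrap

import pytest

TINY_OBO = textwrap.dedent(
    """\
    format-version: 1.2

    [Term]
    id: GO:0000001
    name: root process
    namespace: biological_process

    [Term]
    id: GO:0000002
    name: middle process
    namespace: biological_process
    is_a: GO:0000001

    [Term]
    id: GO:0000003
    name: leaf process
    namespace: biological_process
    is_a: GO:0000002

    [Term]
    id: GO:0000004
    name: twin-parent process
    namespace: biological_process
    is_a: GO:0000001
    is_a: GO:0000002

    [Term]
    id: GO:0000005
    name: retired process
    namespace: biological_process
    is_obsolete: true

    [Term]
    id: GO:0000010
    name: root component
    namespace: cellular_component

    [Term]
    id: GO:0000011
    name: nucleus-like
    namespace: cellular_component
    is_a: GO:0000010

    [Term]
    id: GO:0000012
    name: mitochondrion-like
    namespace: cellular_component
    is_a: GO:0000010
    """
)


@pytest.fixture
def tiny_obo_path(tmp_path):
    path = tmp_path / "tiny.obo"
    path.write_text(TINY_OBO)
    return path


@pytest.fixture
def tiny_ontology(tiny_obo_path):
    from bayespin.io_formats import read_obo

    return read_obo(tiny_obo_path)
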