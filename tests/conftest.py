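import pytest

from hissa import eight_n_design, five_n_design


@pytest.fixture(scope="session")
def design_8n():
    return eight_n_design()


@pytest.fixture(scope="session")
def design_5n():
    return five_n_design()


def build_read(design, umi="", linker="", variable="", tail=None, adapter=None):
    """Assemble a raw read string for a design, with overridable parts."""
    if tail is None:
        tail = design.constant_insert
    if adapter is None:
        adapter = design.adapter3
    return umi + design.anchor5 + linker + variable + tail + adapter
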