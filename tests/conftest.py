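import pytest

from cdarabbit import (
    demo_repository_path,
    load_cdm_catalog,
    parse_repository,
    resolve_all_rmim_classes,
)
from cdarabbit.default_mapper import load_default_rules


DECOR_HEAD = (
    '<?xml version="1.0" encoding="UTF-8"?>\n'
    '<decor xmlns:hl7="urn:hl7-org:v3" xmlns:sdtc="urn:hl7-org:sdtc">\n<rules>\n'
)
DECOR_TAIL = "</rules>\n</decor>\n"


def make_decor(body: str) -> bytes:
    """Wrap template markup into a minimal decor repository file."""
    return (DECOR_HEAD + body + DECOR_TAIL).encode("utf-8")


@pytest.fixture(scope="session")
def catalogue():
    return load_cdm_catalog("5.4")


@pytest.fixture(scope="session")
def rules(catalogue):
    return load_default_rules(catalogue)


@pytest.fixture(scope="session")
def demo_repo():
    repo = parse_repository(demo_repository_path())
    resolve_all_rmim_classes(repo)
    return repo
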