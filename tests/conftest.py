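import pytest

from nifdiv import simulate
from nifdiv.qc import ReferencePanel
from nifdiv.records import INTERNAL_STANDARD


@pytest.fixture(scope="session")
def refs():
    """Two references per isozyme plus the internal standard."""
    return simulate.generate_reference_set(2, seed=7)


@pytest.fixture(scope="session")
def nitro_refs(refs):
    return [r for r in refs if r.isozyme != INTERNAL_STANDARD]


@pytest.fixture(scope="session")
def internal_standard(refs):
    return next(r for r in refs if r.isozyme == INTERNAL_STANDARD)


@pytest.fixture(scope="session")
def panel(refs):
    return ReferencePanel.build(refs)


@pytest.fixture(scope="session")
def amplicons(nitro_refs):
    return {r.id: simulate.reference_amplicon(r) for r in nitro_refs}
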