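import pytest

import mitocomp


@pytest.fixture(scope="session")
def ref_table():
    """Packaged Liriomyza chinensis (MG252777) annotation table."""
    return mitocomp.load_reference_table()
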