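import pytest
from hypothesis import settings

from cystomics import ProteinDB

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_db() -> ProteinDB:
    return ProteinDB(
        {
            "HBA": "MVLSPADKTNVKAAWGKVGAHAGEYGAEALERMF",
            "ALB": "MKWVTFISLLFLFSSAYSRGVFRRDAHKSEVAHRFKDLGEENFKALVLIA",
        }
    )

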