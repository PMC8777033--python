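import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `import oracle` work

from cofseof import toynet_a, toynet_b


@pytest.fixture
def toy_a():
    return toynet_a()


@pytest.fixture
def toy_b():
    return toynet_b()
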