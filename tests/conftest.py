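from pathlib import Path

import pytest

FIXTURES = Path(__file__).parent / "fixtures"


@pytest.fixture
def fixture_maf() -> Path:
    return FIXTURES / "example.maf"


@pytest.fixture
def write_maf(tmp_path):
    """Write MAF text to a temp file and return its path."""

    def _write(text: str, name: str = "input.maf") -> Path:
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
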