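import pytest

from biocrumbs.eutils.config import EutilsConfig
from biocrumbs.mock.eutils_mock import MockEutilsServer, default_transcript_script


@pytest.fixture()
def transcript_server():
    """Scripted E-utilities emulator preloaded with the transcript terms."""
    with MockEutilsServer(default_transcript_script()) as server:
        yield server


@pytest.fixture()
def mock_cfg(transcript_server, tmp_path):
    """Config pointed at the emulator with fast search timeouts."""
    return EutilsConfig(
        email="tester@example.org",
        base_url=transcript_server.base_url,
        download_dir=tmp_path / "downloads",
        timeouts={"search": 5.0},
    )
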