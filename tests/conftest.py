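import pandas as pd
import pytest

from ocorm.io import read_sessions, session_from_row, example_sessions_path


@pytest.fixture(scope="session")
def example_sessions():
    """The three packaged example sessions (printed subject records)."""
    df = read_sessions(example_sessions_path())
    return [session_from_row(row)[0] for _, row in df.iterrows()]


@pytest.fixture(scope="session")
def example_frame() -> pd.DataFrame:
    return read_sessions(example_sessions_path())
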