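import pytest

from pigmentscreen import SyntheticScreenSpec, generate_screen, run_screen_cascade


@pytest.fixture(scope="session")
def preset_screen():
    """Full-scale spiked screen simulation (640 compounds), shared read-only."""
    return generate_screen(SyntheticScreenSpec(seed=11))


@pytest.fixture(scope="session")
def preset_result(preset_screen):
    """Cascade result on the preset screen."""
    return run_screen_cascade(preset_screen)
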