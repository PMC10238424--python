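import pytest

import clicklabel as cl


@pytest.fixture(scope="session")
def az488():
    return cl.lookup_dye("AZ488")


@pytest.fixture(scope="session")
def cy5():
    return cl.lookup_dye("Cy5")


@pytest.fixture(scope="session")
def antibody():
    return cl.lookup_protein("Ab")


@pytest.fixture(scope="session")
def apomb():
    return cl.lookup_protein("apoMb")


@pytest.fixture(scope="session")
def fig2():
    """Reference monitoring scenario, default (noisy) settings."""
    return cl.fig2_scenario(seed=7)


@pytest.fixture(scope="session")
def fig2_clean(fig2):
    """Reference scenario with all noise switched off."""
    return fig2.with_noise(
        chromatogram_rel=0.0, spectrum_abs=0.0, fcs_rel=0.0, ms_rel=0.0
    )


@pytest.fixture(scope="session")
def fig2_conditions(fig2):
    """Reaction conditions of the reference experiment (a0=74.67 uM etc.)."""
    return fig2.rc
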