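import pytest

import snstrace as st


@pytest.fixture(scope="session")
def locus_fixture():
    """Synthetic locus with promoter and CDS trigger windows (seed 42)."""
    locus, windows = st.make_locus_fixture(seed=42)
    return locus, windows


@pytest.fixture(scope="session")
def trigger10(locus_fixture):
    """Spacing-10 transition trigger on the promoter window."""
    locus, windows = locus_fixture
    w0, w1 = windows["promoter"]
    frag = st.TargetFragment(id="promoter_frag", sequence=locus[w0 - 1 : w1])
    return st.design_marked_trigger(frag, st.SNSDesign(spacing=10))


@pytest.fixture(scope="session")
def variant_locus(locus_fixture, trigger10):
    locus, _ = locus_fixture
    return st.project_sns_onto_locus(locus, trigger10)
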