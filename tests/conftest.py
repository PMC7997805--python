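import pytest

import startyper as st
from startyper import pipeline


@pytest.fixture(scope="session")
def model38():
    return st.load_region_model("GRCh38")


@pytest.fixture(scope="session")
def model37():
    return st.load_region_model("GRCh37")


@pytest.fixture(scope="session")
def panel38():
    return st.load_site_panel("GRCh38")


@pytest.fixture(scope="session")
def defs38(model38):
    return st.load_allele_definitions("GRCh38", model38)


@pytest.fixture(scope="session")
def call_counts(model38, panel38, defs38):
    """Simulate a counts bundle for a diplotype and genotype it."""

    def _run(genotype, seed=0, **kw):
        bundle = st.simulate_counts(
            st.SimulationSpec(genotype=genotype, seed=seed, **kw),
            model=model38, panel=panel38, defs=defs38)
        return pipeline.call_from_counts(bundle, model38, panel38, defs38)

    return _run


@pytest.fixture(scope="session")
def na12878(model38, panel38, defs38):
    """Worked-example sample, noise-free: 2 full CYP2D6 + one exon-1
    CYP2D6-CYP2D7 hybrid + 2 CYP2D7 (the *3/*68+*4 structure)."""
    bundle = st.simulate_counts(
        st.SimulationSpec(genotype="*3/*68+*4", seed=42, exact=True),
        model=model38, panel=panel38, defs=defs38)
    return pipeline.call_from_counts(bundle, model38, panel38, defs38)
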