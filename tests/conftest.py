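import logging

import pytest

from zymokin import msquant, synthetic

# proteoform-construction warnings for mass-only species are expected noise
logging.getLogger("zymokin").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def wt_scenario():
    """Reference quenched-flow scenario: 16 uM zymogen, 0.16 uM activator."""
    return synthetic.wild_type_scenario()


def standard_assignments(scenario):
    """Assignments for every scenario species plus the internal standard."""
    out = [msquant.SpeciesAssignment(pf) for pf in scenario.species.values()]
    out.append(msquant.SpeciesAssignment(
        synthetic.internal_standard_proteoform()))
    return out
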