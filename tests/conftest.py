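import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tnfpop as tp

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_timer():
    """Death timer dX/dt = k with closed-form ToD = theta/(m k)."""
    return tp.make_toy_timer(k=1.0, theta=5.0)


@pytest.fixture(scope="session")
def toy_timer_inert():
    """Timer plus a decoupled production rate with zero ToD elasticity."""
    return tp.make_toy_timer(k=1.0, theta=5.0, with_inert=True)


@pytest.fixture(scope="session")
def receptor_model():
    """Synthetic receptor/inhibitor network (ligand binding, protector arm)."""
    return tp.make_toy_receptor_model()


@pytest.fixture(scope="session")
def receptor_resting_state(receptor_model):
    return tp.equilibrate(receptor_model)


@pytest.fixture
def no_stimulus():
    return tp.StimulusProtocol(dose_ng_ml=0.0, horizon_hours=100.0)


MINIMAL_SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="minimal">
    <listOfCompartments>
      <compartment id="cell" size="1"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="A" name="protein A" initialAmount="0" compartment="cell"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="k_syn" value="2.0"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="synth" reversible="false">
        <listOfProducts>
          <speciesReference species="A" stoichiometry="1"/>
        </listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <ci>k_syn</ci>
          </math>
        </kineticLaw>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""


@pytest.fixture
def minimal_sbml(tmp_path):
    path = tmp_path / "minimal.xml"
    path.write_text(MINIMAL_SBML)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(42)
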