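import numpy as np
import pytest

from stentflow.geometry import make_straight_vessel
from stentflow.ldpm import FluidProperties
from stentflow.stent import StentDesign, deploy_stent, extract_cells


@pytest.fixture(scope="session")
def blood() -> FluidProperties:
    return FluidProperties(density=1100.0, viscosity=3.6e-3)


@pytest.fixture(scope="session")
def nominal_deployment():
    """48-wire device deployed in a vessel of exactly nominal diameter."""
    design = StentDesign(n_wires=48, nominal_diameter=4.5e-3, nominal_length=10e-3)
    vessel = make_straight_vessel(2.25e-3, 0.06, 2.5e-4)
    dep = deploy_stent(design, vessel, 5e-3)
    return design, vessel, dep


@pytest.fixture(scope="session")
def nominal_cells(nominal_deployment):
    design, _vessel, dep = nominal_deployment
    return extract_cells(dep, design)


@pytest.fixture(scope="session")
def oversized_deployment():
    """Same device constrained by a narrower vessel (oversized device)."""
    design = StentDesign(n_wires=48, nominal_diameter=4.5e-3, nominal_length=10e-3)
    vessel = make_straight_vessel(2.0e-3, 0.08, 2.5e-4)
    dep = deploy_stent(design, vessel, 5e-3)
    return design, vessel, dep
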