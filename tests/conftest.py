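import numpy as np
import pytest

from unfoldkit.datatypes import TransitionParams
from unfoldkit.synthetic_data import HelixFixtureSpec, make_helix_structure


@pytest.fixture(scope="session")
def dsc_params():
    """The two calorimetric transitions of the study system (dCp = 0)."""
    return (TransitionParams(52.3, 55.0), TransitionParams(69.8, 50.0))


@pytest.fixture(scope="session")
def helix12():
    return make_helix_structure(HelixFixtureSpec(12))


@pytest.fixture(scope="session")
def helix20():
    return make_helix_structure(HelixFixtureSpec(20))


@pytest.fixture(scope="session")
def extended8():
    """Fully extended (phi = psi = 180) chain: no H-bonds, no tethers."""
    return make_helix_structure(HelixFixtureSpec(8, phi=180.0, psi=180.0))


@pytest.fixture(scope="session")
def helix20_graded(helix20):
    """20-mer helix with deterministically graded H-bond strengths.

    Scaling each bond by its donor position creates the strength
    hierarchy a real (asymmetric) structure has, so the network erodes
    gradually instead of collapsing in a single step.
    """
    from dataclasses import replace

    from unfoldkit.rigidity import detect_hbonds

    base = detect_hbonds(helix20)
    graded = [
        replace(hb, energy=hb.energy * (0.6 + 0.05 * helix20.atoms[hb.donor].res_index))
        for hb in base
    ]
    return helix20, graded
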