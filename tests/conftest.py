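import cmath

import numpy as np
import pytest

from nanoswitch.forward_model import Layer, LayerStack, TipModel
from nanoswitch.materials import load_material_table, membrane_stack, two_layer_stack


@pytest.fixture(scope="session")
def tip():
    """Tip with the published modelling parameters (complex g)."""
    return TipModel(
        tapping_amplitude_a=80.0,
        apex_radius_r=60.0,
        spheroid_length_L=300.0,
        g_factor=0.7 * cmath.exp(0.06j),
        min_height=0.0,
    )


@pytest.fixture(scope="session")
def real_tip():
    """Same geometry with a real g, for lossless-phase invariants."""
    return TipModel(g_factor=0.7 + 0j)


@pytest.fixture(scope="session")
def si_stack():
    return LayerStack.from_media([1.0 + 0j, 11.7 + 0j], [])


@pytest.fixture(scope="session")
def uniform_stack():
    return LayerStack.from_media([2.5 + 0j, 2.5 + 0j], [])


@pytest.fixture(scope="session")
def material_table():
    return load_material_table()


@pytest.fixture(scope="session")
def background_stack(material_table):
    """Air | 10 nm SiN | D2O."""
    return membrane_stack(table=material_table)


@pytest.fixture(scope="session")
def vesicle_stack(material_table):
    """Air | 10 nm SiN | 4 nm trans-lipid | D2O."""
    return membrane_stack("lipid_trans", table=material_table)


@pytest.fixture(scope="session")
def si_reference(material_table):
    return two_layer_stack("si", material_table)
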