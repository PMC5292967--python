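import numpy as np
import pytest

from uvnma.enm import BlockDefinition, ENModel
from uvnma.structures import Structure
from uvnma.synthetic import ComplexLayout, ComplexSpec, HelixSpec, make_helix, make_u_v_pair


@pytest.fixture(scope="session")
def layout():
    return ComplexLayout()


@pytest.fixture(scope="session")
def uv_default():
    """Planted 8.5° receptor rotation, no piston/twist/noise."""
    return make_u_v_pair(ComplexSpec())


@pytest.fixture(scope="session")
def uv_full():
    """All perturbations planted: 8.5° rotation, 0.5 Å piston, 19° twist."""
    return make_u_v_pair(ComplexSpec(receptor_rotation_deg=8.5, piston_A=0.5,
                                     tm2_twist_deg=19.0))


def build_bundle(n_res=20, centers=((0.0, 0.0), (7.2, 0.0), (16.7, 0.0), (23.9, 0.0))):
    """Four-helix test bundle: two tight pairs joined by a weak link,
    so the lowest nonzero mode (the inter-pair hinge) is well separated
    from the rest of the spectrum."""
    atoms = []
    serial = 1
    for k, (cx, cy) in enumerate(centers):
        h = make_helix(HelixSpec(n_res, (cx, cy, 0.0), (0, 0, 1),
                                 chain_id="ABCD"[k], phase_deg=40.0 * k),
                       serial_start=serial)
        atoms.extend(h.atoms)
        serial += len(h)
    st = Structure(atoms)
    blocks = BlockDefinition.from_segments(
        [(i * n_res, (i + 1) * n_res) for i in range(4)])
    return st, blocks


@pytest.fixture(scope="session")
def bundle4():
    st, blocks = build_bundle()
    return st, ENModel(st.coords, cutoff=12.0), blocks
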