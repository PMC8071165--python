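import numpy as np
import pytest

from cxcaxis import default_segment_map, make_helical_bundle
from cxcaxis.chemistry import element_from_atom_name
from cxcaxis.io import Structure


def build_structure(residues, title="fixture"):
    """Structure from [(chain, resid, resname, {atom_name: xyz}), ...]."""
    names, elements, res_names, res_ids, chains, coords = [], [], [], [], [], []
    for chain, resid, resname, atoms in residues:
        for atom, xyz in atoms.items():
            names.append(atom)
            elements.append(element_from_atom_name(atom))
            res_names.append(resname)
            res_ids.append(resid)
            chains.append(chain)
            coords.append(xyz)
    return Structure(
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        res_names=np.array(res_names, dtype=object),
        res_ids=np.array(res_ids),
        chain_ids=np.array(chains, dtype=object),
        coords=np.array(coords, dtype=float),
        title=title,
    )


@pytest.fixture(scope="session")
def segment_map():
    return default_segment_map()


@pytest.fixture(scope="session")
def bundle(segment_map):
    return make_helical_bundle(segment_map)
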