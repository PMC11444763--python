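import numpy as np
import pytest

from achescreen.structure_contacts import Frame


def make_frame(coords, elements, ligand_mask, names=None, resids=None, resnames=None):
    """Assemble a minimal Frame for geometric tests."""
    n = len(coords)
    elements = np.array(elements, dtype=object)
    if names is None:
        names = np.array([f"{e}{i}" for i, e in enumerate(elements)], dtype=object)
    if resids is None:
        resids = np.where(np.asarray(ligand_mask), 999, 1)
    if resnames is None:
        resnames = np.where(np.asarray(ligand_mask), "LIG", "ALA").astype(object)
    return Frame(
        coordinates=np.asarray(coords, dtype=float),
        elements=elements,
        atom_names=np.asarray(names, dtype=object),
        residue_names=np.asarray(resnames, dtype=object),
        residue_ids=np.asarray(resids, dtype=int),
        chains=np.array(["L" if m else "A" for m in ligand_mask], dtype=object),
        ligand_mask=np.asarray(ligand_mask, dtype=bool),
    )


@pytest.fixture
def hb_frame():
    """Receptor N-H donor and a ligand O acceptor in collinear HB geometry."""
    return make_frame(
        coords=[[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.9, 0.0, 0.0]],
        elements=["N", "H", "O"],
        ligand_mask=[False, False, True],
    )
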