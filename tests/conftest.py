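import numpy as np
import pytest

from dimerlink import structio


def make_structure(atoms, id="toy"):
    """Build a StructureModel from tuples
    (chain, resnum, resname, atom_name, element, xyz [, b_factor])."""
    st = structio.StructureModel(id=id)
    chain_map = {}
    serial = 0
    for entry in atoms:
        chain, resnum, resname, name, element, xyz = entry[:6]
        b = entry[6] if len(entry) > 6 else 0.0
        serial += 1
        if chain not in chain_map:
            chain_map[chain] = structio.Chain(chain_id=chain)
            st.chains.append(chain_map[chain])
        ch = chain_map[chain]
        if not ch.residues or ch.residues[-1].number != resnum:
            ch.residues.append(structio.Residue(
                name=resname, number=resnum, insertion_code="", hetero=False))
        ch.residues[-1].atoms.append(structio.AtomRecord(
            serial=serial, name=name, element=element, alt_loc="",
            residue_name=resname, residue_number=resnum, insertion_code="",
            chain_id=chain, xyz=np.asarray(xyz, float), occupancy=1.0, b_factor=b))
    return st


@pytest.fixture
def structure_factory():
    return make_structure


@pytest.fixture
def single_carbon():
    return make_structure([("A", 1, "ALA", "C", "C", (0.0, 0.0, 0.0))])


@pytest.fixture(scope="session")
def planted_small():
    """One small planted-path ensemble shared across tests."""
    from dimerlink import synthgen

    spec = synthgen.PlantedEnsembleSpec(seed=7, n_frames=500)
    return synthgen.make_planted_ensemble(spec)
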