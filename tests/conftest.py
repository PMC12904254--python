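"""Shared fixtures: reduced schemes, table landscapes, toy structures."""

import gemmi
import numpy as np
import pytest

from coevoscape import LibraryScheme


@pytest.fixture
def scheme_2x2():
    """Two positions (one per chain), two letters."""
    return LibraryScheme(chain_a_positions=(1,), chain_b_positions=(2,), alphabet=("F", "V"))


@pytest.fixture
def scheme_4x2():
    """Four positions (two per chain), two letters."""
    return LibraryScheme(
        chain_a_positions=(1, 2), chain_b_positions=(3, 4), alphabet=("F", "V")
    )


@pytest.fixture
def scheme_6x5():
    """Reduced 6-position DTS scheme (15,625 sequences, exhaustively tractable)."""
    return LibraryScheme(chain_a_positions=(8, 11, 14), chain_b_positions=(29, 30, 33))


def table_fitness(table):
    """Wrap a dict sequence->fitness as a vectorizable fitness function."""

    def fn(seqs):
        if isinstance(seqs, str):
            return table[seqs]
        return np.array([table[s] for s in seqs], dtype=float)

    return fn


@pytest.fixture
def make_table_fitness():
    return table_fitness


def build_structure(chain_atoms):
    """Build a gemmi.Structure from {chain_id: [(resnum, resname, atom, element, xyz)]}."""
    st = gemmi.Structure()
    st.name = "toy"
    model = gemmi.Model("1")
    for chain_id, rows in chain_atoms.items():
        chain = gemmi.Chain(chain_id)
        residues = {}
        for resnum, resname, atom_name, element, xyz in rows:
            key = (resnum, resname)
            if key not in residues:
                res = gemmi.Residue()
                res.name = resname
                res.seqid = gemmi.SeqId(resnum, " ")
                residues[key] = res
            at = gemmi.Atom()
            at.name = atom_name
            at.element = gemmi.Element(element)
            at.pos = gemmi.Position(*xyz)
            residues[key].add_atom(at)
        for res in residues.values():
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    return st


@pytest.fixture
def make_structure():
    return build_structure
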