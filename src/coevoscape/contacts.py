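"""Inter-chain atomic contacts and library/framework classification.

Given a complex structure, all heavy-atom pairs across two chains closer than
a cutoff (default 4.0 A; a 3.8 A residue-level convention is available by
flag) are collected from the first model, major alternate locations only,
waters and ligands excluded.  Contacts are then classified by whether each
residue is a randomized *library* position of the scheme or a constant
*framework* position: LL (A-library on B-library), LF_A (A-library on
B-framework), LF_B (A-framework on B-library) or FF.  The contact ratio
LL / (LF_A + LF_B) summarizes how much of the interface the randomized
patches themselves carry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

from .library import LibraryScheme

__all__ = ["Contact", "ContactSummary", "inter_chain_contacts", "classify_contacts"]


class Contact(NamedTuple):
    atom_a: str
    atom_b: str
    residue_a: int
    residue_b: int
    resname_a: str
    resname_b: str
    distance: float


@dataclass
class ContactSummary:
    contacts: list
    counts: dict  # LL / LF_A / LF_B / FF
    cutoff: float
    contact_ratio: Optional[float]  # None when no LF contacts exist

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.contacts, columns=Contact._fields)


def _chain_atoms(chain) -> list:
    """Heavy atoms of amino-acid residues, altloc '' or 'A' only."""
    atoms = []
    for res in chain:
        info = gemmi.find_tabulated_residue(res.name)
        if info is None or not info.is_amino_acid():
            continue
        for atom in res:
            if atom.element == gemmi.Element("H"):
                continue
            if atom.altloc not in ("\0", "", "A"):
                continue
            atoms.append((atom.name, res.seqid.num, res.name, atom.pos))
    return atoms


def inter_chain_contacts(
    structure,
    chain_a_id: str,
    chain_b_id: str,
    cutoff: float = 4.0,
) -> list:
    """All cross-chain heavy-atom pairs at distance strictly below ``cutoff``.

    ``structure`` is a path to a PDB/mmCIF file or a ``gemmi.Structure``.
    Only the first model is examined.
    """
    if not isinstance(structure, gemmi.Structure):
        structure = gemmi.read_structure(str(structure))
    model = structure[0]
    available = [ch.name for ch in model]
    chains = {}
    for cid in (chain_a_id, chain_b_id):
        if cid not in available:
            raise KeyError(f"chain {cid!r} not found; available chains: {available}")
        chains[cid] = _chain_atoms(model[cid])
    atoms_a, atoms_b = chains[chain_a_id], chains[chain_b_id]
    if not atoms_a or not atoms_b:
        return []
    xa = np.array([[p.x, p.y, p.z] for *_, p in atoms_a])
    xb = np.array([[p.x, p.y, p.z] for *_, p in atoms_b])
    d = np.sqrt(((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2))
    ii, jj = np.nonzero(d < cutoff)
    out = []
    for i, j in zip(ii, jj):
        name_a, num_a, rn_a, _ = atoms_a[i]
        name_b, num_b, rn_b, _ = atoms_b[j]
        out.append(Contact(name_a, name_b, num_a, num_b, rn_a, rn_b, float(d[i, j])))
    out.sort(key=lambda c: (c.residue_a, c.residue_b, c.atom_a, c.atom_b))
    return out


def classify_contacts(contacts: Sequence[Contact], scheme: LibraryScheme, cutoff: float = 4.0) -> ContactSummary:
    """Label contacts LL/LF_A/LF_B/FF by library membership of both residues.

    The scheme's chain A/B position lists give the randomized residue numbers
    on each chain; every other residue is framework.  contact_ratio =
    LL / (LF_A + LF_B), undefined (None) when no LF contact exists.
    """
    lib_a = set(scheme.chain_a_positions)
    lib_b = set(scheme.chain_b_positions)
    counts = {"LL": 0, "LF_A": 0, "LF_B": 0, "FF": 0}
    for c in contacts:
        a_lib = c.residue_a in lib_a
        b_lib = c.residue_b in lib_b
        if a_lib and b_lib:
            counts["LL"] += 1
        elif a_lib:
            counts["LF_A"] += 1
        elif b_lib:
            counts["LF_B"] += 1
        else:
            counts["FF"] += 1
    lf = counts["LF_A"] + counts["LF_B"]
    ratio = counts["LL"] / lf if lf > 0 else None
    return ContactSummary(list(contacts), counts, cutoff, ratio)
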