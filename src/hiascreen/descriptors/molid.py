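"""Randić molecular-ID descriptors.

The molecular ID weights every simple path by the product of 1/sqrt(d_i d_j)
over its bonds (d = heavy-atom degree) and sums path weights over the graph;
each atom additionally contributes 1, so an isolated atom has ID 1 and the
total ID of an N-atom molecule is N plus the summed path weights. Per-element
variants (MID_C, MID_N, MID_O, MID_X for halogens) sum only the contributions
of atoms of that element, where a path's weight is shared equally between its
two endpoint atoms. A* variants divide by the heavy-atom count.

Path enumeration is capped at ``MAX_PATH_LENGTH`` bonds; longer paths carry
weights shrinking geometrically and are negligible at drug-like sizes.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem

MAX_PATH_LENGTH = 7
_HALOGENS = {9, 17, 35, 53}

_SUBSETS = {
    "": None,
    "_C": {6},
    "_N": {7},
    "_O": {8},
    "_X": _HALOGENS,
}


def feature_names() -> list[str]:
    names = []
    for suffix in _SUBSETS:
        names.append(f"MID{suffix}")
        names.append(f"AMID{suffix}")
    return names


def molecular_id_descriptors(mol: Chem.Mol) -> dict[str, float]:
    n = mol.GetNumAtoms()
    out: dict[str, float] = {}
    if n == 0:
        return {name: np.nan for name in feature_names()}

    deg = np.array([a.GetDegree() for a in mol.GetAtoms()], dtype=float)
    # bond weight 1/sqrt(d_i d_j); per-atom accumulator of half path weights
    contrib = np.ones(n)

    for length in range(1, MAX_PATH_LENGTH + 1):
        for path in Chem.FindAllPathsOfLengthN(mol, length, useBonds=True):
            bonds = [mol.GetBondWithIdx(b) for b in path]
            w = 1.0
            for b in bonds:
                w /= np.sqrt(deg[b.GetBeginAtomIdx()] * deg[b.GetEndAtomIdx()])
            # endpoints of the path as an atom sequence
            first, last = bonds[0], bonds[-1]
            if length == 1:
                ends = (first.GetBeginAtomIdx(), first.GetEndAtomIdx())
            else:
                e1 = {first.GetBeginAtomIdx(), first.GetEndAtomIdx()}
                e2 = {last.GetBeginAtomIdx(), last.GetEndAtomIdx()}
                a1 = _path_end(e1, bonds[1])
                a2 = _path_end(e2, bonds[-2])
                ends = (a1, a2)
            contrib[ends[0]] += w / 2.0
            contrib[ends[1]] += w / 2.0

    z = np.array([a.GetAtomicNum() for a in mol.GetAtoms()])
    for suffix, subset in _SUBSETS.items():
        if subset is None:
            total = float(contrib.sum())
        else:
            mask = np.isin(z, list(subset))
            total = float(contrib[mask].sum()) if mask.any() else 0.0
        out[f"MID{suffix}"] = total
        out[f"AMID{suffix}"] = total / n
    return out


def _path_end(end_bond_atoms: set[int], neighbour_bond) -> int:
    """The endpoint atom of a terminal bond: the one not shared with the next bond."""
    shared = {neighbour_bond.GetBeginAtomIdx(), neighbour_bond.GetEndAtomIdx()}
    only = end_bond_atoms - shared
    # in rings the terminal bond may share both atoms; fall back arbitrarily
    return only.pop() if only else min(end_bond_atoms)
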