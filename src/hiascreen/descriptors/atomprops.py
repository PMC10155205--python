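"""Per-atom property vectors used as autocorrelation weights.

Property codes follow the conventional one/two-letter suffixes used for 2D
autocorrelation descriptors: m (mass), v (van der Waals volume),
e (Sanderson electronegativity), p (polarizability), i (first ionization
energy), s (Kier–Hall intrinsic state), d (sigma electrons, i.e. heavy
degree), dv (valence electrons minus attached hydrogens), c (Gasteiger
partial charge).
"""

from __future__ import annotations

import math

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdPartialCharges

# Sanderson electronegativity
_SANDERSON = {
    1: 2.592, 5: 2.275, 6: 2.746, 7: 3.194, 8: 3.654, 9: 4.000,
    14: 2.138, 15: 2.515, 16: 2.957, 17: 3.475, 35: 3.219, 53: 2.778,
}
# dipole polarizability, Å^3
_POLARIZABILITY = {
    1: 0.667, 5: 3.03, 6: 1.76, 7: 1.10, 8: 0.802, 9: 0.557,
    14: 5.38, 15: 3.63, 16: 2.90, 17: 2.18, 35: 3.05, 53: 5.35,
}
# first ionization energy, eV
_IONIZATION = {
    1: 13.598, 5: 8.298, 6: 11.260, 7: 14.534, 8: 13.618, 9: 17.423,
    14: 8.151, 15: 10.487, 16: 10.360, 17: 12.968, 35: 11.814, 53: 10.451,
}
# principal quantum number of the valence shell, by period
_PERIOD = {1: 1, 5: 2, 6: 2, 7: 2, 8: 2, 9: 2, 14: 3, 15: 3, 16: 3,
           17: 3, 35: 4, 53: 5}

PROPERTY_CODES = ("m", "v", "e", "p", "i", "s", "d", "dv", "c")


def _vdw_volume(pt: Chem.rdchem.PeriodicTable, z: int) -> float:
    r = pt.GetRvdw(z)
    return 4.0 / 3.0 * math.pi * r**3


def atom_properties(mol: Chem.Mol) -> dict[str, np.ndarray]:
    """Heavy-atom property vectors for ``mol`` (hydrogens implicit).

    Unknown elements yield NaN for tabulated properties; NaNs propagate to
    the affected descriptors and are later handled by mean imputation.
    """
    pt = Chem.GetPeriodicTable()
    n = mol.GetNumAtoms()
    out = {code: np.full(n, np.nan) for code in PROPERTY_CODES}

    rdPartialCharges.ComputeGasteigerCharges(mol)
    for idx, atom in enumerate(mol.GetAtoms()):
        z = atom.GetAtomicNum()
        out["m"][idx] = atom.GetMass()
        out["v"][idx] = _vdw_volume(pt, z)
        out["e"][idx] = _SANDERSON.get(z, np.nan)
        out["p"][idx] = _POLARIZABILITY.get(z, np.nan)
        out["i"][idx] = _IONIZATION.get(z, np.nan)
        delta = atom.GetDegree()  # sigma connections to heavy atoms
        n_h = atom.GetTotalNumHs()
        delta_v = pt.GetNOuterElecs(z) - n_h
        out["d"][idx] = float(delta)
        out["dv"][idx] = float(delta_v)
        period = _PERIOD.get(z)
        if period is not None and delta > 0:
            out["s"][idx] = ((2.0 / period) ** 2 * delta_v + 1.0) / delta
        charge = atom.GetDoubleProp("_GasteigerCharge")
        out["c"][idx] = charge if np.isfinite(charge) else np.nan
    return out
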