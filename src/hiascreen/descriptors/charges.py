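"""Partial-charge summary descriptors (Gasteiger charges).

RPCG — relative positive charge: largest positive atomic charge divided by
the sum of all positive charges. RNCG is the negative-charge analogue.
Molecules with no charges of the relevant sign yield NaN.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdPartialCharges


def charge_descriptors(mol: Chem.Mol) -> dict[str, float]:
    rdPartialCharges.ComputeGasteigerCharges(mol)
    q = np.array(
        [a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()]
    )
    q = q[np.isfinite(q)]
    pos = q[q > 0]
    neg = -q[q < 0]
    return {
        "RPCG": float(pos.max() / pos.sum()) if pos.size else np.nan,
        "RNCG": float(neg.max() / neg.sum()) if neg.size else np.nan,
    }
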