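"""2D autocorrelation descriptors on the molecular graph.

Six families over topological distance lags 1..8 and the atomic property
weights of :mod:`.atomprops`:

* ``ATS``   — Moreau–Broto autocorrelation, sum of w_i·w_j over atom pairs at
  topological distance k;
* ``AATS``  — ATS averaged over the number of such pairs;
* ``ATSC``  — centred ATS (weights replaced by deviations from their mean);
* ``AATSC`` — averaged centred ATS;
* ``MATS``  — Moran coefficient (spatial autocorrelation normalised by the
  weight variance, values typically in [-1, 1]);
* ``GATS``  — Geary coefficient (squared-difference form, 1 = no
  autocorrelation).

Feature names join family, lag and property code, e.g. ``MATS1dv`` is the
Moran coefficient at lag 1 weighted by valence electrons and ``GATS4i`` the
Geary coefficient at lag 4 weighted by ionization energy. Undefined values
(no pairs at a lag, zero variance) are NaN and left for imputation.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem

from .atomprops import PROPERTY_CODES, atom_properties

MAX_LAG = 8
FAMILIES = ("ATS", "AATS", "ATSC", "AATSC", "MATS", "GATS")


def feature_names() -> list[str]:
    return [
        f"{fam}{lag}{code}"
        for fam in FAMILIES
        for lag in range(1, MAX_LAG + 1)
        for code in PROPERTY_CODES
    ]


def autocorrelation_descriptors(mol: Chem.Mol) -> dict[str, float]:
    n = mol.GetNumAtoms()
    props = atom_properties(mol)
    dist = Chem.GetDistanceMatrix(mol)

    # unordered atom-pair index lists per lag
    pairs: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    iu, ju = np.triu_indices(n, k=1)
    for lag in range(1, MAX_LAG + 1):
        sel = dist[iu, ju] == lag
        pairs[lag] = (iu[sel], ju[sel])

    out: dict[str, float] = {}
    for code in PROPERTY_CODES:
        w = props[code]
        ok = np.isfinite(w).all() and n > 0
        mean = w.mean() if ok else np.nan
        dev = w - mean
        var_n = float(np.dot(dev, dev)) / n if ok else np.nan  # ÷N
        var_n1 = (
            float(np.dot(dev, dev)) / (n - 1) if ok and n > 1 else np.nan
        )  # ÷(N−1)
        for lag in range(1, MAX_LAG + 1):
            ii, jj = pairs[lag]
            npairs = len(ii)
            if not ok or npairs == 0:
                for fam in FAMILIES:
                    out[f"{fam}{lag}{code}"] = np.nan
                continue
            ats = float(np.dot(w[ii], w[jj]))
            atsc = float(np.dot(dev[ii], dev[jj]))
            sqd = float(np.sum((w[ii] - w[jj]) ** 2))
            out[f"ATS{lag}{code}"] = ats
            out[f"AATS{lag}{code}"] = ats / npairs
            out[f"ATSC{lag}{code}"] = atsc
            out[f"AATSC{lag}{code}"] = atsc / npairs
            out[f"MATS{lag}{code}"] = (
                (atsc / npairs) / var_n if var_n > 0 else np.nan
            )
            out[f"GATS{lag}{code}"] = (
                (sqd / (2.0 * npairs)) / var_n1
                if var_n1 and var_n1 > 0
                else np.nan
            )
    return out
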