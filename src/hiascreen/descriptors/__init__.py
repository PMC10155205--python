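"""2D molecular descriptor computation and preprocessing.

``compute_descriptors`` turns curated molecule records into a samples ×
features :class:`pandas.DataFrame` combining RDKit's general 2D descriptor
set (which includes the PEOE_VSA charge-surface terms) with autocorrelation,
partial-charge and molecular-ID families computed here. ``Preprocessor``
implements the standard tabular-QSPR cleanup: mean imputation of missing
values and removal of constant columns, fitted on training data only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

from ..chem import MoleculeRecord, SmilesParseError, mol_from_smiles
from .autocorr import autocorrelation_descriptors
from .charges import charge_descriptors
from .molid import molecular_id_descriptors

logger = logging.getLogger(__name__)

#: container for samples × descriptors with ids as the index
DescriptorMatrix = pd.DataFrame


def _descriptor_row(mol: Chem.Mol) -> dict[str, float]:
    row: dict[str, float] = {}
    RDLogger.DisableLog("rdApp.warning")
    try:
        row.update(Descriptors.CalcMolDescriptors(mol, missingVal=np.nan))
    finally:
        RDLogger.EnableLog("rdApp.warning")
    row.update(autocorrelation_descriptors(mol))
    row.update(charge_descriptors(mol))
    row.update(molecular_id_descriptors(mol))
    return row


def compute_descriptors(records: Sequence[MoleculeRecord]) -> DescriptorMatrix:
    """Compute the full 2D descriptor matrix for ``records``.

    Deterministic; a descriptor that fails for a molecule becomes NaN
    (missing) rather than aborting the run. Unparsable SMILES raise
    :class:`SmilesParseError` naming the record.
    """
    rows = []
    ids = []
    for rec in records:
        mol = mol_from_smiles(rec.smiles_canonical, rec.id)
        rows.append(_descriptor_row(mol))
        ids.append(rec.id)
    matrix = pd.DataFrame(rows, index=pd.Index(ids, name="id"), dtype=float)
    if matrix.columns.duplicated().any():
        dupes = matrix.columns[matrix.columns.duplicated()].tolist()
        raise ValueError(f"duplicate descriptor names: {dupes}")
    return matrix


@dataclass
class Preprocessor:
    """Mean imputation + constant-column removal, fitted on training data.

    ``feature_means`` hold per-feature means over non-missing training
    values; ``kept_features`` excludes columns that are entirely missing or
    constant (exact equality after imputation).
    """

    feature_means: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    kept_features: list[str] = field(default_factory=list)

    def fit(self, matrix: DescriptorMatrix) -> "Preprocessor":
        if matrix.shape[0] < 2:
            raise ValueError("preprocessor needs at least two samples to fit")
        means = matrix.mean(axis=0, skipna=True)
        all_missing = matrix.isna().all(axis=0)
        if all_missing.any():
            logger.warning(
                "dropping %d all-missing descriptor column(s): %s",
                int(all_missing.sum()),
                matrix.columns[all_missing].tolist()[:10],
            )
        imputed = matrix.fillna(means)
        constant = (imputed == imputed.iloc[0]).all(axis=0)
        keep = ~(all_missing | constant)
        self.kept_features = matrix.columns[keep].tolist()
        self.feature_means = means[self.kept_features]
        if not self.kept_features:
            raise ValueError("all descriptor columns are constant or missing")
        return self

    def transform(self, matrix: DescriptorMatrix) -> DescriptorMatrix:
        missing_cols = [c for c in self.kept_features if c not in matrix.columns]
        if missing_cols:
            raise ValueError(f"input lacks kept feature(s): {missing_cols[:10]}")
        if not self.kept_features:
            raise ValueError("preprocessor has no kept features (not fitted?)")
        out = matrix[self.kept_features].fillna(self.feature_means)
        return out

    def fit_transform(self, matrix: DescriptorMatrix) -> DescriptorMatrix:
        return self.fit(matrix).transform(matrix)

    def to_dict(self) -> dict:
        return {
            "kept_features": list(self.kept_features),
            "feature_means": {k: float(v) for k, v in self.feature_means.items()},
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "Preprocessor":
        kept = list(payload["kept_features"])
        means = pd.Series(payload["feature_means"], dtype=float)[kept]
        return cls(feature_means=means, kept_features=kept)


def fit_preprocessor(train_matrix: DescriptorMatrix) -> Preprocessor:
    return Preprocessor().fit(train_matrix)


def apply_preprocessor(
    model: Preprocessor, matrix: DescriptorMatrix
) -> DescriptorMatrix:
    return model.transform(matrix)
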