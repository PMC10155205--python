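"""Curation of SMILES + HIA datasets.

Loading, canonicalization, structure-based deduplication and intersection,
class labelling at the 85% absorption boundary, reproducible 70:30 splitting,
and dataset characterization (pairwise Tanimoto similarity, molecular weight).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator

logger = logging.getLogger(__name__)

#: HIA percentage above which a compound counts as highly permeable
#: (FDA/EMA permeability guidance; boundary is inclusive).
CLASS_BOUNDARY = 85.0

DEFAULT_FINGERPRINT_SPEC = "morgan/radius=2/2048bits"


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed.

    Carries the offending input and, when known, the row id it came from.
    """

    def __init__(self, smiles: str, row_id: str | None = None):
        self.smiles = smiles
        self.row_id = row_id
        where = f" (row id {row_id!r})" if row_id is not None else ""
        super().__init__(f"unparsable SMILES {smiles!r}{where}")


@dataclass(frozen=True)
class MoleculeRecord:
    """One compound: identifier, raw and canonical SMILES, HIA percent."""

    id: str
    smiles_raw: str
    smiles_canonical: str
    hia_percent: float | None = None
    source: str | None = None

    def __post_init__(self):
        if self.hia_percent is not None and not (0.0 <= self.hia_percent <= 100.0):
            raise ValueError(
                f"hia_percent must lie in [0, 100], got {self.hia_percent} "
                f"for record {self.id!r}"
            )


@dataclass(frozen=True)
class CuratedDataset:
    """Deduplicated collection of molecule records."""

    records: tuple[MoleculeRecord, ...]
    n_raw: int

    @property
    def n_unique(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def smiles_set(self) -> set[str]:
        return {r.smiles_canonical for r in self.records}

    def hia_array(self) -> np.ndarray:
        """HIA values in record order; raises if any record lacks one."""
        vals = []
        for r in self.records:
            if r.hia_percent is None:
                raise ValueError(f"record {r.id!r} has no HIA value")
            vals.append(r.hia_percent)
        return np.asarray(vals, dtype=float)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


@dataclass(frozen=True)
class SplitAssignment:
    """Disjoint, exhaustive train/test partition of a dataset's ids."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    test_fraction: float
    seed: int


@dataclass(frozen=True)
class SimilaritySummary:
    min: float
    median: float
    max: float
    fingerprint_spec: str = DEFAULT_FINGERPRINT_SPEC


@dataclass(frozen=True)
class WeightSummary:
    """Molecular-weight summary (average-atomic-mass weights, g/mol)."""

    min: float
    median: float
    max: float


def mol_from_smiles(smiles: str, row_id: str | None = None) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles, row_id)
    return mol


def canonicalize(smiles: str, row_id: str | None = None) -> str:
    """Return the canonical SMILES spelling of ``smiles``.

    Two structurally identical inputs map to the same output, and the
    function is idempotent. Unparsable input raises :class:`SmilesParseError`.
    """
    if not smiles:
        raise SmilesParseError(smiles, row_id)
    return Chem.MolToSmiles(mol_from_smiles(smiles, row_id))


def make_record(
    id: str,
    smiles: str,
    hia_percent: float | None = None,
    source: str | None = None,
) -> MoleculeRecord:
    """Build a record, canonicalizing the SMILES."""
    return MoleculeRecord(
        id=str(id),
        smiles_raw=smiles,
        smiles_canonical=canonicalize(smiles, row_id=str(id)),
        hia_percent=hia_percent,
        source=source,
    )


def deduplicate(records: Sequence[MoleculeRecord]) -> CuratedDataset:
    """Collapse records sharing a canonical SMILES into one.

    First-occurrence order is preserved. A duplicate group keeps the first
    record's id and source; its HIA becomes the arithmetic mean of the group's
    non-missing values. Groups whose HIA values disagree are logged as
    warnings so conflicting literature entries stay auditable.
    """
    groups: dict[str, list[MoleculeRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.smiles_canonical not in groups:
            groups[rec.smiles_canonical] = []
            order.append(rec.smiles_canonical)
        groups[rec.smiles_canonical].append(rec)

    out: list[MoleculeRecord] = []
    for smi in order:
        group = groups[smi]
        first = group[0]
        hia_vals = [r.hia_percent for r in group if r.hia_percent is not None]
        if len(set(hia_vals)) > 1:
            logger.warning(
                "duplicate group %r (ids %s) has disagreeing HIA values %s; "
                "using the mean",
                smi,
                [r.id for r in group],
                hia_vals,
            )
        hia = float(np.mean(hia_vals)) if hia_vals else None
        out.append(replace(first, hia_percent=hia))
    return CuratedDataset(records=tuple(out), n_raw=len(records))


def intersect_by_structure(a: CuratedDataset, b: CuratedDataset) -> CuratedDataset:
    """Records of ``a`` whose canonical SMILES also occur in ``b``.

    Ids, HIA values and ordering follow ``a``.
    """
    in_b = b.smiles_set()
    kept = tuple(r for r in a.records if r.smiles_canonical in in_b)
    return CuratedDataset(records=kept, n_raw=len(a.records))


def assign_class(hia_percent: float, threshold: float = CLASS_BOUNDARY) -> int:
    """1 (highly permeable) iff HIA >= threshold, else 0."""
    if hia_percent is None:
        raise ValueError("cannot assign a permeability class without an HIA value")
    if not (0.0 <= hia_percent <= 100.0):
        raise ValueError(f"hia_percent must lie in [0, 100], got {hia_percent}")
    return int(hia_percent >= threshold)


def labels_for(dataset: CuratedDataset, threshold: float = CLASS_BOUNDARY) -> np.ndarray:
    return np.asarray(
        [assign_class(r.hia_percent, threshold) for r in dataset.records], dtype=int
    )


def split(
    dataset: CuratedDataset, test_fraction: float = 0.3, seed: int = 0
) -> SplitAssignment:
    """Seeded uniform shuffle followed by a prefix/suffix cut.

    The train set holds ``floor(n * (1 - test_fraction))`` records; the rest
    form the test set (141 records at 0.3 give 98 train / 43 test).
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    ids = dataset.ids()
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(n * (1.0 - test_fraction)))
    train = tuple(ids[i] for i in perm[:n_train])
    test = tuple(ids[i] for i in perm[n_train:])
    return SplitAssignment(
        train_ids=train, test_ids=test, test_fraction=test_fraction, seed=seed
    )


def subset(dataset: CuratedDataset, ids: Iterable[str]) -> CuratedDataset:
    wanted = list(ids)
    by_id = {r.id: r for r in dataset.records}
    return CuratedDataset(
        records=tuple(by_id[i] for i in wanted), n_raw=len(wanted)
    )


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| between binary fingerprints.

    Defined as 0 when both fingerprints are empty.
    """
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def _fingerprints(dataset: CuratedDataset, radius: int, n_bits: int) -> np.ndarray:
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fps = np.zeros((len(dataset), n_bits), dtype=bool)
    for i, rec in enumerate(dataset.records):
        mol = mol_from_smiles(rec.smiles_canonical, rec.id)
        fps[i] = np.array(gen.GetFingerprint(mol), dtype=bool)
    return fps


def similarity_summary(
    dataset: CuratedDataset, radius: int = 2, n_bits: int = 2048
) -> SimilaritySummary:
    """Min/median/max Tanimoto over all unordered distinct molecule pairs.

    Circular (Morgan) fingerprints, radius 2, 2048 bits by default.
    """
    n = len(dataset)
    if n < 2:
        raise ValueError("similarity summary needs at least two molecules")
    fps = _fingerprints(dataset, radius, n_bits)
    vals = [
        tanimoto(fps[i], fps[j]) for i in range(n) for j in range(i + 1, n)
    ]
    arr = np.asarray(vals)
    return SimilaritySummary(
        min=float(arr.min()),
        median=float(np.median(arr)),
        max=float(arr.max()),
        fingerprint_spec=f"morgan/radius={radius}/{n_bits}bits",
    )


def weight_summary(dataset: CuratedDataset) -> WeightSummary:
    weights = [
        Descriptors.MolWt(mol_from_smiles(r.smiles_canonical, r.id))
        for r in dataset.records
    ]
    arr = np.asarray(weights)
    return WeightSummary(
        min=float(arr.min()), median=float(np.median(arr)), max=float(arr.max())
    )


# ---------------------------------------------------------------------------
# File I/O


def read_molecules_csv(path, delimiter: str | None = None) -> list[MoleculeRecord]:
    """Read a molecule table with header columns id, smiles, hia[, source].

    Column matching is case-insensitive; ``hia`` may be absent for
    prediction-only inputs. Delimiter is sniffed from the extension
    (``.tsv`` → tab) unless given.
    """
    path = str(path)
    if delimiter is None:
        delimiter = "\t" if path.endswith(".tsv") else ","
    records: list[MoleculeRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        cols = {c.lower().strip(): c for c in reader.fieldnames}
        for need in ("id", "smiles"):
            if need not in cols:
                raise ValueError(f"{path}: missing required column {need!r}")
        for row in reader:
            hia = None
            if "hia" in cols and row[cols["hia"]] not in (None, ""):
                hia = float(row[cols["hia"]])
            source = row[cols["source"]] if "source" in cols else None
            records.append(
                make_record(row[cols["id"]], row[cols["smiles"]], hia, source)
            )
    return records


def write_molecules_csv(path, records: Iterable[MoleculeRecord]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "hia", "source"])
        for r in records:
            writer.writerow(
                [r.id, r.smiles_canonical,
                 "" if r.hia_percent is None else r.hia_percent,
                 r.source or ""]
            )


def read_smiles_list(path) -> list[MoleculeRecord]:
    """Read a plain-text SMILES list, one molecule per line.

    A line may be ``SMILES`` alone or ``SMILES<TAB>id``; blank lines and
    ``#`` comments are skipped. Records get sequential ids when none given.
    """
    records = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            mol_id = parts[1].strip() if len(parts) > 1 else f"mol{i + 1}"
            records.append(make_record(mol_id, smiles))
    return records
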