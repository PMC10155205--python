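"""Curation: canonicalization, dedup, intersection, labelling, splitting,
similarity and weight characterization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hiascreen import (
    assign_class,
    canonicalize,
    deduplicate,
    intersect_by_structure,
    make_record,
    similarity_summary,
    split,
    tanimoto,
    weight_summary,
)
from hiascreen.chem import SmilesParseError, read_molecules_csv, write_molecules_csv


class TestCanonicalize:
    def test_equivalent_spellings_collapse(self):
        assert canonicalize("OCC") == canonicalize("CCO")

    @pytest.mark.parametrize(
        "smiles", ["CCO", "c1ccccc1", "CC(=O)Oc1ccccc1C(=O)O", "C[N+](C)(C)C"]
    )
    def test_idempotent(self, smiles):
        once = canonicalize(smiles)
        assert canonicalize(once) == once

    @pytest.mark.parametrize("bad", ["C(", "", "not_a_smiles(("])
    def test_malformed_input_raises(self, bad):
        with pytest.raises(SmilesParseError):
            canonicalize(bad)

    def test_error_carries_row_id(self):
        with pytest.raises(SmilesParseError) as exc:
            canonicalize("C(", row_id="row7")
        assert "row7" in str(exc.value)
        assert exc.value.smiles == "C("


class TestDeduplicate:
    def test_identical_duplicates_collapse(self):
        recs = [make_record("a", "CCO", 90), make_record("b", "OCC", 90)]
        ds = deduplicate(recs)
        assert ds.n_unique == 1 and ds.n_raw == 2
        assert ds.records[0].hia_percent == 90

    def test_disagreeing_hia_averaged_with_warning(self, caplog):
        recs = [make_record("a", "CCO", 80), make_record("b", "OCC", 90)]
        with caplog.at_level("WARNING"):
            ds = deduplicate(recs)
        assert ds.records[0].hia_percent == pytest.approx(85)
        assert any("disagreeing" in r.message for r in caplog.records)

    def test_first_occurrence_order_and_id(self):
        recs = [
            make_record("x", "CCN", 50),
            make_record("y", "CCO", 60),
            make_record("z", "OCC", 70),
        ]
        ds = deduplicate(recs)
        assert [r.id for r in ds.records] == ["x", "y"]

    def test_idempotent(self):
        recs = [make_record(str(i), s, 50) for i, s in enumerate(["CCO", "OCC", "CCN"])]
        once = deduplicate(recs)
        twice = deduplicate(list(once.records))
        assert [r.smiles_canonical for r in twice.records] == [
            r.smiles_canonical for r in once.records
        ]

    def test_empty_input(self):
        assert deduplicate([]).n_unique == 0


class TestIntersect:
    def test_disjoint_sets_empty(self):
        a = deduplicate([make_record("a", "CCO", 90)])
        b = deduplicate([make_record("b", "CCN", 80)])
        assert len(intersect_by_structure(a, b)) == 0

    def test_self_intersection_is_identity(self, small_records):
        ds = deduplicate(small_records)
        assert intersect_by_structure(ds, ds).smiles_set() == ds.smiles_set()

    def test_membership_commutative_values_from_first(self):
        a = deduplicate([make_record("a1", "CCO", 90), make_record("a2", "CCN", 70)])
        b = deduplicate([make_record("b1", "OCC", 10)])
        ab = intersect_by_structure(a, b)
        ba = intersect_by_structure(b, a)
        assert ab.smiles_set() == ba.smiles_set()
        assert ab.records[0].hia_percent == 90  # taken from `a`
        assert ba.records[0].hia_percent == 10  # taken from `b`


class TestAssignClass:
    @pytest.mark.parametrize(
        "hia,expected", [(85, 1), (84.99, 0), (100, 1), (0, 0), (90, 1)]
    )
    def test_boundary_inclusive(self, hia, expected):
        assert assign_class(hia) == expected

    def test_missing_hia_rejected(self):
        with pytest.raises(ValueError):
            assign_class(None)


class TestSplit:
    def test_split_sizes(self):
        ids = [f"m{i}" for i in range(141)]
        from hiascreen.chem import CuratedDataset, MoleculeRecord

        recs = tuple(
            MoleculeRecord(id=i, smiles_raw="C", smiles_canonical=f"C{i}", hia_percent=50)
            for i in ids
        )
        ds = CuratedDataset(records=recs, n_raw=141)
        sp = split(ds, test_fraction=0.3, seed=0)
        assert len(sp.train_ids) == 98 and len(sp.test_ids) == 43

    def test_small_split(self):
        from hiascreen.chem import CuratedDataset, MoleculeRecord

        recs = tuple(
            MoleculeRecord(id=f"m{i}", smiles_raw="C", smiles_canonical=f"C{i}")
            for i in range(10)
        )
        ds = CuratedDataset(records=recs, n_raw=10)
        sp = split(ds, test_fraction=0.3, seed=1)
        assert len(sp.train_ids) == 7 and len(sp.test_ids) == 3

    def test_deterministic_and_partition(self):
        from hiascreen.chem import CuratedDataset, MoleculeRecord

        recs = tuple(
            MoleculeRecord(id=f"m{i}", smiles_raw="C", smiles_canonical=f"C{i}")
            for i in range(141)
        )
        ds = CuratedDataset(records=recs, n_raw=141)
        first = split(ds, seed=5)
        again = split(ds, seed=5)
        assert first == again
        for seed in range(50):
            sp = split(ds, seed=seed)
            train, test = set(sp.train_ids), set(sp.test_ids)
            assert not train & test
            assert train | test == {r.id for r in recs}

    def test_bad_fraction(self):
        from hiascreen.chem import CuratedDataset, MoleculeRecord

        ds = CuratedDataset(
            records=(MoleculeRecord(id="a", smiles_raw="C", smiles_canonical="C"),),
            n_raw=1,
        )
        for frac in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                split(ds, test_fraction=frac)


class TestTanimoto:
    def test_identical_nonempty_is_one(self):
        fp = np.zeros(16, dtype=bool)
        fp[[1, 5, 9]] = True
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros(8, dtype=bool)
        b = np.zeros(8, dtype=bool)
        a[0] = True
        b[1] = True
        assert tanimoto(a, b) == 0.0

    def test_hand_count(self):
        a = np.zeros(8, dtype=bool)
        b = np.zeros(8, dtype=bool)
        a[[1, 2]] = True
        b[[2, 3]] = True
        assert tanimoto(a, b) == pytest.approx(1 / 3)

    def test_both_empty_defined_zero(self):
        z = np.zeros(8, dtype=bool)
        assert tanimoto(z, z) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tanimoto(np.zeros(8, dtype=bool), np.zeros(9, dtype=bool))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=64))
    def test_symmetry_and_self_similarity(self, bits):
        rng = np.random.default_rng(sum(bits) + len(bits))
        a = np.array(bits, dtype=bool)
        b = rng.random(len(bits)) < 0.5
        assert tanimoto(a, b) == pytest.approx(tanimoto(b, a))
        if a.any():
            assert tanimoto(a, a) == 1.0


class TestCharacterization:
    def test_similarity_identical_molecules(self):
        ds = deduplicate([make_record("a", "CCO", 50)])
        from hiascreen.chem import CuratedDataset

        clones = CuratedDataset(records=ds.records * 3, n_raw=3)
        summary = similarity_summary(clones)
        assert summary.min == summary.median == summary.max == 1.0

    def test_two_molecule_dataset(self, small_records):
        ds = deduplicate(small_records[:2])
        s = similarity_summary(ds)
        assert s.min == s.median == s.max

    def test_singleton_rejected(self):
        ds = deduplicate([make_record("a", "CCO", 50)])
        with pytest.raises(ValueError):
            similarity_summary(ds)

    def test_methane_weight(self):
        ds = deduplicate([make_record("methane", "C", 50)])
        w = weight_summary(ds)
        assert w.min == w.median == w.max == pytest.approx(16.04, abs=0.01)

    def test_weight_ordering(self, small_records):
        w = weight_summary(deduplicate(small_records))
        assert 0 < w.min <= w.median <= w.max


class TestIO:
    def test_csv_round_trip(self, tmp_path, small_records):
        path = tmp_path / "mols.csv"
        write_molecules_csv(path, small_records)
        back = read_molecules_csv(path)
        assert [r.id for r in back] == [r.id for r in small_records]
        assert [r.smiles_canonical for r in back] == [
            r.smiles_canonical for r in small_records
        ]
        assert [r.hia_percent for r in back] == [r.hia_percent for r in small_records]

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,hia\n1,50\n")
        with pytest.raises(ValueError, match="smiles"):
            read_molecules_csv(path)

    def test_smiles_list(self, tmp_path):
        from hiascreen import read_smiles_list

        path = tmp_path / "list.smi"
        path.write_text("CCO\tethanol\n# comment\n\nCCN\n")
        records = read_smiles_list(path)
        assert [r.id for r in records] == ["ethanol", "mol4"]
        assert records[0].hia_percent is None
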