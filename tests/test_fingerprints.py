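"""Fingerprint generation and table I/O."""

import numpy as np
import pytest

from mol2mat import (
    FINGERPRINT_SPECS,
    LabelledMolecule,
    compute_fingerprint,
    compute_fingerprints,
    get_spec,
    load_fingerprint_table,
    write_fingerprint_table,
)
from mol2mat.fingerprints import TableFormatError, read_smiles_file, read_sdf

ALL_SPECS = sorted(FINGERPRINT_SPECS)


def test_registry_lengths_and_kinds():
    expected = {
        "ALOGP": (120, "count"), "CDK": (1024, "binary"), "ECFC4": (1024, "count"),
        "ECFP4": (1024, "binary"), "EPFP4": (1024, "binary"), "GOFP": (1024, "binary"),
        "PCFP": (881, "binary"), "MDL": (166, "binary"),
    }
    assert {k: (v.length, v.value_kind) for k, v in FINGERPRINT_SPECS.items()} == expected


@pytest.mark.parametrize("spec_name", ALL_SPECS)
def test_vector_length_and_value_domain(spec_name):
    spec = get_spec(spec_name)
    vec = compute_fingerprint("CC(=O)Oc1ccccc1C(=O)O", spec)  # aspirin
    assert vec.shape == (spec.length,)
    assert vec.sum() > 0, "a non-trivial molecule must set at least one feature"
    if spec.value_kind == "binary":
        assert set(np.unique(vec)) <= {0, 1}
    else:
        assert (vec >= 0).all() and np.issubdtype(vec.dtype, np.integer)


@pytest.mark.parametrize("spec_name", ALL_SPECS)
def test_determinism_across_smiles_writings(spec_name):
    # same molecule written two ways -> identical vector after canonicalisation
    a = compute_fingerprint("c1ccccc1O", spec_name)
    b = compute_fingerprint("Oc1ccccc1", spec_name)
    assert np.array_equal(a, b)


def test_benzene_vs_cyclohexane_differ():
    a = compute_fingerprint("c1ccccc1", "ECFP4")
    b = compute_fingerprint("C1CCCCC1", "ECFP4")
    # independent popcount Tanimoto
    c = int(((a == 1) & (b == 1)).sum())
    sim = c / (int(a.sum()) + int(b.sum()) - c)
    assert sim < 1.0


def test_graph_only_fingerprint_merges_bond_orders():
    # aromatic and saturated six-ring have identical graphs once bond orders
    # are stripped, so GOFP must coincide where ECFP4 differs
    assert np.array_equal(
        compute_fingerprint("c1ccccc1", "GOFP"), compute_fingerprint("C1CCCCC1", "GOFP")
    )


def test_unparsable_smiles_is_rejected_with_id():
    mols = [
        LabelledMolecule("ok", "a", smiles="CCO"),
        LabelledMolecule("bad", "a", smiles="not_a_smiles(("),
    ]
    frame, rejected = compute_fingerprints(mols, "MDL")
    assert rejected == ["bad"]
    assert list(frame.index) == ["ok"]


def test_unknown_spec_name_raises():
    with pytest.raises(KeyError, match="unknown fingerprint"):
        get_spec("NOPE")


def test_table_round_trip(tmp_path, rng):
    X = rng.integers(0, 2, size=(5, 166))
    y = ["a", "b", "a", "b", "a"]
    path = tmp_path / "fp.csv"
    write_fingerprint_table(path, X, y)
    X2, y2 = load_fingerprint_table(path, "MDL")
    assert np.array_equal(X, X2)
    assert list(y2) == y


def test_table_column_count_mismatch(tmp_path, rng):
    path = tmp_path / "fp.csv"
    write_fingerprint_table(path, rng.integers(0, 2, size=(3, 1000)), ["a", "b", "a"])
    with pytest.raises(TableFormatError, match="expected 1024 feature columns"):
        load_fingerprint_table(path, "CDK")


def test_table_non_numeric_cell(tmp_path):
    path = tmp_path / "fp.csv"
    path.write_text("f0,f1,f2,class\n1,oops,0,a\n0,1,1,b\n")
    with pytest.raises(TableFormatError, match="non-numeric"):
        load_fingerprint_table(path, __import__("mol2mat").FingerprintSpec("X3", 3, "binary"))


def test_smiles_file_reader(tmp_path):
    path = tmp_path / "mols.smi"
    path.write_text("CCO\tm1\talcohols\nc1ccccc1\tm2\tarenes\nbad((\tm3\tarenes\n")
    mols, rejected = read_smiles_file(path)
    assert [m.id for m in mols] == ["m1", "m2"]
    assert rejected == ["m3"]


def test_sdf_reader_matches_smiles_schema(tmp_path, smiles_molecules):
    from rdkit import Chem

    sdf = tmp_path / "mols.sdf"
    writer = Chem.SDWriter(str(sdf))
    for m in smiles_molecules[:6]:
        mol = Chem.MolFromSmiles(m.smiles)
        mol.SetProp("_Name", m.id)
        mol.SetProp("class", m.activity_class)
        writer.write(mol)
    writer.close()
    mols, rejected = read_sdf(sdf)
    assert rejected == []
    assert [m.id for m in mols] == [m.id for m in smiles_molecules[:6]]
    # same molecule through SDF or SMILES -> same fingerprint
    for via_sdf, via_smiles in zip(mols, smiles_molecules):
        assert np.array_equal(
            compute_fingerprint(via_sdf, "ECFP4"), compute_fingerprint(via_smiles, "ECFP4")
        )
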