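"""Two-dimensional molecular fingerprints.

Eight fingerprint families are supported, spanning the descriptor types
commonly used in ligand-based virtual screening: circular (ECFP4/ECFC4),
hashed path (EPFP4, CDK, GOFP), substructure keys (MDL/MACCS, PCFP) and an
atom-type count block (ALOGP).  Each family maps a molecule to a fixed-length
bit or count vector; downstream code treats vectors purely positionally, so a
CSV ingest path is also provided for fingerprints exported from external
software.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Avalon import pyAvalonTools
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "FingerprintSpec",
    "LabelledMolecule",
    "FINGERPRINT_SPECS",
    "get_spec",
    "compute_fingerprint",
    "compute_fingerprints",
    "load_fingerprint_table",
    "write_fingerprint_table",
    "read_smiles_file",
    "read_sdf",
]


@dataclass(frozen=True)
class FingerprintSpec:
    """Name, length and value kind (binary/count) of one fingerprint family."""

    name: str
    length: int
    value_kind: str  # "binary" or "count"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"fingerprint length must be positive, got {self.length}")
        if self.value_kind not in ("binary", "count"):
            raise ValueError(f"value_kind must be 'binary' or 'count', got {self.value_kind!r}")


#: The eight supported fingerprint families.  Lengths follow the conventional
#: sizes for each family: 1024 positions for the hashed/circular fingerprints,
#: 166 MACCS keys, 881 PubChem-style keys and 120 atom-type count features.
FINGERPRINT_SPECS: dict[str, FingerprintSpec] = {
    "ALOGP": FingerprintSpec("ALOGP", 120, "count"),
    "CDK": FingerprintSpec("CDK", 1024, "binary"),
    "ECFC4": FingerprintSpec("ECFC4", 1024, "count"),
    "ECFP4": FingerprintSpec("ECFP4", 1024, "binary"),
    "EPFP4": FingerprintSpec("EPFP4", 1024, "binary"),
    "GOFP": FingerprintSpec("GOFP", 1024, "binary"),
    "PCFP": FingerprintSpec("PCFP", 881, "binary"),
    "MDL": FingerprintSpec("MDL", 166, "binary"),
}

#: Aliases occasionally used in the literature for the same families.
_ALIASES = {"GRAPH": "GOFP", "MACCS": "MDL", "PUBCHEM": "PCFP", "CDKFP": "CDK"}


def get_spec(name: str | FingerprintSpec) -> FingerprintSpec:
    """Resolve a fingerprint name (case-insensitive, aliases allowed) to its spec."""
    if isinstance(name, FingerprintSpec):
        return name
    key = name.upper()
    key = _ALIASES.get(key, key)
    try:
        return FINGERPRINT_SPECS[key]
    except KeyError:
        raise KeyError(
            f"unknown fingerprint {name!r}; supported: {sorted(FINGERPRINT_SPECS)}"
        ) from None


@dataclass
class LabelledMolecule:
    """One molecule with its activity-class label.

    ``smiles`` may be None when features arrive precomputed through the CSV
    ingest path.
    """

    id: str
    activity_class: str
    smiles: str | None = None


class UnparsableSmilesError(ValueError):
    """Raised for a record whose SMILES does not parse; carries the molecule id."""

    def __init__(self, molecule_id: str, smiles: str):
        self.molecule_id = molecule_id
        self.smiles = smiles
        super().__init__(f"molecule {molecule_id!r}: unparsable SMILES {smiles!r}")


def _mol_from_smiles(smiles: str, molecule_id: str = "?") -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise UnparsableSmilesError(molecule_id, smiles)
    return mol


# --- generators per family -------------------------------------------------

_morgan = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
_linear_path = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=1024, branchedPaths=False)
_branched_path = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=1024)


def _strip_bond_orders(mol: Chem.Mol) -> Chem.Mol:
    """Copy of the molecular graph with every bond reduced to a single bond."""
    rw = Chem.RWMol(mol)
    for atom in rw.GetAtoms():
        atom.SetIsAromatic(False)
        atom.SetNoImplicit(True)
    for bond in rw.GetBonds():
        bond.SetBondType(Chem.BondType.SINGLE)
        bond.SetIsAromatic(False)
    out = rw.GetMol()
    Chem.SanitizeMol(out, Chem.SanitizeFlags.SANITIZE_SYMMRINGS)
    return out


def _atom_type_counts(mol: Chem.Mol, length: int = 120) -> np.ndarray:
    """Atom-type count block: each atom's local environment tuple is hashed
    (stable crc32) into one of ``length`` count bins."""
    counts = np.zeros(length, dtype=np.int64)
    for atom in mol.GetAtoms():
        key = (
            atom.GetSymbol(),
            atom.GetDegree(),
            atom.GetTotalNumHs(),
            atom.GetIsAromatic(),
            atom.GetFormalCharge(),
            atom.IsInRing(),
        )
        counts[zlib.crc32(repr(key).encode()) % length] += 1
    return counts


def _fp_to_array(fp, length: int) -> np.ndarray:
    arr = np.zeros(length, dtype=np.int64)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def _count_fp_to_array(fp, length: int) -> np.ndarray:
    arr = np.zeros(length, dtype=np.int64)
    for bit, count in fp.GetNonzeroElements().items():
        arr[bit] = count
    return arr


def compute_fingerprint(molecule: LabelledMolecule | str, spec: str | FingerprintSpec) -> np.ndarray:
    """Compute one fingerprint vector for one molecule.

    Parameters
    ----------
    molecule : LabelledMolecule or SMILES string
    spec : fingerprint name or FingerprintSpec

    Returns
    -------
    numpy integer array of exactly ``spec.length`` entries (0/1 for binary
    families, non-negative counts for ECFC4 and ALOGP).  Deterministic: the
    SMILES is canonicalised by parsing, so any writing of the same molecule
    yields the same vector.
    """
    spec = get_spec(spec)
    if isinstance(molecule, LabelledMolecule):
        if molecule.smiles is None:
            raise ValueError(f"molecule {molecule.id!r} has no SMILES")
        mol = _mol_from_smiles(molecule.smiles, molecule.id)
    else:
        mol = _mol_from_smiles(molecule)

    if spec.name == "ECFP4":
        vec = _fp_to_array(_morgan.GetFingerprint(mol), spec.length)
    elif spec.name == "ECFC4":
        vec = _count_fp_to_array(_morgan.GetCountFingerprint(mol), spec.length)
    elif spec.name == "EPFP4":
        vec = _fp_to_array(_linear_path.GetFingerprint(mol), spec.length)
    elif spec.name == "CDK":
        vec = _fp_to_array(_branched_path.GetFingerprint(mol), spec.length)
    elif spec.name == "GOFP":
        vec = _fp_to_array(_linear_path.GetFingerprint(_strip_bond_orders(mol)), spec.length)
    elif spec.name == "MDL":
        # RDKit MACCS keys are indexed 1..166; bit 0 is unused padding.
        full = MACCSkeys.GenMACCSKeys(mol)
        vec = np.array([int(full.GetBit(i)) for i in range(1, 167)], dtype=np.int64)
    elif spec.name == "PCFP":
        vec = _fp_to_array(pyAvalonTools.GetAvalonFP(mol, nBits=spec.length), spec.length)
    elif spec.name == "ALOGP":
        vec = _atom_type_counts(mol, spec.length)
    else:  # pragma: no cover - registry is closed
        raise KeyError(spec.name)
    assert vec.shape == (spec.length,)
    return vec


def compute_fingerprints(
    molecules: Iterable[LabelledMolecule],
    spec: str | FingerprintSpec,
) -> tuple[pd.DataFrame, list[str]]:
    """Fingerprint a collection of molecules, skipping unparsable records.

    Returns a DataFrame (index = molecule id, columns f0..f{L-1} plus
    ``class``) and the list of rejected molecule ids.  Record-level failures
    never abort the run.
    """
    spec = get_spec(spec)
    rows, ids, labels, rejected = [], [], [], []
    for mol in molecules:
        try:
            rows.append(compute_fingerprint(mol, spec))
        except UnparsableSmilesError:
            rejected.append(mol.id)
            continue
        ids.append(mol.id)
        labels.append(mol.activity_class)
    frame = pd.DataFrame(
        np.asarray(rows, dtype=np.int64).reshape(len(rows), spec.length),
        index=pd.Index(ids, name="id"),
        columns=[f"f{i}" for i in range(spec.length)],
    )
    frame["class"] = labels
    return frame, rejected


class TableFormatError(ValueError):
    """A fingerprint CSV whose shape does not match the declared spec."""


def load_fingerprint_table(
    path, spec: str | FingerprintSpec, label_column: str = "class"
) -> tuple[np.ndarray, np.ndarray]:
    """Load a fingerprint CSV (one row per molecule) as (X, y).

    The feature column count must equal ``spec.length``; row order is
    preserved.  Non-numeric feature cells raise a row-level error.
    """
    spec = get_spec(spec)
    frame = pd.read_csv(path)
    if label_column not in frame.columns:
        raise TableFormatError(f"label column {label_column!r} not found in {path}")
    feature_cols = [c for c in frame.columns if c != label_column and c != "id"]
    if len(feature_cols) != spec.length:
        raise TableFormatError(
            f"{path}: expected {spec.length} feature columns for {spec.name}, "
            f"found {len(feature_cols)}"
        )
    features = frame[feature_cols].apply(pd.to_numeric, errors="coerce")
    bad = features.isna().any(axis=1)
    if bad.any():
        raise TableFormatError(
            f"{path}: non-numeric feature cell in row(s) {list(frame.index[bad])[:5]}"
        )
    X = features.to_numpy()
    if spec.value_kind == "binary" and not np.isin(X, (0, 1)).all():
        raise TableFormatError(f"{path}: binary fingerprint {spec.name} contains non-0/1 values")
    if (X < 0).any():
        raise TableFormatError(f"{path}: negative feature values")
    return X, frame[label_column].astype(str).to_numpy()


def write_fingerprint_table(path, X: np.ndarray, y: Sequence, ids: Sequence | None = None) -> None:
    """Write (X, y) as the standard fingerprint CSV (f0..f{L-1},class)."""
    X = np.asarray(X)
    frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    frame["class"] = list(y)
    if ids is not None:
        frame.insert(0, "id", list(ids))
    frame.to_csv(path, index=False)


def read_smiles_file(path) -> tuple[list[LabelledMolecule], list[str]]:
    """Read a SMILES file with one ``SMILES<TAB>id<TAB>class`` record per line.

    Unparsable SMILES are rejected (not raised); their ids are returned so the
    caller can report the rejection count.
    """
    molecules, rejected = [], []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise TableFormatError(
                    f"{path}:{line_no}: expected 'SMILES<TAB>id<TAB>class', got {len(parts)} fields"
                )
            smiles, mol_id, cls = parts
            if Chem.MolFromSmiles(smiles) is None:
                rejected.append(mol_id)
                continue
            molecules.append(LabelledMolecule(id=mol_id, activity_class=cls, smiles=smiles))
    ids = [m.id for m in molecules]
    if len(set(ids)) != len(ids):
        raise TableFormatError(f"{path}: duplicate molecule ids")
    return molecules, rejected


def read_sdf(path, class_property: str = "class") -> tuple[list[LabelledMolecule], list[str]]:
    """Read an SDF file; the activity class is taken from a named property."""
    molecules, rejected = [], []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            rejected.append(f"record_{i}")
            continue
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"record_{i}"
        if not mol.HasProp(class_property):
            rejected.append(mol_id)
            continue
        molecules.append(
            LabelledMolecule(
                id=mol_id,
                activity_class=mol.GetProp(class_property),
                smiles=Chem.MolToSmiles(mol),
            )
        )
    return molecules, rejected
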