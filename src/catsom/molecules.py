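"""Molecule parsing, standardization, graph utilities and scalar properties.

Molecules are lightweight wrappers around RDKit graphs.  Parsing applies a
fixed standardization (largest organic fragment, neutralization of simple
charged acids and bases) so that downstream descriptors see a single,
reproducible form of each structure.  All distances are topological
(bond counts on the heavy-atom graph); no 3D geometry is ever used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

# proton mass used for [M+H]+ (CODATA, truncated to the precision reported
# by typical HR-MS software)
PROTON_MASS = 1.00728

#: sentinel for topological distance between disconnected atoms
DISCONNECTED = -1


class MoleculeParseError(ValueError):
    """Raised when a SMILES or SDF record cannot be parsed."""


@dataclass(frozen=True)
class Molecule:
    """Standardized heavy-atom molecular graph.

    Attributes
    ----------
    rdmol:
        The underlying RDKit molecule (implicit hydrogens, sanitized).
    smiles:
        Canonical SMILES of the standardized structure.
    """

    rdmol: Chem.Mol = field(compare=False, repr=False)
    smiles: str

    @property
    def num_atoms(self) -> int:
        """Heavy atom count."""
        return self.rdmol.GetNumAtoms()

    @property
    def atoms(self) -> list[tuple[str, int, int, bool]]:
        """Per-atom (element, formal charge, implicit H count, aromatic)."""
        return [
            (a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs(), a.GetIsAromatic())
            for a in self.rdmol.GetAtoms()
        ]

    @property
    def bonds(self) -> list[tuple[int, int, object]]:
        """Bonds as (i, j, order) with order in {1, 2, 3, 'aromatic'}."""
        out = []
        for b in self.rdmol.GetBonds():
            if b.GetIsAromatic():
                order: object = "aromatic"
            else:
                order = int(b.GetBondTypeAsDouble())
            out.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
        return out

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.smiles


_uncharger = rdMolStandardize.Uncharger()


def _standardize(rdmol: Chem.Mol) -> Chem.Mol:
    """Keep the largest fragment and neutralize simple charged groups.

    This mirrors, at a documented and deliberately simpler level, the kind
    of vendor 'wash' routinely applied to building-block stocks: salts and
    counterions are stripped, and charged acids/bases with an obvious
    neutral form (carboxylates, protonated amines, ...) are neutralized.
    Tautomer canonicalization is intentionally not attempted.
    """
    frags = Chem.GetMolFrags(rdmol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        rdmol = max(frags, key=lambda m: m.GetNumAtoms())
    rdmol = _uncharger.uncharge(rdmol)
    Chem.SanitizeMol(rdmol)
    return rdmol


def parse_smiles(text: str) -> Molecule:
    """Parse a SMILES string into a standardized :class:`Molecule`.

    Parameters
    ----------
    text:
        Non-empty SMILES string.  Multi-component inputs keep the largest
        fragment only.

    Raises
    ------
    MoleculeParseError
        If the string is empty or not valid SMILES.
    """
    if not text or not text.strip():
        raise MoleculeParseError("empty SMILES string")
    text = text.strip()
    rdmol = Chem.MolFromSmiles(text)
    if rdmol is None:
        raise MoleculeParseError(f"cannot parse SMILES {text!r}")
    rdmol = _standardize(rdmol)
    return Molecule(rdmol=rdmol, smiles=Chem.MolToSmiles(rdmol))


def from_rdkit(rdmol: Chem.Mol) -> Molecule:
    """Wrap an already-built RDKit molecule, applying standardization."""
    rdmol = _standardize(Chem.Mol(rdmol))
    return Molecule(rdmol=rdmol, smiles=Chem.MolToSmiles(rdmol))


def molecular_weight(mol: Molecule) -> float:
    """Average molecular weight in Da, implicit hydrogens included."""
    return Descriptors.MolWt(mol.rdmol)


def monoisotopic_mz_protonated(mol: Molecule) -> float:
    """Monoisotopic m/z of the protonated molecular ion [M+H]+.

    Sum of monoisotopic atomic masses (implicit hydrogens included) plus
    the proton mass, rounded to two decimals as reported by HR-MS.
    """
    return round(Descriptors.ExactMolWt(mol.rdmol) + PROTON_MASS, 2)


def alogp(mol: Molecule) -> float:
    """Estimated octanol-water logP (Wildman-Crippen atomic contributions).

    Deterministic for a fixed contribution table; the table is the
    Wildman-Crippen scheme as shipped with the pinned RDKit version.
    """
    return Crippen.MolLogP(mol.rdmol)


@dataclass(frozen=True)
class DistanceMatrix:
    """Topological (bond-count) distances between heavy atoms.

    ``d[i, j]`` is the shortest-path length in bonds; ``DISCONNECTED``
    marks unreachable pairs (cannot occur for standardized single-fragment
    molecules, but the sentinel keeps the type total).
    """

    d: np.ndarray

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def __getitem__(self, ij: tuple[int, int]) -> int:
        return int(self.d[ij])


def topological_distances(mol: Molecule) -> DistanceMatrix:
    """BFS shortest-path matrix over the heavy-atom bond graph."""
    raw = Chem.GetDistanceMatrix(mol.rdmol, force=True)
    d = np.asarray(raw)
    out = np.where(d > mol.num_atoms, DISCONNECTED, d).astype(np.int64)
    return DistanceMatrix(d=out)


# ---------------------------------------------------------------------------
# file I/O


def read_smiles_file(path) -> list[tuple[Molecule, str, list[str]]]:
    """Read a whitespace-delimited SMILES file.

    Each non-empty line holds: SMILES, identifier, and optionally a
    semicolon-separated list of class labels.  Lines starting with ``#``
    are comments.  Returns (molecule, id, labels) triples.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise MoleculeParseError(
                    f"{path}:{lineno}: expected 'SMILES id [labels]', got {line!r}"
                )
            smi, mol_id = parts[0], parts[1]
            labels = parts[2].split(";") if len(parts) > 2 else []
            try:
                mol = parse_smiles(smi)
            except MoleculeParseError as exc:
                raise MoleculeParseError(f"{path}:{lineno}: {exc}") from exc
            records.append((mol, mol_id, labels))
    return records


def read_sdf(path) -> list[tuple[Molecule, str, list[str]]]:
    """Read a V2000 SDF; molecule name field is used as the identifier."""
    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, rdmol in enumerate(supplier):
        if rdmol is None:
            raise MoleculeParseError(f"{path}: record {i} is not parseable")
        mol_id = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else f"sdf_{i}"
        labels = []
        if rdmol.HasProp("labels"):
            labels = [s for s in rdmol.GetProp("labels").split(";") if s]
        records.append((from_rdkit(rdmol), mol_id or f"sdf_{i}", labels))
    return records


def write_smiles_tsv(records, path) -> None:
    """Write (molecule, id[, labels]) records as canonical SMILES TSV."""
    with open(path, "w") as fh:
        for rec in records:
            mol, mol_id = rec[0], rec[1]
            labels = rec[2] if len(rec) > 2 else []
            cols = [mol.smiles, str(mol_id)]
            if labels:
                cols.append(";".join(labels))
            fh.write("\t".join(cols) + "\n")
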