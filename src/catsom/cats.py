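"""CATS topological pharmacophore descriptor.

Every heavy atom is annotated with zero or more potential-pharmacophore-
point types — hydrogen-bond donor (D), acceptor (A), negatively ionizable
(N), positively ionizable (P), lipophilic (L) — and all type pairs are
counted at each topological (bond-count) distance from 0 to 9.  With 15
unordered type pairs and 10 distance bins this yields a 150-dimensional
vector per molecule.

Two scaling modes exist: ``raw`` keeps integer pair counts;
``type-frequency`` divides each bin of pair {t1, t2} by (n_t1 + n_t2),
the summed occurrence counts of the two types in the molecule (0/0 is
defined as 0).  The frequency-scaled form is the default used for map
training, making the descriptor less sensitive to molecular size.

Typing rules are loaded from the versioned data file
``data/pharmacophore_types.yaml``; editing that file is a breaking change.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem

from .molecules import Molecule, topological_distances

logger = logging.getLogger(__name__)

#: type order defining the lexicographic pair layout
TYPES = ("D", "A", "N", "P", "L")

#: the 15 unordered type pairs: DD, DA, DN, DP, DL, AA, AN, ..., LL
PAIR_NAMES: tuple[str, ...] = tuple(
    TYPES[i] + TYPES[j] for i in range(5) for j in range(i, 5)
)

MAX_DISTANCE = 9
N_BINS = len(PAIR_NAMES) * (MAX_DISTANCE + 1)  # 150

#: column names of the descriptor table, e.g. "DA_03"
BIN_NAMES: tuple[str, ...] = tuple(
    f"{pair}_{d:02d}" for pair in PAIR_NAMES for d in range(MAX_DISTANCE + 1)
)

_PAIR_INDEX = {pair: i for i, pair in enumerate(PAIR_NAMES)}
_PAIR_INDEX.update({pair[::-1]: i for i, pair in enumerate(PAIR_NAMES)})

_ALIASES = {
    "HDON": "D",
    "HACC": "A",
    "LIPO": "L",
    "POS": "P",
    "POSION": "P",
    "NEG": "N",
    "NEGION": "N",
    "D": "D",
    "A": "A",
    "N": "N",
    "P": "P",
    "L": "L",
}

RAW = "raw"
TYPE_FREQUENCY = "type-frequency"


def bin_index(pair: str, distance: int) -> int:
    """Flat index of a (type pair, distance) bin."""
    return _PAIR_INDEX[pair] * (MAX_DISTANCE + 1) + distance


def resolve_bin(name: str | int) -> int:
    """Resolve a bin given as index, short name or descriptive name.

    Accepts an integer in [0, 150), a short name such as ``"DA_04"``, or a
    descriptive form such as ``"HDon-HAcc 4 bonds"`` (type aliases: HDon,
    HAcc, Lipo, PosIon, NegIon).
    """
    if isinstance(name, (int, np.integer)):
        if not 0 <= int(name) < N_BINS:
            raise KeyError(f"bin index {name} outside [0, {N_BINS})")
        return int(name)
    text = str(name).strip()
    if text in BIN_NAMES:
        return BIN_NAMES.index(text)
    if "_" in text:
        pair, _, dist = text.partition("_")
        if pair in _PAIR_INDEX and dist.isdigit() and int(dist) <= MAX_DISTANCE:
            return bin_index(pair, int(dist))
    try:
        words = text.replace("bonds", "").replace("bond", "").strip()
        head, dist = words.rsplit(" ", 1)
        t1, t2 = head.split("-")
        pair = _ALIASES[t1.strip().upper()] + _ALIASES[t2.strip().upper()]
        return bin_index(pair, int(dist))
    except (ValueError, KeyError):
        raise KeyError(
            f"unknown bin {name!r}; use an index in [0,150), a short name "
            f"like 'DA_04', or 'HDon-HAcc 4 bonds' "
            f"(valid short names: {', '.join(BIN_NAMES[:3])}, ...)"
        ) from None


# ---------------------------------------------------------------------------
# atom typing


def _load_rules() -> dict:
    ref = importlib.resources.files("catsom.data") / "pharmacophore_types.yaml"
    return yaml.safe_load(ref.read_text())


_RULES = _load_rules()
_SMARTS = {
    "D": [Chem.MolFromSmarts(s) for s in _RULES["donor"]],
    "A": [Chem.MolFromSmarts(s) for s in _RULES["acceptor"]],
    "P": [Chem.MolFromSmarts(s) for s in _RULES["positive"]],
    "N": [Chem.MolFromSmarts(s) for s in _RULES["negative"]],
}
_LIPO_ELEMENTS = set(_RULES["lipophilic"]["elements"])
_LIPO_NEIGHBORS = set(_RULES["lipophilic"]["allowed_neighbors"])


@dataclass(frozen=True)
class PharmacophoreAssignment:
    """Per-atom pharmacophore types and per-type occurrence counts."""

    atom_types: tuple[frozenset[str], ...]
    counts: dict[str, int]

    @property
    def typed_atoms(self) -> list[tuple[int, frozenset[str]]]:
        return [(i, t) for i, t in enumerate(self.atom_types) if t]


def assign_types(mol: Molecule) -> PharmacophoreAssignment:
    """Annotate every heavy atom with its pharmacophore types."""
    rdmol = mol.rdmol
    n = rdmol.GetNumAtoms()
    types: list[set[str]] = [set() for _ in range(n)]
    for t, patterns in _SMARTS.items():
        for patt in patterns:
            for match in rdmol.GetSubstructMatches(patt):
                types[match[0]].add(t)
    for atom in rdmol.GetAtoms():
        if atom.GetSymbol() in _LIPO_ELEMENTS and atom.GetFormalCharge() == 0:
            if all(
                nb.GetSymbol() in _LIPO_NEIGHBORS for nb in atom.GetNeighbors()
            ):
                types[atom.GetIdx()].add("L")
    frozen = tuple(frozenset(t) for t in types)
    counts = {t: sum(1 for s in frozen if t in s) for t in TYPES}
    return PharmacophoreAssignment(atom_types=frozen, counts=counts)


# ---------------------------------------------------------------------------
# descriptor


@dataclass(frozen=True)
class CATSVector:
    """150 pharmacophore-pair counts, possibly frequency-scaled."""

    values: np.ndarray
    scaling: str

    def __post_init__(self):
        if self.values.shape != (N_BINS,):
            raise ValueError(f"CATS vector must have {N_BINS} entries")

    def __len__(self) -> int:
        return N_BINS


def cats_descriptor(mol: Molecule, scaling: str = TYPE_FREQUENCY) -> CATSVector:
    """Compute the 150-dimensional CATS vector of a molecule.

    For every unordered atom pair {i, j} with topological distance
    d(i, j) <= 9 and every type t1 on i, t2 on j, the bin
    (pair{t1, t2}, d) is incremented.  At d = 0 each unordered pair of
    *distinct* types co-occurring on a single atom counts once — a lone
    occurrence of a type is not a pair.
    """
    if scaling not in (RAW, TYPE_FREQUENCY):
        raise ValueError(f"unknown scaling mode {scaling!r}")
    assignment = assign_types(mol)
    typed = assignment.typed_atoms
    values = np.zeros(N_BINS, dtype=float)
    if typed:
        dmat = topological_distances(mol).d
        for a in range(len(typed)):
            i, ti = typed[a]
            # d = 0: distinct-type co-occurrence on one atom
            tlist = sorted(ti, key=TYPES.index)
            for x in range(len(tlist)):
                for y in range(x + 1, len(tlist)):
                    values[bin_index(tlist[x] + tlist[y], 0)] += 1
            for b in range(a + 1, len(typed)):
                j, tj = typed[b]
                d = dmat[i, j]
                if d < 1 or d > MAX_DISTANCE:
                    continue
                for t1 in ti:
                    for t2 in tj:
                        values[bin_index(t1 + t2, d)] += 1
    if scaling == TYPE_FREQUENCY:
        scaled = np.zeros_like(values)
        for p, pair in enumerate(PAIR_NAMES):
            denom = assignment.counts[pair[0]] + assignment.counts[pair[1]]
            sl = slice(p * 10, (p + 1) * 10)
            if denom > 0:
                scaled[sl] = values[sl] / denom
        values = scaled
    return CATSVector(values=values, scaling=scaling)


def cats_matrix(
    records: Iterable[tuple[Molecule, str]],
    scaling: str = TYPE_FREQUENCY,
) -> pd.DataFrame:
    """Descriptor table for a compound collection.

    Rows are compounds (index = id, input order preserved), columns the
    150 named bins.  A molecule whose descriptor fails is logged and
    excluded from the table.
    """
    rows, ids = [], []
    for mol, mol_id in records:
        try:
            vec = cats_descriptor(mol, scaling=scaling)
        except Exception as exc:
            logger.warning("descriptor failed for %s: %s — row excluded", mol_id, exc)
            continue
        rows.append(vec.values)
        ids.append(str(mol_id))
    data = np.vstack(rows) if rows else np.empty((0, N_BINS))
    return pd.DataFrame(data, index=pd.Index(ids, name="id"), columns=list(BIN_NAMES))


def write_cats_tsv(table: pd.DataFrame, path) -> None:
    """Write a descriptor table as TSV (id column first, '.' decimals)."""
    table.to_csv(path, sep="\t", float_format="%.10g")


def read_cats_tsv(path) -> pd.DataFrame:
    """Read a descriptor table written by :func:`write_cats_tsv`."""
    table = pd.read_csv(path, sep="\t", index_col="id")
    table.index = table.index.astype(str)
    table = table.astype(float)
    if list(table.columns) != list(BIN_NAMES):
        raise ValueError(f"{path}: columns do not match the 150 CATS bin names")
    return table
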