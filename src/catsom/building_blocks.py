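"""Reactive-role detection and building-block selection filtering.

Two roles feed the virtual Biginelli condensation: aldehydes (R-CHO with a
carbon substituent; formaldehyde is excluded) and 1,3-dicarbonyls
(C(=O)-CH2-C(=O)X with X a carbon, O-linked or N-linked substituent, i.e.
1,3-diketones, beta-ketoesters and beta-ketoamides).  The selection filter
keeps small, polar, halogen-light blocks bearing exactly one reactive site:
MW < 300 Da, alogP < 2, no Br or I, single functionality — all thresholds
strict, as printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from rdkit import Chem

from .molecules import Molecule, alogp, molecular_weight

ALDEHYDE = "aldehyde"
DICARBONYL = "dicarbonyl"

# carbonyl carbon with exactly one H and a carbon neighbour (excludes
# formaldehyde, formates and formamides)
_ALDEHYDE_SMARTS = Chem.MolFromSmarts("[CX3H1](=[OX1])[#6]")

# C(=O)-CH2-C(=O)X, X in {C, O-linked, N-linked}; matched in both
# directions for asymmetric motifs and deduplicated on the core atoms
_DICARBONYL_SMARTS = Chem.MolFromSmarts(
    "[#6][CX3](=[OX1])[CH2X4][CX3](=[OX1])[#6,OX2,NX3]"
)


@dataclass(frozen=True)
class RoleMatch:
    """One reactive-site match: role plus the atom indices of the site."""

    role: str
    atom_indices: tuple[int, ...]


def _aldehyde_matches(mol: Molecule) -> list[RoleMatch]:
    matches = mol.rdmol.GetSubstructMatches(_ALDEHYDE_SMARTS)
    return [RoleMatch(ALDEHYDE, m[:2]) for m in matches]


def _dicarbonyl_matches(mol: Molecule) -> list[RoleMatch]:
    seen: dict[frozenset, RoleMatch] = {}
    for m in mol.rdmol.GetSubstructMatches(_DICARBONYL_SMARTS):
        # core = two carbonyl carbons + central CH2; symmetric/asymmetric
        # motifs match in both directions but share the same core
        core = frozenset((m[1], m[3], m[4]))
        if core not in seen:
            seen[core] = RoleMatch(DICARBONYL, (m[1], m[2], m[3], m[4], m[5]))
    return list(seen.values())


def detect_role(mol: Molecule) -> tuple[Optional[str], list[RoleMatch]]:
    """Detect the reactive role of a prospective building block.

    Returns ``(role, matches)``.  ``role`` is ``"aldehyde"`` or
    ``"dicarbonyl"`` when exactly one kind of reactive site is present
    (possibly several times); molecules carrying both kinds are ambiguous
    and return ``(None, all_matches)``; molecules with neither return
    ``(None, [])``.
    """
    ald = _aldehyde_matches(mol)
    dic = _dicarbonyl_matches(mol)
    if ald and dic:
        return None, ald + dic
    if ald:
        return ALDEHYDE, ald
    if dic:
        return DICARBONYL, dic
    return None, []


@dataclass(frozen=True)
class BuildingBlock:
    """A filter-passing educt with its detected reactive site."""

    molecule: Molecule
    id: str
    role: str
    reactive_sites: tuple[RoleMatch, ...]

    @property
    def site(self) -> RoleMatch:
        return self.reactive_sites[0]


@dataclass(frozen=True)
class FilterCriteria:
    """Building-block selection thresholds (all strict inequalities)."""

    max_mw: float = 300.0
    max_alogp: float = 2.0
    forbidden_elements: frozenset[str] = frozenset({"Br", "I"})
    require_single_functionality: bool = True


REASON_MW = "molecular weight"
REASON_ALOGP = "alogp"
REASON_ELEMENT = "forbidden element"
REASON_NO_ROLE = "no reactive functionality"
REASON_MULTIPLE = "multiple functionality"
REASON_AMBIGUOUS = "ambiguous functionality"


@dataclass(frozen=True)
class Rejection:
    id: str
    molecule: Molecule
    reason: str


def _first_failure(
    mol: Molecule, criteria: FilterCriteria
) -> tuple[Optional[str], Optional[str], list[RoleMatch]]:
    """Return (reason or None, role, matches); checked in the order:
    forbidden elements, MW, alogp, functionality (element membership is
    the cheapest and most clear-cut check, so it reports first)."""
    symbols = {a.GetSymbol() for a in mol.rdmol.GetAtoms()}
    if symbols & criteria.forbidden_elements:
        return REASON_ELEMENT, None, []
    if not molecular_weight(mol) < criteria.max_mw:
        return REASON_MW, None, []
    if not alogp(mol) < criteria.max_alogp:
        return REASON_ALOGP, None, []
    role, matches = detect_role(mol)
    if role is None:
        return (REASON_AMBIGUOUS if matches else REASON_NO_ROLE), None, matches
    if criteria.require_single_functionality and len(matches) != 1:
        return REASON_MULTIPLE, role, matches
    return None, role, matches


def filter_building_blocks(
    blocks: Iterable[tuple[Molecule, str]],
    criteria: FilterCriteria = FilterCriteria(),
    role: Optional[str] = None,
) -> tuple[list[BuildingBlock], list[Rejection]]:
    """Partition candidate blocks into kept building blocks and rejections.

    Parameters
    ----------
    blocks:
        (molecule, id) pairs, order preserved in both outputs.
    criteria:
        Selection thresholds; defaults follow the printed criteria.
    role:
        If given (``"aldehyde"`` or ``"dicarbonyl"``), blocks whose
        detected role differs are rejected with a reason naming the
        expected role.

    Each rejection carries the first failing criterion, checked in the
    order: MW, alogp, forbidden elements, functionality.
    """
    kept: list[BuildingBlock] = []
    rejected: list[Rejection] = []
    for mol, mol_id in blocks:
        reason, detected, matches = _first_failure(mol, criteria)
        if reason is None and role is not None and detected != role:
            reason = f"wrong role (expected {role}, found {detected})"
        if reason is not None:
            rejected.append(Rejection(id=mol_id, molecule=mol, reason=reason))
        else:
            kept.append(
                BuildingBlock(
                    molecule=mol,
                    id=mol_id,
                    role=detected,
                    reactive_sites=tuple(matches),
                )
            )
    return kept, rejected
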