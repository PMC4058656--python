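"""Exhaustive virtual Biginelli three-component product construction.

The Biginelli condensation joins an aldehyde, a 1,3-dicarbonyl compound and
urea into a 3,4-dihydropyrimidin-2(1H)-one.  Urea is hard-coded as the third
component; each (aldehyde, dicarbonyl) pair yields exactly one product.

Ring construction (atom labels follow pyrimidinone numbering)::

    N1(H)-C2(=O)-N3(H)-C4(H)(R_ald)-C5=C6(R_ket)-N1

The ring-forming carbonyl of the dicarbonyl becomes C6 and keeps its
substituent; the other carbonyl stays exocyclic on C5.  Two carbonyl
oxygens (one from the aldehyde, one from the ring-forming ketone) are lost
as water during the double condensation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from rdkit import Chem

from .building_blocks import ALDEHYDE, DICARBONYL, BuildingBlock
from .molecules import Molecule, from_rdkit

#: SMARTS for the 3,4-dihydropyrimidin-2(1H)-one core
DIHYDROPYRIMIDINONE_SMARTS = Chem.MolFromSmarts(
    "[NX3H1]1[CX3](=[OX1])[NX3H1][CX4][CX3]=[CX3]1"
)


class EnumerationError(RuntimeError):
    """Raised when a product cannot be assembled from a block pair."""


@dataclass(frozen=True)
class ProductRecord:
    """One virtual product with its provenance."""

    molecule: Molecule
    id: str
    aldehyde_id: str
    dicarbonyl_id: str
    #: True when the dicarbonyl was asymmetric and a regiochemical choice
    #: (which carbonyl enters the ring) was made
    regiochemical_choice: bool


def _substituent_size(rdmol: Chem.Mol, carbonyl: int, exclude: set[int]) -> tuple[int, int]:
    """Heavy-atom count of the substituent on ``carbonyl`` away from the
    motif, with the substituent root index as tie-break key."""
    root = None
    for nb in rdmol.GetAtomWithIdx(carbonyl).GetNeighbors():
        if nb.GetIdx() not in exclude:
            root = nb.GetIdx()
    if root is None:  # no substituent beyond the motif (cannot happen for
        return 0, -1  # SMARTS-matched blocks, kept for safety)
    seen = {carbonyl, root}
    stack = [root]
    while stack:
        for nb in rdmol.GetAtomWithIdx(stack.pop()).GetNeighbors():
            if nb.GetIdx() not in seen:
                seen.add(nb.GetIdx())
                stack.append(nb.GetIdx())
    return len(seen) - 1, root


def _pick_ring_carbonyl(rdmol: Chem.Mol, site) -> tuple[int, int, int, int, bool]:
    """Decide which carbonyl of the 1,3-dicarbonyl motif enters the ring.

    Returns (ring_C, ring_O, exo_C, central_CH2, regio_choice).  The
    carbonyl whose non-methylene substituent is smaller (fewer heavy
    atoms) becomes the ring carbonyl — the methyl ketone wins, matching
    classical Biginelli selectivity where the ketone condenses into the
    ring while esters and amides cannot.  Ester-/amide-type carbonyls
    (O-/N-linked substituent) never enter the ring; among two ketones the
    size rule applies, ties broken by lower atom index.  ``regio_choice``
    is True whenever the two carbonyls are not symmetry-equivalent, i.e.
    a genuine regiochemical decision was made.
    """
    c1, o1, ch2, c2, o2 = site.atom_indices
    motif = {c1, o1, ch2, c2, o2}

    ranks = list(Chem.CanonicalRankAtoms(rdmol, breakTies=False))
    choice = ranks[c1] != ranks[c2]

    def is_ketone(c: int) -> bool:
        for nb in rdmol.GetAtomWithIdx(c).GetNeighbors():
            if nb.GetIdx() not in motif:
                return nb.GetSymbol() == "C"
        return False

    k1, k2 = is_ketone(c1), is_ketone(c2)
    if k1 and not k2:
        return c1, o1, c2, ch2, choice
    if k2 and not k1:
        return c2, o2, c1, ch2, choice
    size1, _ = _substituent_size(rdmol, c1, motif)
    size2, _ = _substituent_size(rdmol, c2, motif)
    if (size1, c1) <= (size2, c2):
        return c1, o1, c2, ch2, choice
    return c2, o2, c1, ch2, choice


def biginelli_product(aldehyde: BuildingBlock, dicarbonyl: BuildingBlock) -> ProductRecord:
    """Assemble the dihydropyrimidinone product of one block pair.

    Raises
    ------
    EnumerationError
        If either role is wrong or graph assembly produces an invalid
        molecule; the message names both block ids.
    """
    if aldehyde.role != ALDEHYDE or dicarbonyl.role != DICARBONYL:
        raise EnumerationError(
            f"wrong roles for pair ({aldehyde.id}, {dicarbonyl.id}): "
            f"got ({aldehyde.role}, {dicarbonyl.role})"
        )
    try:
        return _assemble(aldehyde, dicarbonyl)
    except EnumerationError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise EnumerationError(
            f"assembly failed for pair ({aldehyde.id}, {dicarbonyl.id}): {exc}"
        ) from exc


def _assemble(aldehyde: BuildingBlock, dicarbonyl: BuildingBlock) -> ProductRecord:
    ald_mol = aldehyde.molecule.rdmol
    dic_mol = dicarbonyl.molecule.rdmol
    ald_c, ald_o = aldehyde.site.atom_indices[:2]
    ring_c, ring_o, exo_c, ch2, choice = _pick_ring_carbonyl(dic_mol, dicarbonyl.site)

    combined = Chem.RWMol(Chem.CombineMols(ald_mol, dic_mol))
    off = ald_mol.GetNumAtoms()
    ring_c, ring_o, ch2 = ring_c + off, ring_o + off, ch2 + off

    # urea fragment: N1, C2, O2, N3
    n1 = combined.AddAtom(Chem.Atom(7))
    c2 = combined.AddAtom(Chem.Atom(6))
    o2 = combined.AddAtom(Chem.Atom(8))
    n3 = combined.AddAtom(Chem.Atom(7))
    combined.AddBond(n1, c2, Chem.BondType.SINGLE)
    combined.AddBond(c2, o2, Chem.BondType.DOUBLE)
    combined.AddBond(c2, n3, Chem.BondType.SINGLE)

    # close the ring: N3-C4(ald), C4-C5(ch2), C5=C6(ring ketone C), C6-N1
    combined.AddBond(n3, ald_c, Chem.BondType.SINGLE)
    combined.AddBond(ald_c, ch2, Chem.BondType.SINGLE)
    combined.RemoveBond(ch2, ring_c)
    combined.AddBond(ch2, ring_c, Chem.BondType.DOUBLE)
    combined.AddBond(ring_c, n1, Chem.BondType.SINGLE)

    # two condensations lose both carbonyl oxygens as water
    for o_idx in sorted((ald_o, ring_o), reverse=True):
        combined.RemoveAtom(o_idx)

    rdmol = combined.GetMol()
    try:
        Chem.SanitizeMol(rdmol)
        product = from_rdkit(rdmol)
    except Exception as exc:
        raise EnumerationError(
            f"invalid product for pair ({aldehyde.id}, {dicarbonyl.id}): {exc}"
        ) from exc
    if not product.rdmol.HasSubstructMatch(DIHYDROPYRIMIDINONE_SMARTS):
        raise EnumerationError(
            f"product of ({aldehyde.id}, {dicarbonyl.id}) lacks the "
            "dihydropyrimidinone core"
        )
    return ProductRecord(
        molecule=product,
        id=f"{aldehyde.id}__{dicarbonyl.id}",
        aldehyde_id=aldehyde.id,
        dicarbonyl_id=dicarbonyl.id,
        regiochemical_choice=choice,
    )


def enumerate_library(
    aldehydes: Sequence[BuildingBlock],
    dicarbonyls: Sequence[BuildingBlock],
    skip_failures: bool = False,
    dedup: bool = False,
) -> list[ProductRecord]:
    """Full combinatorial enumeration, aldehyde-major order.

    Exactly one product per (aldehyde, dicarbonyl) pair, so the output
    size is ``len(aldehydes) * len(dicarbonyls)`` unless ``dedup`` removes
    identical products from distinct pairs (off by default) or
    ``skip_failures`` drops failing pairs (otherwise the first failure
    aborts the run).
    """
    if not aldehydes or not dicarbonyls:
        raise EnumerationError("both building-block lists must be non-empty")
    products: list[ProductRecord] = []
    seen: set[str] = set()
    for ald in aldehydes:
        for dic in dicarbonyls:
            try:
                rec = biginelli_product(ald, dic)
            except EnumerationError:
                if skip_failures:
                    continue
                raise
            if dedup:
                if rec.molecule.smiles in seen:
                    continue
                seen.add(rec.molecule.smiles)
            products.append(rec)
    return products
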