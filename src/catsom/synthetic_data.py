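"""Synthetic building blocks and annotated reference libraries.

Real building-block stocks and annotated bioactivity collections are
proprietary, so every experiment in this package can run on synthetic
stand-ins generated here.  Generation is grammar-based — templates with
substitution slots filled from small decoration alphabets — so chemical
validity is guaranteed by construction, and every emitted structure is
checked against the package's own parsing, filtering and descriptor code.

Building blocks emulate a stock of small, filter-passing aldehydes
(substituted benzaldehydes plus aliphatic aldehydes) and 1,3-dicarbonyls
(beta-ketoamides, beta-ketoesters, 1,3-diketones).  Reference libraries
emulate a target-annotated compound collection: each target class is a
scaffold family with a distinct pharmacophore-pair signature, so class
structure is recoverable from CATS space by construction — exactly what
the descriptor can see, and nothing else.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .building_blocks import (
    ALDEHYDE,
    DICARBONYL,
    BuildingBlock,
    FilterCriteria,
    filter_building_blocks,
)
from .molecules import Molecule, parse_smiles

# ---------------------------------------------------------------------------
# building-block grammars

# ring substituents lean polar: the selection filter demands alogP < 2 and
# the benzaldehyde core alone sits near 1.5
_RING_SUBS = [
    "C", "OC", "OCC", "O", "F", "Cl", "C#N", "N(C)C", "N", "CO",
    "C(N)=O", "NC(C)=O", "OCCO", "[N+](=O)[O-]", "S(C)(=O)=O",
]

_ALDEHYDE_TEMPLATES = [
    "O=Cc1ccccc1",
    "O=Cc1ccc({X})cc1",
    "O=Cc1cccc({X})c1",
    "O=Cc1ccc({X})c({Y})c1",
]

_ALIPHATIC_ALDEHYDES = [
    "O=CC",
    "O=CCC",
    "O=CCCC",
    "O=CCCCC",
    "O=CC(C)C",
    "O=CCC(C)C",
    "O=CCOC",
    "O=CCCOC",
    "O=CCc1ccccc1",
    "O=CCCc1ccccc1",
]

_AMIDE_N_SUBS = ["C", "CC", "CCC", "C(C)C", "CCO", "CCOC"]
_ANILIDE_TEMPLATES = [
    "CC(=O)CC(=O)Nc1ccccc1",
    "CC(=O)CC(=O)Nc1ccc({X})cc1",
    "CC(=O)CC(=O)Nc1cccc({X})c1",
]
_ESTER_O_SUBS = ["C", "CC", "CCC", "C(C)C", "CCCC", "CC(C)C", "CCOC", "CCCOC", "CCO", "CCCO"]
_KETONE_SUBS = ["C", "CC", "CCC", "C(C)C"]
_DIKETONE_SUBS = ["C", "CC", "CCC", "C(C)C", "C(C)(C)C", "c1ccccc1", "c1ccc(OC)cc1", "c1ccc(F)cc1"]


def _aldehyde_grammar() -> list[str]:
    out = ["O=Cc1ccccc1"]
    out += [f"O=Cc1ccc({x})cc1" for x in _RING_SUBS]
    out += [f"O=Cc1cccc({x})c1" for x in _RING_SUBS]
    out += [
        f"O=Cc1ccc({x})c({y})c1" for x, y in itertools.product(_RING_SUBS, _RING_SUBS)
    ]
    out += list(_ALIPHATIC_ALDEHYDES)
    return out


def _dicarbonyl_grammar() -> list[str]:
    out = []
    # beta-ketoamides: alkyl amides, anilides (incl. substituted rings),
    # N,N-dialkyl amides, and ketone-side variants
    out += [f"CC(=O)CC(=O)N{x}" for x in _AMIDE_N_SUBS]
    out += ["CC(=O)CC(=O)Nc1ccccc1"]
    out += [f"CC(=O)CC(=O)Nc1ccc({x})cc1" for x in _RING_SUBS]
    out += [f"CC(=O)CC(=O)Nc1cccc({x})c1" for x in _RING_SUBS]
    out += [f"CC(=O)CC(=O)N({x})C" for x in _AMIDE_N_SUBS if x != "C"]
    out += [f"{r}C(=O)CC(=O)NC" for r in _KETONE_SUBS if r != "C"]
    # beta-ketoesters
    out += [f"CC(=O)CC(=O)O{x}" for x in _ESTER_O_SUBS]
    out += [f"{r}C(=O)CC(=O)OCC" for r in _KETONE_SUBS if r != "C"]
    out += [f"{r}C(=O)CC(=O)OC" for r in _KETONE_SUBS if r != "C"]
    # 1,3-diketones
    out += [f"CC(=O)CC(=O){r}" for r in _DIKETONE_SUBS]
    out += ["CCC(=O)CC(=O)CC", "CCC(=O)CC(=O)CCC"]
    return out


class GrammarCapacityError(ValueError):
    """Requested more blocks than the grammar can supply."""


def _filtered_pool(smiles_list: Sequence[str], role: str) -> list[BuildingBlock]:
    """Parse a grammar, run the real selection filter, dedupe canonically."""
    seen: set[str] = set()
    candidates: list[tuple[Molecule, str]] = []
    for i, smi in enumerate(smiles_list):
        mol = parse_smiles(smi)
        if mol.smiles in seen:
            continue
        seen.add(mol.smiles)
        candidates.append((mol, f"{role[:3]}_{i:03d}"))
    kept, _ = filter_building_blocks(candidates, FilterCriteria(), role=role)
    return kept


def gen_building_blocks(
    n_aldehydes: int, n_dicarbonyls: int, seed: int = 0
) -> tuple[list[BuildingBlock], list[BuildingBlock]]:
    """Generate unique, filter-passing aldehyde and 1,3-dicarbonyl blocks.

    The full grammar is enumerated deterministically, passed through the
    default selection filter, then subsampled with a seeded shuffle; the
    same seed always returns the same lists.

    Raises
    ------
    GrammarCapacityError
        If a requested count exceeds the number of filter-passing
        structures the grammar can produce (the message states the
        maximum).
    """
    if n_aldehydes < 1 or n_dicarbonyls < 1:
        raise ValueError("block counts must be >= 1")
    pools = {
        ALDEHYDE: _filtered_pool(_aldehyde_grammar(), ALDEHYDE),
        DICARBONYL: _filtered_pool(_dicarbonyl_grammar(), DICARBONYL),
    }
    for role, n in ((ALDEHYDE, n_aldehydes), (DICARBONYL, n_dicarbonyls)):
        if n > len(pools[role]):
            raise GrammarCapacityError(
                f"requested {n} {role} blocks but the grammar supplies at "
                f"most {len(pools[role])}"
            )
    rng = np.random.default_rng(seed)
    out = []
    for role, n in ((ALDEHYDE, n_aldehydes), (DICARBONYL, n_dicarbonyls)):
        pool = pools[role]
        idx = rng.permutation(len(pool))[:n]
        out.append([pool[i] for i in sorted(idx)])
    return out[0], out[1]


# ---------------------------------------------------------------------------
# reference libraries


@dataclass(frozen=True)
class ClassSpec:
    """One synthetic target class: a scaffold family with a CATS signature.

    ``templates`` are SMILES with ``{R}`` substitution slots filled from
    ``decorations``.  ``signature_bins`` documents which descriptor bins
    the family elevates (metadata, not enforced).  ``purity`` is the
    probability that a compound is drawn from this family's own templates
    rather than from a shared neutral pool — the effect-size dial: 1.0
    plants the strongest class signal.
    """

    name: str
    templates: tuple[str, ...]
    decorations: tuple[str, ...]
    n_compounds: int
    signature_bins: tuple[str, ...] = ()
    purity: float = 1.0


#: neutral filler scaffolds used when purity < 1
_NEUTRAL_TEMPLATES = (
    "CCOC(=O)c1ccc({R})cc1",
    "CC(C)Cc1ccc({R})cc1",
    "COc1ccc(C{R})cc1",
)


def default_class_specs(
    n_signal: int = 125, n_background: int = 375
) -> list[ClassSpec]:
    """Two-class default: a donor/acceptor-rich 'kinase_like' signal class
    against a lipophilic-amine 'gpcr_like' background class.

    The signal class is deliberately the minority (default 25% of
    compounds): the fold over-representation of a class in a pure cluster
    is bounded by the reciprocal of its background fraction, so a
    balanced design could never show more than 2-fold enrichment.
    """
    kinase = ClassSpec(
        name="kinase_like",
        templates=(
            "O=C(Nc1ccc({R})cc1)Nc1ncccn1",
            "Nc1nc({R})nc(Nc2ccccc2)n1",
            "O=C(N{R})c1ccc(Nc2ncccn2)cc1",
            "Nc1ncnc(N{R})n1",
        ),
        decorations=("C", "CC", "CCC", "C(C)C", "Cc1ccccc1", "CCO", "CCOC"),
        n_compounds=n_signal,
        signature_bins=("DA_02", "DA_03", "DA_04", "DD_02", "DD_03"),
    )
    gpcr = ClassSpec(
        name="gpcr_like",
        templates=(
            "CN(C)CCCc1ccc({R})cc1",
            "CCN(CC)CCOc1ccc({R})cc1",
            "CN(C)CCCOc1cccc({R})c1",
            "CCCN(CCC)CCc1ccc({R})cc1",
        ),
        decorations=("C", "CC", "CCC", "C(C)C", "CCCC", "Cl", "CCc1ccccc1"),
        n_compounds=n_background,
        signature_bins=("PL_03", "PL_04", "PL_05", "LL_04", "LL_05"),
    )
    return [kinase, gpcr]


def gen_reference_library(
    specs: Sequence[ClassSpec], seed: int = 0
) -> list[tuple[Molecule, str, list[str]]]:
    """Generate a labeled reference library from class specifications.

    Returns shuffled (molecule, id, labels) triples; every compound
    carries exactly the label of its class.  Deterministic per seed.
    """
    if not specs:
        raise ValueError("at least one ClassSpec is required")
    rng = np.random.default_rng(seed)
    records: list[tuple[Molecule, str, list[str]]] = []
    for spec in specs:
        if not (0 < spec.purity <= 1):
            raise ValueError(f"class {spec.name!r}: purity must be in (0, 1]")
        for i in range(spec.n_compounds):
            if rng.random() < spec.purity:
                template = spec.templates[rng.integers(len(spec.templates))]
            else:
                template = _NEUTRAL_TEMPLATES[rng.integers(len(_NEUTRAL_TEMPLATES))]
            smi = template
            while "{R}" in smi:
                smi = smi.replace(
                    "{R}", spec.decorations[rng.integers(len(spec.decorations))], 1
                )
            mol = parse_smiles(smi)
            records.append((mol, f"{spec.name}_{i:04d}", [spec.name]))
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def labels_dict(records: Sequence[tuple[Molecule, str, list[str]]]) -> dict[str, list[str]]:
    """Map compound id -> class labels for a generated library."""
    return {rec[1]: list(rec[2]) for rec in records}
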