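"""Target-class analytics on a trained map.

A "cluster" is a single neuron, labeled by its 0-based grid coordinate
"(x/y)".  Reference compounds carry one or more target-class labels;
multi-label compounds count once per class (labels are annotations, not a
partition).  Enrichment of a class in a cluster is its fraction among the
cluster's reference compounds divided by a background fraction.  The
default background basis is "compound": the fraction of all reference
compounds carrying the class, which makes the whole-map enrichment of
every class exactly 1.  A "target" basis — background fractions computed
over a target catalogue rather than over compounds — is supported by
passing explicit background fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .som import Assignment, SOMModel

COMPOUND_BASIS = "compound"
TARGET_BASIS = "target"


class EnrichmentUndefinedError(ValueError):
    """Raised when a fold cannot be computed (zero background fraction)."""


def density_map(
    assignments: Sequence[Assignment], config, origin: Optional[str] = None
) -> np.ndarray:
    """Per-neuron compound counts as an (H, W) integer grid.

    ``grid[y, x]`` is the number of assignments on neuron (x, y); when
    ``origin`` is given only assignments with that origin tag count.
    """
    grid = np.zeros((config.height, config.width), dtype=int)
    for a in assignments:
        if origin is not None and a.origin != origin:
            continue
        grid[a.y, a.x] += 1
    return grid


def _cluster_members(
    assignments: Sequence[Assignment], cluster: tuple[int, int], origin: str
) -> list[Assignment]:
    x, y = cluster
    return [a for a in assignments if a.x == x and a.y == y and a.origin == origin]


def class_fractions(
    assignments: Sequence[Assignment],
    labels: Mapping[str, Sequence[str]],
    cluster: tuple[int, int],
) -> dict[str, float]:
    """Per-class fraction among the reference compounds on one neuron.

    fraction = (cluster members carrying the class) / (reference
    compounds in the cluster).  An empty cluster returns an empty dict.
    """
    members = _cluster_members(assignments, cluster, "reference")
    if not members:
        return {}
    counts: dict[str, int] = {}
    for a in members:
        for cls in labels.get(a.compound_id, ()):
            counts[cls] = counts.get(cls, 0) + 1
    return {cls: c / len(members) for cls, c in counts.items()}


def background_fractions(
    assignments: Sequence[Assignment], labels: Mapping[str, Sequence[str]]
) -> dict[str, float]:
    """Compound-basis background: fraction of references carrying each class."""
    refs = [a for a in assignments if a.origin == "reference"]
    if not refs:
        return {}
    counts: dict[str, int] = {}
    for a in refs:
        for cls in labels.get(a.compound_id, ()):
            counts[cls] = counts.get(cls, 0) + 1
    return {cls: c / len(refs) for cls, c in counts.items()}


def enrichment_factor(cluster_fraction: float, background_fraction: float) -> float:
    """Fold over-representation: cluster fraction / background fraction.

    A zero background makes the fold undefined and raises
    :class:`EnrichmentUndefinedError` — never infinity.
    """
    if cluster_fraction < 0 or background_fraction < 0:
        raise ValueError("fractions must be non-negative")
    if background_fraction == 0:
        raise EnrichmentUndefinedError(
            "background fraction is 0: fold over-representation is undefined"
        )
    return cluster_fraction / background_fraction


def top_cluster(
    assignments: Sequence[Assignment],
    labels: Mapping[str, Sequence[str]],
    class_name: str,
    config,
) -> tuple[int, int]:
    """Neuron with the most reference members of a class.

    Ties break toward the smallest linear index y*W + x.
    """
    counts = np.zeros((config.height, config.width), dtype=int)
    for a in assignments:
        if a.origin == "reference" and class_name in labels.get(a.compound_id, ()):
            counts[a.y, a.x] += 1
    if counts.sum() == 0:
        raise ValueError(f"class {class_name!r} absent from the reference assignments")
    flat = int(np.argmax(counts))  # argmax is first-max: smallest y*W + x
    return flat % config.width, flat // config.width


def centroid_reference(
    model: SOMModel,
    cluster: tuple[int, int],
    assignments: Sequence[Assignment],
) -> str:
    """Reference compound closest to the cluster's neuron weight vector.

    For members of the cluster the stored BMU distance *is* the distance
    to that neuron's weights, so the member with the smallest distance is
    the centroid representative.
    """
    members = _cluster_members(assignments, cluster, "reference")
    if not members:
        raise ValueError(
            f"cluster ({cluster[0]}/{cluster[1]}) holds no reference compounds"
        )
    best = min(members, key=lambda a: (a.distance, a.compound_id))
    return best.compound_id


def candidate_pick(
    assignments: Sequence[Assignment], cluster: tuple[int, int]
) -> list[str]:
    """Library compounds on a neuron, sorted by BMU distance ascending."""
    members = _cluster_members(assignments, cluster, "library")
    members.sort(key=lambda a: (a.distance, a.compound_id))
    return [a.compound_id for a in members]


def feature_map(
    model: SOMModel,
    bin_name,
    mode: str = "weights",
    assignments: Optional[Sequence[Assignment]] = None,
    table=None,
) -> np.ndarray:
    """Per-neuron value of one CATS bin as an (H, W) grid.

    ``mode="weights"`` (default) shows the neuron weight plane — the
    column slice of the weight matrix.  ``mode="mean"`` averages the bin
    over the compounds assigned to each neuron (requires ``assignments``
    and the descriptor ``table``); empty neurons show NaN.
    """
    from .cats import resolve_bin

    idx = resolve_bin(bin_name)
    cfg = model.config
    if mode == "weights":
        return model.weights[:, idx].reshape(cfg.height, cfg.width)
    if mode == "mean":
        if assignments is None or table is None:
            raise ValueError("mode='mean' needs assignments and a descriptor table")
        total = np.zeros((cfg.height, cfg.width))
        count = np.zeros((cfg.height, cfg.width))
        col = table.iloc[:, idx]
        values = dict(zip(table.index.astype(str), col.to_numpy(dtype=float)))
        for a in assignments:
            if a.compound_id in values:
                total[a.y, a.x] += values[a.compound_id]
                count[a.y, a.x] += 1
        with np.errstate(invalid="ignore"):
            return np.where(count > 0, total / np.maximum(count, 1), np.nan)
    raise ValueError(f"unknown feature-map mode {mode!r}")


def write_labels_tsv(labels: Mapping[str, Sequence[str]], path) -> None:
    """Write id -> semicolon-joined class labels as a two-column TSV."""
    with open(path, "w") as fh:
        fh.write("id\tlabels\n")
        for mol_id, classes in labels.items():
            fh.write(f"{mol_id}\t{';'.join(classes)}\n")


def read_labels_tsv(path) -> dict[str, list[str]]:
    """Read a labels TSV written by :func:`write_labels_tsv`."""
    labels: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            mol_id, _, raw = line.partition("\t")
            labels[mol_id] = [c for c in raw.split(";") if c]
    return labels


@dataclass(frozen=True)
class ClusterProfile:
    """Class composition of one neuron."""

    x: int
    y: int
    total: int
    class_counts: dict[str, int]
    class_fractions: dict[str, float]
    folds: dict[str, float]


@dataclass(frozen=True)
class EnrichmentReport:
    """Per-neuron class fractions and folds plus the background used."""

    basis: str
    background: dict[str, float]
    clusters: list[ClusterProfile]

    def cluster(self, x: int, y: int) -> Optional[ClusterProfile]:
        for c in self.clusters:
            if c.x == x and c.y == y:
                return c
        return None

    def to_dict(self) -> dict:
        return {
            "basis": self.basis,
            "background": dict(sorted(self.background.items())),
            "clusters": [
                {
                    "x": c.x,
                    "y": c.y,
                    "label": f"({c.x}/{c.y})",
                    "total": c.total,
                    "class_counts": dict(sorted(c.class_counts.items())),
                    "class_fractions": dict(sorted(c.class_fractions.items())),
                    "folds": dict(sorted(c.folds.items())),
                }
                for c in self.clusters
            ],
        }


def enrichment_report(
    assignments: Sequence[Assignment],
    labels: Mapping[str, Sequence[str]],
    config,
    background: Optional[Mapping[str, float]] = None,
    basis: str = COMPOUND_BASIS,
) -> EnrichmentReport:
    """Full per-neuron enrichment profile of the reference projection.

    With the default compound basis the background is computed from the
    reference assignments themselves; a target-basis background (class
    fractions over a target catalogue) can be passed explicitly.  Folds
    for classes with zero background are omitted (undefined, never
    infinity).
    """
    if background is None:
        if basis != COMPOUND_BASIS:
            raise ValueError("explicit background fractions required for target basis")
        background = background_fractions(assignments, labels)
    clusters: list[ClusterProfile] = []
    refs = [a for a in assignments if a.origin == "reference"]
    occupied = sorted({(a.y, a.x) for a in refs})
    for y, x in occupied:
        members = _cluster_members(refs, (x, y), "reference")
        counts: dict[str, int] = {}
        for a in members:
            for cls in labels.get(a.compound_id, ()):
                counts[cls] = counts.get(cls, 0) + 1
        fractions = {cls: c / len(members) for cls, c in counts.items()}
        folds = {
            cls: fractions[cls] / background[cls]
            for cls in fractions
            if background.get(cls, 0) > 0
        }
        clusters.append(
            ClusterProfile(
                x=x,
                y=y,
                total=len(members),
                class_counts=counts,
                class_fractions=fractions,
                folds=folds,
            )
        )
    return EnrichmentReport(basis=basis, background=dict(background), clusters=clusters)
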