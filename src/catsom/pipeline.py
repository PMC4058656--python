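"""End-to-end library-profiling pipeline.

Drives the whole chain on file inputs: filter building blocks, enumerate
the virtual library, compute CATS descriptors for references and library,
train a toroidal SOM on the references, project both collections, profile
target-class enrichment, and pick candidate compounds from the class's top
cluster.  Every artifact is written to the output directory together with
a manifest of all parameter values and derived seeds, which is sufficient
to reproduce every output byte for byte.

One global seed is expanded into per-stage seeds by hashing
``"<seed>:<stage name>"`` (SHA-256, reduced mod 2^31), so any stage can be
rerun in isolation with its own seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .building_blocks import ALDEHYDE, DICARBONYL, FilterCriteria, filter_building_blocks
from .cats import TYPE_FREQUENCY, cats_matrix, write_cats_tsv
from .enumeration import enumerate_library
from .molecules import read_smiles_file
from .profiling import (
    candidate_pick,
    centroid_reference,
    enrichment_report,
    top_cluster,
    write_labels_tsv,
)
from .som import SOMConfig, init_som, project, train, write_assignments_tsv

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed: SHA-256 of '<seed>:<stage>' mod 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)


@dataclass
class PipelineConfig:
    """All inputs and parameters of one profiling run."""

    aldehydes: str
    dicarbonyls: str
    references: str
    outdir: str
    target_class: str
    seed: int = 42
    scaling: str = TYPE_FREQUENCY
    labels: Optional[str] = None  # defaults to labels in the references file
    filter_criteria: FilterCriteria = field(default_factory=FilterCriteria)
    som_width: int = 15
    som_height: int = 20
    som_cycles: int = 1_000_000
    som_sigma0: float = 7.0
    som_sigma_end: float = 0.5
    som_alpha0: float = 0.5
    som_alpha_end: float = 0.01

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        crit = raw.pop("filter_criteria", None)
        if crit is not None:
            if "forbidden_elements" in crit:
                crit["forbidden_elements"] = frozenset(crit["forbidden_elements"])
            raw["filter_criteria"] = FilterCriteria(**crit)
        return cls(**raw)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


@dataclass(frozen=True)
class PipelineResult:
    outdir: Path
    report: dict
    candidates: list[str]
    top_cluster: tuple[int, int]
    centroid_id: str
    manifest: dict


def _check_inputs(config: PipelineConfig) -> None:
    for name in ("aldehydes", "dicarbonyls", "references"):
        path = getattr(config, name)
        if not Path(path).is_file():
            raise PipelineError(f"stage load: missing {name} file {path}")
    if config.labels is not None and not Path(config.labels).is_file():
        raise PipelineError(f"stage load: missing labels file {config.labels}")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute filter → enumerate → cats → train → project → profile.

    Returns the in-memory result; all artifacts are also written under
    ``config.outdir``.
    """
    _check_inputs(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("stage %s ...", name)
        timings[name] = time.perf_counter()
        return name

    def done(name):
        timings[name] = time.perf_counter() - timings[name]
        logger.info("stage %s done in %.1fs", name, timings[name])

    # ---- filter -----------------------------------------------------------
    s = stage("filter")
    ald_raw = [(m, i) for m, i, _ in read_smiles_file(config.aldehydes)]
    dic_raw = [(m, i) for m, i, _ in read_smiles_file(config.dicarbonyls)]
    aldehydes, ald_rej = filter_building_blocks(
        ald_raw, config.filter_criteria, role=ALDEHYDE
    )
    dicarbonyls, dic_rej = filter_building_blocks(
        dic_raw, config.filter_criteria, role=DICARBONYL
    )
    if not aldehydes or not dicarbonyls:
        raise PipelineError("stage filter: no building blocks survive the filter")
    done(s)

    # ---- enumerate --------------------------------------------------------
    s = stage("enumerate")
    products = enumerate_library(aldehydes, dicarbonyls)
    done(s)

    # ---- descriptors ------------------------------------------------------
    s = stage("cats")
    ref_records = read_smiles_file(config.references)
    if config.labels is not None:
        from .profiling import read_labels_tsv

        labels = read_labels_tsv(config.labels)
    else:
        labels = {rid: lab for _, rid, lab in ref_records}
    if not any(labels.values()):
        raise PipelineError("stage cats: reference compounds carry no class labels")
    ref_table = cats_matrix([(m, i) for m, i, _ in ref_records], scaling=config.scaling)
    lib_table = cats_matrix(
        [(p.molecule, p.id) for p in products], scaling=config.scaling
    )
    write_cats_tsv(ref_table, outdir / "cats_references.tsv")
    write_cats_tsv(lib_table, outdir / "cats_library.tsv")
    done(s)

    # ---- train ------------------------------------------------------------
    s = stage("train")
    som_seed = stage_seed(config.seed, "train")
    som_config = SOMConfig(
        width=config.som_width,
        height=config.som_height,
        cycles=config.som_cycles,
        sigma0=config.som_sigma0,
        sigma_end=config.som_sigma_end,
        alpha0=config.som_alpha0,
        alpha_end=config.som_alpha_end,
        seed=som_seed,
    )
    model = train(init_som(som_config, ref_table), ref_table)
    model.to_json(outdir / "som.json")
    done(s)

    # ---- project ----------------------------------------------------------
    s = stage("project")
    ref_assign = project(model, ref_table, origin="reference")
    lib_assign = project(model, lib_table, origin="library")
    write_assignments_tsv(ref_assign, outdir / "assignments_references.tsv")
    write_assignments_tsv(lib_assign, outdir / "assignments_library.tsv")
    done(s)

    # ---- profile ----------------------------------------------------------
    s = stage("profile")
    try:
        cluster = top_cluster(ref_assign, labels, config.target_class, som_config)
    except ValueError as exc:
        raise PipelineError(f"stage profile: {exc}") from exc
    report = enrichment_report(ref_assign, labels, som_config)
    centroid_id = centroid_reference(model, cluster, ref_assign)
    candidates = candidate_pick(ref_assign + lib_assign, cluster)
    report_dict = {
        "target_class": config.target_class,
        "top_cluster": {"x": cluster[0], "y": cluster[1], "label": f"({cluster[0]}/{cluster[1]})"},
        "centroid_reference": centroid_id,
        "n_candidates": len(candidates),
        "enrichment": report.to_dict(),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report_dict, fh, indent=2, sort_keys=True)
    with open(outdir / "candidates.tsv", "w") as fh:
        fh.write("rank\tid\n")
        for rank, cid in enumerate(candidates, 1):
            fh.write(f"{rank}\t{cid}\n")
    write_labels_tsv(labels, outdir / "labels.tsv")
    done(s)

    manifest = {
        "package_version": __version__,
        "config": {
            **{
                k: v
                for k, v in asdict(config).items()
                if k != "filter_criteria"
            },
            "filter_criteria": {
                "max_mw": config.filter_criteria.max_mw,
                "max_alogp": config.filter_criteria.max_alogp,
                "forbidden_elements": sorted(config.filter_criteria.forbidden_elements),
                "require_single_functionality": config.filter_criteria.require_single_functionality,
            },
        },
        "derived_seeds": {"train": som_seed},
        "counts": {
            "aldehydes_kept": len(aldehydes),
            "aldehydes_rejected": len(ald_rej),
            "dicarbonyls_kept": len(dicarbonyls),
            "dicarbonyls_rejected": len(dic_rej),
            "products": len(products),
            "references": int(ref_table.shape[0]),
        },
        "stage_seconds": {k: round(v, 2) for k, v in timings.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        outdir=outdir,
        report=report_dict,
        candidates=candidates,
        top_cluster=cluster,
        centroid_id=centroid_id,
        manifest=manifest,
    )
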