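"""End-to-end runs: bulge census and activation analysis.

Each run writes its outputs plus a manifest (input file hashes, seeds,
parameters, package version) sufficient to reproduce them exactly; reruns
with unchanged inputs are byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .features import PruneConfig, build_feature_table, common_residues, prune_correlated
from .forest import RFConfig, export_vector_script, fit_importances
from .secondary import assign_secondary_structure, bulge_census, find_alpha_bulges
from .structures import (
    SegmentTable,
    Structure,
    apply_numbering,
    default_segments,
    load_numbering_table,
    mapping_for,
    read_structure,
    strip_to_receptor,
)

__all__ = ["RunConfig", "run_bulge_census", "run_activation_analysis", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a run cannot proceed (missing inputs, no usable data)."""


@dataclass
class StructureEntry:
    path: str
    chain: str = "A"
    model: int = 1
    keep_ranges: list[tuple[int, int]] | None = None


@dataclass
class RunConfig:
    structures: list[StructureEntry]
    mapping_file: str | None = None
    segment_file: str | None = None
    labels_file: str | None = None
    output_dir: str = "seventm_out"
    prune_threshold: float = 0.90
    prune_absolute: bool = False
    seed: int = 0
    n_trees: int = 1000
    top_k: int = 20
    reference_structure_id: str | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        entries = [StructureEntry(**e) if isinstance(e, dict) else StructureEntry(e) for e in raw.pop("structures")]
        return cls(structures=entries, **raw)

    def preflight(self) -> None:
        missing = []
        for entry in self.structures:
            if not Path(entry.path).exists():
                missing.append(entry.path)
        for p in (self.mapping_file, self.segment_file, self.labels_file):
            if p is not None and not Path(p).exists():
                missing.append(p)
        if missing:
            raise PipelineError(f"missing input files: {missing}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_structures(config: RunConfig) -> list[Structure]:
    mapping_table = load_numbering_table(config.mapping_file) if config.mapping_file else None
    structures = []
    for entry in config.structures:
        try:
            st = read_structure(entry.path, chain=entry.chain, model=entry.model)
            if entry.keep_ranges:
                st = strip_to_receptor(st, [tuple(r) for r in entry.keep_ranges])
            if mapping_table is not None:
                mapping = mapping_for(mapping_table, st.id, entry.chain)
                if mapping:
                    st = apply_numbering(st, mapping)
            structures.append(st)
        except Exception as exc:  # noqa: BLE001 - runs continue past bad entries
            logger.warning("skipping %s: %s", entry.path, exc)
    if not structures:
        raise PipelineError("no structure could be loaded")
    return structures


def _segments(config: RunConfig) -> SegmentTable:
    return SegmentTable.from_tsv(config.segment_file) if config.segment_file else default_segments()


def _manifest(config: RunConfig, extra: dict) -> dict:
    inputs = {}
    for entry in config.structures:
        inputs[entry.path] = _sha256(entry.path)
    for p in (config.mapping_file, config.segment_file, config.labels_file):
        if p is not None:
            inputs[p] = _sha256(p)
    return {
        "seventm_version": __version__,
        "seed": config.seed,
        "prune_threshold": config.prune_threshold,
        "n_trees": config.n_trees,
        "inputs_sha256": inputs,
        **extra,
    }


def run_bulge_census(config: RunConfig) -> "object":
    """α-bulge census over all configured structures; returns the DataFrame
    and writes census.tsv plus per-structure assignment TSVs."""
    config.preflight()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    structures = _load_structures(config)
    segments = _segments(config)

    for st in structures:
        try:
            assignment = assign_secondary_structure(st)
            assignment.to_tsv(st, out / f"{st.id}_assignment.tsv")
        except Exception as exc:  # noqa: BLE001
            logger.warning("assignment failed for %s: %s", st.id, exc)
    census = bulge_census(structures, segments)
    if census.empty:
        raise PipelineError("census failed for every structure")
    census.to_csv(out / "census.tsv", sep="\t", index_label="structure_id")
    with open(out / "manifest.json", "w") as fh:
        json.dump(_manifest(config, {"run": "bulge_census", "n_structures": len(census)}), fh, indent=2, sort_keys=True)
    return census


def _load_labels(path: str | Path) -> dict[str, str]:
    labels = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if line.strip():
                sid, cls = line.rstrip("\n").split("\t")[:2]
                labels[sid] = cls
    return labels


def run_activation_analysis(config: RunConfig):
    """common residues → feature table → pruning → forest → vector script.

    Writes features.tsv, prune_log.json, importance.tsv, vectors.pml/.tsv
    and manifest.json into the output directory; returns the report.
    """
    config.preflight()
    if config.labels_file is None:
        raise PipelineError("activation analysis needs a labels file")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    structures = _load_structures(config)
    labels = _load_labels(config.labels_file)

    residues = common_residues(structures)
    table = build_feature_table(structures, residues)
    table.to_tsv(out / "features.tsv")

    pruned, removals = prune_correlated(
        table,
        PruneConfig(threshold=config.prune_threshold, seed=config.seed, absolute=config.prune_absolute),
    )
    with open(out / "prune_log.json", "w") as fh:
        json.dump(
            {
                "threshold": config.prune_threshold,
                "seed": config.seed,
                "absolute": config.prune_absolute,
                "n_before": table.n_features,
                "n_after": pruned.n_features,
                "removals": [
                    {"kept": list(r.kept), "removed": list(r.removed),
                     "r": None if r.r != r.r else round(r.r, 6), "reason": r.reason}
                    for r in removals
                ],
            },
            fh,
            indent=2,
        )

    report = fit_importances(pruned, labels, RFConfig(n_trees=config.n_trees, seed=config.seed))
    report.to_tsv(out / "importance.tsv")
    if report.oob_error >= 0.5 - 1e-9:
        logger.warning("classes appear inseparable (OOB error %.2f)", report.oob_error)

    reference = structures[0]
    if config.reference_structure_id is not None:
        reference = next(
            (st for st in structures if st.id == config.reference_structure_id), reference
        )
    export_vector_script(report, config.top_k, reference, out / "vectors.pml", out / "vectors.tsv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(
            _manifest(
                config,
                {
                    "run": "activation_analysis",
                    "n_common_residues": len(residues),
                    "n_features": table.n_features,
                    "n_features_pruned": pruned.n_features,
                    "oob_error": report.oob_error,
                },
            ),
            fh,
            indent=2,
            sort_keys=True,
        )
    return report
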