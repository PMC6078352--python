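"""End-to-end pipeline: manifest validation and stage orchestration.

A run manifest (YAML or JSON) names the conditions of a competition
experiment, flags exactly one as the control, and points each
condition/replicate at either a pre-tabulated count table or a set of
FASTQ files (one per timepoint).  ``run_pipeline`` then produces, in
one output directory: per-condition normalized landscapes, difference
maps against the control, the position classification, hierarchical
clustering, and PCA of the difference vectors, plus a JSON run report
with parameters and input digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .barcode_counts import collapse_to_variants, extract_and_count, read_count_table
from .fitness import (
    DEFAULT_MIN_T0_COUNT,
    DEFAULT_PSEUDOCOUNT,
    average_replicates,
    estimate_raw_fitness,
    normalize_landscape,
    write_landscape,
)
from .landscape import (
    classify_positions,
    difference_map,
    min_across_conditions,
    position_average,
    write_classification,
    write_difference_map,
)
from .multivariate import (
    DEFAULT_CLUSTER_CUTOFF,
    build_condition_matrix,
    flat_clusters,
    pca_difference,
    tree_to_newick,
    ward_cluster,
    write_linkage,
    write_pca,
)
from .synthetic_data import read_barcode_map
from .variants import YEAST_UBIQUITIN

logger = logging.getLogger(__name__)


class ManifestError(ValueError):
    """Raised when a run manifest fails validation."""


class StageError(RuntimeError):
    """Raised when a pipeline stage fails, naming stage and condition."""


@dataclass
class ReplicateInput:
    replicate: int
    generations: list[float]
    counts: Path | None = None
    fastq: list[Path] = field(default_factory=list)


@dataclass
class ConditionSpec:
    name: str
    control: bool
    replicates: list[ReplicateInput]


@dataclass
class RunManifest:
    """Validated experiment description.

    Exactly one condition is flagged as the control; every referenced
    file must resolve at validation time, before any computation.
    """

    conditions: list[ConditionSpec]
    wt_sequence: str = YEAST_UBIQUITIN
    barcode_map: Path | None = None
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        controls = [c for c in self.conditions if c.control]
        if len(controls) != 1:
            raise ManifestError(
                f"exactly one control condition required, found {len(controls)}"
            )
        missing: list[str] = []
        needs_map = False
        for cond in self.conditions:
            if not cond.replicates:
                raise ManifestError(f"condition {cond.name!r} has no replicates")
            for rep in cond.replicates:
                if rep.counts is not None:
                    if not rep.counts.exists():
                        missing.append(str(rep.counts))
                elif rep.fastq:
                    needs_map = True
                    if len(rep.fastq) != len(rep.generations):
                        raise ManifestError(
                            f"{cond.name} replicate {rep.replicate}: one FASTQ "
                            "per timepoint required"
                        )
                    missing.extend(str(p) for p in rep.fastq if not p.exists())
                else:
                    raise ManifestError(
                        f"{cond.name} replicate {rep.replicate}: needs counts or fastq"
                    )
        if needs_map:
            if self.barcode_map is None:
                raise ManifestError("FASTQ inputs require a barcode_map")
            if not self.barcode_map.exists():
                missing.append(str(self.barcode_map))
        if missing:
            raise ManifestError(f"missing input files: {missing}")

    @property
    def control(self) -> ConditionSpec:
        return next(c for c in self.conditions if c.control)

    def input_paths(self) -> list[Path]:
        paths = []
        if self.barcode_map is not None:
            paths.append(self.barcode_map)
        for cond in self.conditions:
            for rep in cond.replicates:
                if rep.counts is not None:
                    paths.append(rep.counts)
                paths.extend(rep.fastq)
        return paths


def load_manifest(path: str | Path) -> RunManifest:
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    base = path.parent

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    conditions = []
    for c in doc.get("conditions", []):
        reps = []
        for r in c.get("replicates", []):
            reps.append(
                ReplicateInput(
                    replicate=int(r.get("replicate", len(reps) + 1)),
                    generations=[float(g) for g in r["generations"]],
                    counts=resolve(r["counts"]) if "counts" in r else None,
                    fastq=[resolve(p) for p in r.get("fastq", [])],
                )
            )
        conditions.append(
            ConditionSpec(
                name=c["name"], control=bool(c.get("control", False)), replicates=reps
            )
        )
    return RunManifest(
        conditions=conditions,
        wt_sequence=doc.get("wt_sequence", YEAST_UBIQUITIN),
        barcode_map=resolve(doc["barcode_map"]) if "barcode_map" in doc else None,
        parameters=doc.get("parameters", {}),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(manifest: RunManifest, out_dir: str | Path) -> dict:
    """Execute every stage; returns the machine-readable run report.

    Deterministic given the manifest and its inputs: re-running with
    identical inputs produces byte-identical tabular outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = {
        "pseudocount": DEFAULT_PSEUDOCOUNT,
        "min_t0_count": DEFAULT_MIN_T0_COUNT,
        "max_mismatch": 1,
        "cluster_cutoff": DEFAULT_CLUSTER_CUTOFF,
        "exclude_stops_pca": True,
        **manifest.parameters,
    }
    report: dict = {
        "version": __version__,
        "parameters": params,
        "inputs": {str(p): _sha256(p) for p in sorted(manifest.input_paths())},
        "stages": {},
    }

    bmap = None
    if manifest.barcode_map is not None:
        bmap = read_barcode_map(manifest.barcode_map, manifest.wt_sequence)

    # Stage 1: counts -> normalized, replicate-averaged landscapes
    landscapes = {}
    for cond in manifest.conditions:
        try:
            reps = []
            for rep in cond.replicates:
                if rep.counts is not None:
                    table = read_count_table(rep.counts)
                else:
                    table = extract_and_count(
                        rep.fastq,
                        bmap,
                        max_mismatch=int(params["max_mismatch"]),
                        generations=rep.generations,
                        condition=cond.name,
                        replicate=rep.replicate,
                    )
                if table.level == "barcode":
                    if bmap is None:
                        raise ValueError(
                            "barcode-level counts require a barcode_map"
                        )
                    table = collapse_to_variants(table, bmap)
                raw = estimate_raw_fitness(
                    table,
                    pseudocount=float(params["pseudocount"]),
                    min_t0_count=int(params["min_t0_count"]),
                )
                reps.append(
                    normalize_landscape(
                        raw, manifest.wt_sequence, cond.name, rep.replicate
                    )
                )
            landscapes[cond.name] = average_replicates(reps)
        except Exception as exc:
            raise StageError(f"fitness stage failed for {cond.name!r}: {exc}") from exc
    land_dir = out_dir / "landscapes"
    land_dir.mkdir(exist_ok=True)
    for name, l in landscapes.items():
        write_landscape(l, land_dir / f"{name}.tsv")
    report["stages"]["fitness"] = {"conditions": sorted(landscapes)}

    control_name = manifest.control.name
    treatments = [c.name for c in manifest.conditions if not c.control]

    # Stage 2: difference maps vs control
    diff_maps = {}
    if treatments:
        diff_dir = out_dir / "difference_maps"
        diff_dir.mkdir(exist_ok=True)
        for name in treatments:
            try:
                dmap = difference_map(landscapes[name], landscapes[control_name])
            except Exception as exc:
                raise StageError(
                    f"difference stage failed for {name!r}: {exc}"
                ) from exc
            diff_maps[name] = dmap
            write_difference_map(dmap, diff_dir / f"{name}_minus_{control_name}.tsv")
        report["stages"]["difference"] = {"treatments": sorted(diff_maps)}
    else:
        logger.info("control-only manifest: difference stage skipped")
        report["stages"]["difference"] = "skipped (control only)"

    # Stage 3: position classification on the minimum average fitness
    profiles = [position_average(l) for l in landscapes.values()]
    classified = classify_positions(min_across_conditions(profiles))
    write_classification(classified, out_dir / "position_classes.tsv")
    counts = classified.labels.value_counts().to_dict()
    report["stages"]["classification"] = {str(k): int(v) for k, v in counts.items()}

    # Stage 4: hierarchical clustering of absolute fitness vectors
    if len(landscapes) >= 2:
        try:
            cmat = build_condition_matrix(landscapes, exclude_stops=False)
            tree = ward_cluster(cmat)
        except Exception as exc:
            raise StageError(f"clustering stage failed: {exc}") from exc
        write_linkage(tree, out_dir / "linkage.tsv")
        (out_dir / "dendrogram.nwk").write_text(tree_to_newick(tree) + "\n")
        assign = flat_clusters(tree, float(params["cluster_cutoff"]))
        assign.to_csv(out_dir / "clusters.tsv", sep="\t")
        report["stages"]["clustering"] = {
            "n_vectors": len(cmat.conditions),
            "n_mutants": len(cmat.mutants),
            "n_clusters": int(assign.max()),
        }
    else:
        logger.info("fewer than 2 conditions: clustering skipped")
        report["stages"]["clustering"] = "skipped"

    # Stage 5: PCA of difference vectors (stop substitutions excluded)
    if len(diff_maps) >= 2:
        try:
            dmat = build_condition_matrix(
                {n: d for n, d in diff_maps.items()},
                exclude_stops=bool(params["exclude_stops_pca"]),
            )
            pca = pca_difference(dmat)
        except Exception as exc:
            raise StageError(f"PCA stage failed: {exc}") from exc
        write_pca(pca, out_dir)
        report["stages"]["pca"] = {
            "n_vectors": len(dmat.conditions),
            "n_mutants": len(dmat.mutants),
            "explained_variance_ratio": [
                float(x) for x in pca.explained_variance_ratio[:5]
            ],
        }
    else:
        logger.info("fewer than 2 treatments: PCA skipped")
        report["stages"]["pca"] = "skipped"

    (out_dir / "run_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report


@dataclass(frozen=True)
class IdentityResult:
    """Positionwise percent identity between two equal-length
    amino-acid sequences."""

    length: int
    mismatches: int

    @property
    def matches(self) -> int:
        return self.length - self.mismatches

    @property
    def exact_fraction(self) -> float:
        return self.matches / self.length

    @property
    def percent(self) -> int:
        """Identity rounded to the nearest integer percent."""
        return round(100.0 * self.exact_fraction)


def pairwise_identity(seq_a: str, seq_b: str) -> IdentityResult:
    """Positionwise identity of two equal-length sequences (no
    alignment is performed)."""
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequences have different lengths ({len(seq_a)} vs {len(seq_b)})"
        )
    if not seq_a:
        raise ValueError("sequences are empty")
    mismatches = sum(a != b for a, b in zip(seq_a, seq_b))
    return IdentityResult(length=len(seq_a), mismatches=mismatches)
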