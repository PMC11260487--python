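"""End-to-end runs: occupancy → classification → states [→ gradients].

A run is driven by a RunConfig, executes the stages in order on either
rendered density maps or a precomputed occupancy table, and writes every
stage output plus a JSON manifest (seed, parameters, package version,
sha256 of each output) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .blocks import load_block_library
from .clustering import (
    ClassAssignment,
    LatentEncodings,
    VolumePartition,
    class_mean_occupancy,
    hierarchical_cluster,
    kmeans_partition,
    order_heatmap,
)
from .errors import ComparisonError, ValidationError
from .gradients import DEFAULT_WINDOWS, baseline_correct, quantify_profile
from .io_formats import read_density_map, read_gradient_trace, read_structure
from .occupancy import DEFAULT_THRESHOLD, load_occupancy_matrix, occupancy_matrix, save_occupancy_matrix
from .synthetic import SyntheticEnsemble
from .taxonomy import StateSummary, TaxonomyRules, assign_state, compare_state_distributions, state_fractions

logger = logging.getLogger("ribohet")

__all__ = [
    "RunConfig",
    "run_pipeline",
    "compare_runs",
    "volume_matrix_from_particles",
    "classify_and_summarize",
]


@dataclass
class RunConfig:
    """Inputs, thresholds and clustering options of one pipeline run."""

    out_dir: str
    blocks_path: str | None = None
    model_path: str | None = None
    maps_dir: str | None = None
    matrix_path: str | None = None  # alternative to maps_dir + model
    trace_paths: list[str] = field(default_factory=list)
    threshold: float = DEFAULT_THRESHOLD  # occupancy threshold tau, sd units
    theta: float = 0.5  # folded threshold of the taxonomy
    h68_bins: tuple[float, float, float] = (0.25, 0.5, 0.75)
    n_classes: int | str = "auto"
    seed: int = 0
    dataset: str = "run"

    def validate(self) -> None:
        if self.matrix_path is None and (self.maps_dir is None or self.model_path is None):
            raise ValidationError("config needs either matrix_path or maps_dir + model_path")
        if self.blocks_path is None:
            raise ValidationError("config needs a block library path")
        for p in filter(None, [self.blocks_path, self.model_path, self.maps_dir,
                               self.matrix_path, *self.trace_paths]):
            if not Path(p).exists():
                raise ValidationError(f"input path does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def volume_matrix_from_particles(
    ensemble: SyntheticEnsemble, partition: VolumePartition
) -> pd.DataFrame:
    """Per-volume occupancy rows from a particle partition.

    Each k-means cluster becomes one volume whose occupancy row is the mean
    of its member particles' rows — the matrix-level analogue of
    reconstructing a representative map from the cluster's particles.
    """
    rows, ids, counts = [], [], []
    for k in range(partition.K):
        members = partition.assignment == k
        if not members.any():
            continue
        rows.append(ensemble.occupancy_rows[members].mean(axis=0))
        ids.append(f"vol{k:03d}")
        counts.append(int(members.sum()))
    matrix = pd.DataFrame(np.asarray(rows), columns=ensemble.block_names)
    matrix.insert(0, "particle_count", counts)
    matrix.insert(0, "volume_id", ids)
    return matrix


def classify_and_summarize(
    matrix: pd.DataFrame,
    rules: TaxonomyRules,
    n_classes: int | str = "auto",
    dataset: str = "",
) -> tuple[ClassAssignment, pd.DataFrame, dict, StateSummary]:
    """Ward classification, class means, per-class states, state summary."""
    classes = hierarchical_cluster(matrix, n_classes=n_classes)
    means = class_mean_occupancy(matrix, classes)
    block_cols = [c for c in means.columns if c != "particle_count"]
    states = {
        int(label): assign_state(means.loc[label, block_cols], rules)
        for label in means.index
    }
    summary = state_fractions(
        classes,
        states,
        matrix["particle_count"].to_numpy(),
        dataset=dataset,
        taxonomy_signature=rules.signature(),
    )
    return classes, means, states, summary


def run_pipeline(config: RunConfig) -> dict:
    """Execute the stages in order and write outputs + manifest to out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    library = load_block_library(config.blocks_path)
    outputs: dict[str, str] = {}

    # stage 1: occupancy
    if config.matrix_path is not None:
        matrix = load_occupancy_matrix(config.matrix_path)
        logger.info("loaded occupancy matrix: %d volumes", len(matrix))
    else:
        model = read_structure(config.model_path)
        map_paths = sorted(Path(config.maps_dir).glob("*.mrc")) + sorted(
            Path(config.maps_dir).glob("*.map")
        )
        volumes = [read_density_map(p) for p in map_paths]
        logger.info("read %d volumes, %d atoms", len(volumes), len(model))
        matrix = occupancy_matrix(volumes, model, library, threshold=config.threshold)
    matrix_path = out / "occupancy_matrix.tsv"
    save_occupancy_matrix(matrix, matrix_path)
    outputs["occupancy_matrix"] = str(matrix_path)

    # stage 2: classification
    rules = TaxonomyRules.from_library(library, theta=config.theta, h68_bins=config.h68_bins)
    classes, means, states, summary = classify_and_summarize(
        matrix, rules, n_classes=config.n_classes, dataset=config.dataset
    )
    logger.info("classified %d volumes into %d classes", len(matrix), classes.n_classes)
    assign_path = out / "class_assignment.tsv"
    pd.DataFrame(
        {"volume_id": matrix["volume_id"], "class": classes.labels}
    ).to_csv(assign_path, sep="\t", index=False)
    outputs["class_assignment"] = str(assign_path)
    ordered_path = out / "ordered_matrix.tsv"
    heatmap_path = out / "heatmap.png"
    order_heatmap(matrix, classes, image_path=heatmap_path).to_csv(
        ordered_path, sep="\t", index=False
    )
    outputs["ordered_matrix"] = str(ordered_path)
    outputs["heatmap"] = str(heatmap_path)

    # stage 3: states
    means_path = out / "class_mean_occupancy.tsv"
    means.assign(state=[str(states[i]) for i in means.index]).to_csv(means_path, sep="\t")
    outputs["class_mean_occupancy"] = str(means_path)
    summary_path = out / "state_summary.tsv"
    summary.to_frame().to_csv(summary_path, sep="\t")
    outputs["state_summary"] = str(summary_path)

    # stage 4: gradient traces (optional)
    if config.trace_paths:
        quant_rows = []
        for tp in config.trace_paths:
            trace = baseline_correct(read_gradient_trace(tp))
            quant = quantify_profile(trace, DEFAULT_WINDOWS)
            row = {"sample": quant.label, "ratio_50s_30s": quant.ratio_50s_30s}
            quant_rows.append(row)
        quant_path = out / "gradient_quantification.tsv"
        pd.DataFrame(quant_rows).to_csv(quant_path, sep="\t", index=False)
        outputs["gradient_quantification"] = str(quant_path)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "dataset": config.dataset,
        "parameters": {
            "threshold": config.threshold,
            "theta": config.theta,
            "h68_bins": list(config.h68_bins),
            "n_classes": config.n_classes,
        },
        "taxonomy_signature": rules.signature(),
        "n_volumes": int(len(matrix)),
        "n_classes_found": int(classes.n_classes),
        "outputs": {k: {"path": v, "sha256": _sha256(Path(v))} for k, v in outputs.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    manifest["manifest_path"] = str(manifest_path)
    return manifest


def _load_summary(manifest: dict) -> StateSummary:
    path = manifest["outputs"]["state_summary"]["path"]
    df = pd.read_csv(path, sep="\t", index_col="state")
    return StateSummary(
        fractions=df["fraction"],
        counts=df["particle_count"],
        dataset=manifest.get("dataset", ""),
        taxonomy_signature=manifest.get("taxonomy_signature"),
    )


def compare_runs(manifest_a: dict, manifest_b: dict) -> dict:
    """State-distribution delta table plus a parameter diff between two runs."""
    if manifest_a.get("taxonomy_signature") != manifest_b.get("taxonomy_signature"):
        raise ComparisonError("runs use different taxonomies; distributions not comparable")
    delta = compare_state_distributions(_load_summary(manifest_a), _load_summary(manifest_b))
    pa, pb = manifest_a["parameters"], manifest_b["parameters"]
    param_diff = {
        k: {"a": pa.get(k), "b": pb.get(k)}
        for k in sorted(set(pa) | set(pb))
        if pa.get(k) != pb.get(k)
    }
    if param_diff:
        logger.warning("runs differ in parameters: %s", sorted(param_diff))
    return {"delta_table": delta, "parameter_diff": param_diff}
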