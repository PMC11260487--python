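"""Headline recovery experiments at study scale.

Each function regenerates its synthetic inputs at the study's stated
conditions, runs the pipeline, and returns the recovered quantity:

* class-count recovery — 500 occupancy rows drawn from the per-class state
  templates (per-block noise sd 0.05), auto dendrogram cut;
* state-fraction recovery — an ensemble of particles drawn with the
  reported per-state weights, partitioned into 500 volumes by k-means on
  8-D latent encodings, ward-classified, taxonomized, and summarized with
  particle weighting;
* gradient-ratio recovery — a two-peak A260 trace planted with a given
  (pre)50S/30S area ratio, baseline-corrected and integrated.
"""

from __future__ import annotations

import numpy as np

from .clustering import LatentEncodings, hierarchical_cluster, kmeans_partition
from .gradients import DEFAULT_WINDOWS, baseline_correct, quantify_profile
from .pipeline import classify_and_summarize, volume_matrix_from_particles
from .synthetic import (
    StateTemplate,
    delta_nloop_templates,
    delta_yjga_templates,
    make_phantom,
    simulate_ensemble,
    simulate_gradient_trace,
    template_matrix,
)
from .taxonomy import StateSummary, TaxonomyRules

__all__ = [
    "recover_class_count",
    "recover_state_fractions",
    "recover_gradient_ratio",
    "TEMPLATE_SETS",
]

TEMPLATE_SETS = {"delta_yjga": delta_yjga_templates, "delta_nloop": delta_nloop_templates}


def recover_class_count(
    dataset: str, n_volumes: int = 500, noise_sd: float = 0.05, seed: int = 1
) -> int:
    """Auto-cut class count of a synthetic volume ensemble."""
    matrix = template_matrix(
        TEMPLATE_SETS[dataset](), n_volumes=n_volumes, noise_sd=noise_sd, seed=seed
    )
    return hierarchical_cluster(matrix, n_classes="auto").n_classes


def recover_state_fractions(
    dataset: str,
    n_particles: int = 200_000,
    K: int = 500,
    seed: int = 1,
) -> StateSummary:
    """Full occupancy -> partition -> classification -> taxonomy recovery.

    Particles are drawn with the dataset's per-state weights; k-means on
    their latent encodings defines the volumes; each volume's occupancy row
    is the mean over its member particles; classes and states follow.
    """
    templates = TEMPLATE_SETS[dataset]()
    ensemble = simulate_ensemble(templates, n_particles=n_particles, seed=seed)
    partition = kmeans_partition(
        LatentEncodings(ensemble.latent_values), K=K, seed=seed, n_init=1
    )
    matrix = volume_matrix_from_particles(ensemble, partition)
    _, library = make_phantom(seed=seed)
    rules = TaxonomyRules.from_library(library)
    _, _, _, summary = classify_and_summarize(
        matrix, rules, n_classes="auto", dataset=dataset
    )
    return summary


def recover_gradient_ratio(
    planted_ratio: float,
    seed: int = 1,
    n_points: int = 2000,
    noise_fraction: float = 0.01,
) -> float:
    """Recovered (pre)50S/30S area ratio from a planted two-peak trace.

    The 30S peak has unit area; the (pre)50S peak carries the planted area
    ratio; white noise sd is the stated fraction of the tallest peak, on a
    linear drifting baseline.
    """
    width_30s, width_50s = 0.20, 0.22
    max_height = max(
        1.0 / (width_30s * np.sqrt(2 * np.pi)),
        planted_ratio / (width_50s * np.sqrt(2 * np.pi)),
    )
    trace = simulate_gradient_trace(
        [(3.0, 1.0, width_30s), (5.0, planted_ratio, width_50s)],
        drift_slope=0.005,
        drift_intercept=0.1,
        noise_sd=noise_fraction * max_height,
        n_points=n_points,
        seed=seed,
        label=f"planted_{planted_ratio}",
    )
    quant = quantify_profile(baseline_correct(trace), DEFAULT_WINDOWS)
    return quant.ratio_50s_30s
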