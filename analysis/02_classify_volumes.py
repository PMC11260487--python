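#!/usr/bin/env python
"""Ward-classify the simulated volume ensembles and check class recovery.

Reads the occupancy matrices written by 01_simulate_ensembles.py, clusters
each with the auto dendrogram cut, writes the ordered heatmap and class
assignment, and reports the recovered class count against the planted one
(11 classes for the yjgA-deletion ensemble, 10 for the N-loop one).
"""

import json
from pathlib import Path

import pandas as pd

from ribohet.clustering import class_mean_occupancy, hierarchical_cluster, order_heatmap
from ribohet.occupancy import load_occupancy_matrix

ENSEMBLES = Path(__file__).resolve().parent.parent / "results" / "ensembles"


def main() -> None:
    for dataset_dir in sorted(ENSEMBLES.iterdir()):
        matrix = load_occupancy_matrix(dataset_dir / "occupancy_matrix.tsv")
        truth = json.loads((dataset_dir / "ground_truth.json").read_text())
        classes = hierarchical_cluster(matrix, n_classes="auto")
        ordered = order_heatmap(matrix, classes, image_path=dataset_dir / "heatmap.png")
        ordered.to_csv(dataset_dir / "ordered_matrix.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"volume_id": matrix["volume_id"], "class": classes.labels}
        ).to_csv(dataset_dir / "class_assignment.tsv", sep="\t", index=False)
        class_mean_occupancy(matrix, classes).to_csv(
            dataset_dir / "class_mean_occupancy.tsv", sep="\t"
        )
        planted = len(set(truth["classes"]))
        mark = "recovered" if classes.n_classes == planted else "MISMATCH"
        print(f"{dataset_dir.name}: auto cut -> {classes.n_classes} classes "
              f"(planted {planted}; {mark})")


if __name__ == "__main__":
    main()
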